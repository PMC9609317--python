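name	casrn	role	formula	mz	ccs	adduct	parents
Aldrin	309-00-2	parent	C12H8Cl6	361.88	157.56	ambiguous
DDD-p,p'	72-54-8	parent	C14H10Cl4	316.95	170.62	M-H
DDT-o,p'	789-02-6	parent	C14H9Cl5
DDT-p,p'	50-29-3	parent	C14H9Cl5
Dicofol	115-32-2	parent	C14H9Cl5O
Dieldrin	60-57-1	parent	C12H8Cl6O	378.88	160.76	M+H
Endosulfan I	115-29-7	parent	C9H6Cl6O3S	404.82	175.19	M+H
Endrin	72-20-8	parent	C12H8Cl6O
Heptachlor epoxide B	1024-57-3	parent	C10H5Cl7O	386.82	177.49	M+H
Heptachlor	76-44-8	parent	C10H5Cl7
Lindane	58-89-9	parent	C6H6Cl6
Methoxychlor-o,p'	72-43-5	parent	C16H15Cl3O2
Parathion	56-38-2	parent	C10H14NO5PS
Trifluralin	1582-09-8	parent	C13H16F3N3O4	336.12	161.69	M+H
2,4-Dinitrophenol	51-28-5	parent	C6H4N2O5	183.01	127.81	M-H
Azinphos-methyl	86-50-0	parent	C10H12N3O3PS2	339.99	169.57	M+Na
Chlorpyrifos	2921-88-2	parent	C9H11Cl3NO3PS	371.91	172.35	M+Na
Diazinon	333-41-5	parent	C12H21N2O3PS	327.09	174.89	M+Na
Disulfoton	298-04-4	parent	C8H19O2PS3	297.02	165.2	M+Na
Ethion	563-12-2	parent	C9H22O4P2S4	406.98	180.81	M+Na
2-Amino-4-nitrophenol	99-57-0	metabolite	C6H6N2O3	153.03	116.54	M-H	2,4-Dinitrophenol
4-Amino-2-nitrophenol	119-34-6	metabolite	C6H6N2O3	153.03	117.87	M-H	2,4-Dinitrophenol
Azinphos-methyl oxon	961-22-8	metabolite	C10H12N3O4PS	324.02	177.67	M+Na	Azinphos-methyl
DDA-p,p'	5359-38-6	metabolite	C14H10Cl2O2	278.98	152.46	M-H	DDD-p,p'
DDE-p,p'	72-55-9	metabolite	C14H8Cl4				DDT-p,p'
Diazoxon	962-58-3	metabolite	C12H21N2O4P				Diazinon
Diethylthiophosphate	5871-17-0	metabolite	C4H11O3PS	171.02	129.33	M+H	Diazinon;Chlorpyrifos;Ethion
Diethyldithiophosphate	298-06-6	metabolite	C4H11O2PS2	187.00	135.08	M+H	Ethion
Dimethylthiophosphate	1112-38-5	metabolite	C2H7O3PS	142.99	113.21	M+H	Azinphos-methyl
Disulfoton sulfone	2497-06-5	metabolite	C8H19O4PS3	307.03	156.79	M+H	Disulfoton
Atrazine	1912-24-9	internal_standard	C8H14ClN5
Benzo[a]anthracene	56-55-3	internal_standard	C18H12
Terbutryn	886-50-0	internal_standard	C10H19N5S
Mifepristone	84371-65-3	internal_standard	C29H35NO2
Troglitazone	97322-87-7	internal_standard	C24H27NO5S
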