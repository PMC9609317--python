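# Methods

## Chemical registry and ion library

The registry (`mixtox/data/default_library.tsv`) lists the 20 test
pesticides, 10 known metabolites and 5 internal standards by name and CASRN,
with molecular formulas resolved from the CASRNs (universal chemical
identities, not experimental data).  Twelve parents and eight metabolites
carry IMS-MS reference values: m/z recorded to two decimals and collision
cross section (CCS, Å²), plus the parent→metabolite biotransformation edges
used for attribution (diethylthiophosphate ← diazinon, chlorpyrifos,
ethion; diethyldithiophosphate ← ethion; both aminonitrophenols ←
2,4-dinitrophenol; etc.).

Monoisotopic masses are element-wise sums of IUPAC monoisotopic constants
(≥5 decimals), so any residual against the 2-decimal library values is
attributable to rounding of the recorded values.  The electrospray adduct
space is fixed to the four singly charged forms observed in this kind of
screen — M+H, M−H, M+Na, M+NH4 — with electron-mass-corrected shifts
(proton 1.007276 Da).  Adduct inference picks the candidate with the
smallest |theoretical − recorded| residual; exact ties (which do not occur
in the packaged registry) would be broken in the order M+H, M−H, M+Na,
M+NH4.  Two entries deserve note:

* **Aldrin** (recorded 361.88) equals its neutral monoisotopic mass
  (361.8757); no supported adduct lies within 0.02 Da.  This is consistent
  with a radical ion from photo-ionization, but since the ionization form is
  not recorded the entry is kept `ambiguous` rather than guessed.
* **DDA-p,p′** (recorded 278.98) sits 0.019 Da below the theoretical M−H
  (278.9985) — inside the 0.02 Da window but well beyond 2-decimal rounding
  error (±0.005).  The recorded value is kept as library truth and the
  residual is retained on the assignment.

The library file format is UTF-8 TSV (`name, casrn, role, formula, mz, ccs,
adduct, parents`); `load_library()`/`save_library()` round-trip it.  The
structural invariants (unique names, resolvable parent references, positive
m/z/CCS, metabolites must name parents) hold for any library; the
12-parent/8-metabolite detectability count is additionally enforced when
loading the packaged default, since user-supplied libraries may legitimately
be smaller.

## Synthetic study design

The generator encodes the three culture formats as `ModelDesign` values:

| format       | timepoints (min)  | volume (µL) | cells  | control          |
|--------------|-------------------|-------------|--------|------------------|
| suspension   | 0, 60, 120, 240   | 1000        | 5×10⁵  | heat-inactivated |
| sandwich     | 0, 2880           | 100         | 1×10⁵  | cell-free        |
| organoplate  | 0, 2880           | 100         | 2×10⁴  | cell-free        |

Triplicate wells throughout.  The suspension volume (1 mL: 500 µL cell stock
+ 500 µL chemical spike) and the microfluidic device's cell number
(2.5 µL of gel at 8×10⁶ cells/mL → 2×10⁴ hepatocytes, 50 µL media at inlet
and outlet) follow the seeding arithmetic of the protocols being emulated;
both are overridable.  The device's control type is not fixed by protocol;
cell-free is the default.

**Noise** is multiplicative lognormal with mean 1 at a configured CV
(default 10%): concentrations are positive and MS responses are
heteroscedastic, which an additive Gaussian would misrepresent.  **Abiotic
loss** is a single shared exponential applied to treated and control wells
alike; its default gives 10% loss over the longest interval of the design.
**LOQ censoring** records values below the limit of quantitation (default
0.01 µM) *at* the LOQ with a flag (substitution documented, not silent).
All randomness is seed-scoped per operation; no global state is touched.

The default scenario (`paper_like_scenario`) assigns five designated
fast-clearing compounds — 2,4-dinitrophenol, azinphos-methyl, disulfoton,
chlorpyrifos, ethion — true suspension clearances drawn in 6–13 µL/min/10⁶
cells (inside the 5–14 band the screen is meant to resolve) and every other
compound below 1.  In the 48-h batch formats *all* compounds sit below
1 µL/min/10⁶ cells (fast five 0.3–0.9, others 0.05–0.35): slow clearance in
monolayer/microfluidic formats is the behavior being emulated, and larger
rates would also deplete a 48-h interval below the LOQ and leave nothing to
fit.  The 5 µM arm multiplies true rates by 0.6 to emulate reduced metabolic
capacity at the higher exposure and is flagged "interpret with caution" in
reports; no viability correction is applied.

Feature tables place parent peaks with abundance proportional to remaining
concentration (one global response factor, 10⁵ counts/µM — ratios, not
absolute counts, carry the information) and metabolite peaks proportional to
yield × cumulative metabolic parent loss, estimated from the
treated-to-control concentration ratio so that an uncleared parent forms no
metabolite even under abiotic loss.  Metabolite abundance is therefore
non-decreasing in time while the parent depletes.  Default yields: 2A4NP
0.5 from 2,4-DNP; oxon 0.4 from azinphos-methyl; sulfone 0.45 from
disulfoton; diethylthiophosphate 0.4/0.3/0.35 from chlorpyrifos, diazinon,
ethion; diethyldithiophosphate 0.25 from ethion — five metabolites, one fed
by three parents.  Metabolite feature abundances are derived from
replicate-mean concentrations, so they carry between-timepoint but not
between-replicate noise.  m/z is jittered N(lib, 0.005 Da) and CCS
N(lib, 0.3%) by default — the mass-accuracy (≈5–15 ppm) and drift-tube CCS
reproducibility (≈0.3% RSD) a QTOF-class instrument actually delivers, and
comfortably inside the matching windows so that window dropout is a rare
tail event rather than a routine one.  Decoys are uniform over the observed
windows, rejected within 3× the matching tolerances of any library entry.
**Validation mode** truncates the jitter at ±2 SD and emits a
`truth_label`; run with SDs at half the matching tolerances (0.01 Da, 0.5%)
the truncation coincides exactly with the windows, making "every true
feature matches something" a structural guarantee.  Identity-level accuracy
is a separate question because
the two aminonitrophenols share m/z 153.03 and differ by only 1.14% in CCS,
so occasional swaps between them are possible by construction (both resolve
to the same parent, leaving the mass balance unaffected).

What the generator does **not** emulate: saturable (Michaelis–Menten)
kinetics, protein binding, viability decline over the incubation,
chromatographic or drift-time structure (drift time is a fixed linear proxy
of CCS), response-factor differences between compounds, isotope patterns,
and in-source fragmentation.  Passing tests therefore demonstrate that the
estimators recover the truth of *this* data-generating process at realistic
noise, not that they are robust to those unmodeled effects in real data.

## Clearance estimation

For each compound and format, the fit regresses
ln(C_treated,it / C̄_control,t) on time, pooled across replicates, with the
intercept free (absorbing recovery/matrix offsets) and censored observations
excluded — substituting censored values at the LOQ would bias k, so they are
dropped.  k = −slope.  Pooling replicates in one regression (rather than
fitting per replicate and averaging) was chosen for stability at n = 3.

The reported standard error is the OLS slope error **augmented by the
delta-method variance of the log control means**: the normalizer
ln C̄_control,t is itself estimated from replicates and is shared by every
treated observation at that timepoint, a variance component plain OLS treats
as fixed.  For balanced designs this roughly multiplies the se by √2;
empirically it restores calibrated coverage (≈98–99% of true rates within
k̂ ± 3·se across slow/medium/fast kinetics at CV 10%), where the naive se
undercovers.  With only two distinct timepoints the se is undefined (no
residual degrees of freedom) and reported as NaN; censoring then falls back
to the sign of k.

Censoring: a fit with k ≤ 0 or k < z·se (z = 1.645, one-sided 5%) is
reported as zero clearance with `censored = True`; the raw k and se are
always retained.  Units are asserted throughout: k min⁻¹, V µL, N cells,
Cl_in_vitro µL/min/10⁶ cells, Cl_int mL/min (1 µL/min/10⁶ cells →
137 × 1820 / 1000 = 249.34 mL/min).

## Nontargeted screening

Matching is a joint two-dimensional window: |Δm/z| ≤ 0.02 Da (the precision
of the recorded library values) and |ΔCCS| ≤ 1% (typical drift-tube
reproducibility), both configurable.  Among multiple in-window candidates
the minimum of `|Δm/z|/mz_tol + |ΔCCS%|/ccs_tol` wins — a normalized
combined score, since nothing in the recorded values privileges one
dimension.  Each feature is assigned at most once; unmatched features pass
through labeled `unknown`.  Matching is tolerance-monotone: widening either
window never un-matches a feature.

Percent remaining is 100 × treated/control on replicate-averaged abundances
(ratio of averages, not average of ratios); values above 100 are legal
(noise) and flagged.  Mass-balance aggregation (`replicate_mean_abundance`)
sums matched abundance within each replicate and divides by the number of
replicate samples in the condition, so a replicate in which a compound went
unmatched contributes zero instead of being silently dropped — this keeps
per-parent metabolite totals conserved when the two CCS-adjacent
aminonitrophenol isomers swap identities in a single replicate.  Metabolite detection requires a match above a minimum
abundance at ≥1 timepoint and, by default, the abundance maximum at the
final timepoint (time-dependent formation).

Mass balance decomposes each parent's control-referenced signal into
parent_pct + Σ metabolite_pct + other_pct = 100.  Abundances are used
without response-factor correction, so this is an abundance balance, not a
molar balance — a documented limitation, not an approximation error.
Multi-parent metabolites are attributed by rule: `equal_split` (default —
one stacked bar per parent requires a disjoint split), `full_to_each`
(double-counts by design; closure intentionally not guaranteed), or `joint`
(kept out of per-parent attribution, reported once for the parent group).
`other` is floored at zero with a `ClosureWarning` if the named components
overshoot 100%.

## Concordance and pipeline

Spearman ρ is the Pearson correlation of midrank vectors (average ranks for
ties), with rank 1 = highest clearance.  The two-sided p-value is exact
(enumeration of all n! permutations) for n ≤ 8 and the t-approximation
t = ρ√((n−2)/(1−ρ²)) otherwise.  "Targeted" clearance is fitted on
concentrations; "nontargeted" clearance re-runs the same depletion fit on
matched feature abundances of the 12 detectable parents — the package's
operationalization of comparing quantitation routes, since abundance ratios
estimate concentration ratios under a constant response factor.

`run_pipeline` is a pure function of (config, seed): scenario seeds are
drawn from one generator, the feature-table seed is derived as seed+1, and
CSVs are written with a fixed float format, so identical inputs give
byte-identical outputs.  It writes seven artifacts (timecourse, clearance,
assignments, detections, mass_balance, concordance, model_comparison) plus a
manifest with the config hash and library versions.

## Problem sizes

The test suite and acceptance script use 100 seeded studies for rate
recovery (3 rate regimes × 100 = 300 fits), 1,000 random instances for the
Spearman oracle check, 20-compound scenarios for end-to-end runs, and 25
decoy species for matching validation — sizes at which the binomial noise of
the checked proportions is well below the asserted margins while the whole
suite stays fast on a single CPU.

## Known limitations

* First-order kinetics only; no Michaelis–Menten or biphasic depletion, no
  plasma-protein-binding correction, no hepatic blood-flow (well-stirred /
  parallel-tube) models.
* Abundance-based mass balance inherits unknown response factors; percentages
  are comparable within a compound over time, not across compounds.
* The censoring rule (z = 1.645) is a reporting convention, not a hypothesis
  test with multiplicity control.
* CCS values are taken as given; no prediction from structure, no drift-time
  calibration.
* logP is an optional registry field, unused by the estimators.
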