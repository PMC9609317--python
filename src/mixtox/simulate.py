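"""Synthetic concentration–time and IMS-MS feature tables.

Emulates the three hepatocyte culture formats used for mixture clearance:

* ``suspension`` — cells in suspension, media sampled at 0/60/120/240 min,
  heat-inactivated-cell negative controls;
* ``sandwich`` — 2D collagen sandwich culture, single 48-h exposure interval,
  cell-free controls;
* ``organoplate`` — microfluidic co-culture device, single 48-h exposure
  interval, cell-free controls.

Treated wells deplete each parent compound with first-order kinetics on top
of a shared abiotic loss; controls see the abiotic loss only.  Measurement
noise is multiplicative lognormal at a configured CV, and concentrations
below the limit of quantitation are recorded at the LOQ with a censoring
flag.  Feature tables place jittered (m/z, CCS) peaks for remaining parents
and accumulating metabolites among uniform decoys.

All generation is seed-scoped: every operation takes or carries its own seed
and never touches global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chem import ReferenceLibrary

__all__ = [
    "ModelDesign",
    "suspension_design",
    "sandwich_design",
    "organoplate_design",
    "simulate_depletion",
    "simulate_feature_table",
    "paper_like_scenario",
    "Scenario",
    "FAST_COMPOUNDS",
    "DEFAULT_YIELDS",
    "RESPONSE_FACTOR",
]

#: Suspension compounds given appreciable clearance in the default scenario.
FAST_COMPOUNDS = (
    "2,4-Dinitrophenol",
    "Azinphos-methyl",
    "Disulfoton",
    "Chlorpyrifos",
    "Ethion",
)

#: Fractional metabolite yields (parent -> metabolite -> yield) used by the
#: default scenario; five metabolites, diethylthiophosphate fed by three parents.
DEFAULT_YIELDS: Mapping[str, Mapping[str, float]] = {
    "2,4-Dinitrophenol": {"2-Amino-4-nitrophenol": 0.5},
    "Azinphos-methyl": {"Azinphos-methyl oxon": 0.4},
    "Disulfoton": {"Disulfoton sulfone": 0.45},
    "Chlorpyrifos": {"Diethylthiophosphate": 0.4},
    "Diazinon": {"Diethylthiophosphate": 0.3},
    "Ethion": {"Diethylthiophosphate": 0.35, "Diethyldithiophosphate": 0.25},
}

#: Instrument response, counts per µM; one global constant keeps abundance
#: ratios interpretable as concentration ratios.
RESPONSE_FACTOR = 1.0e5


def _default_abiotic_rate(timepoints: tuple[float, ...]) -> float:
    """Abiotic loss rate giving 10% loss over the longest interval."""
    t_max = max(timepoints)
    return -math.log(0.9) / t_max if t_max > 0 else 0.0


@dataclass
class ModelDesign:
    """Experimental design of one culture format.

    Volumes are µL, times minutes, concentrations µM.  ``cv`` is the
    fractional coefficient of variation of the multiplicative measurement
    noise; ``loq`` the limit of quantitation below which measurements are
    censored.
    """

    model: str
    timepoints: tuple[float, ...]
    replicates: int = 3
    volume: float = 1000.0
    cells: float = 5e5
    control_kind: str = "heat_inactivated"
    abiotic_loss_rate: Optional[float] = None
    cv: float = 0.1
    loq: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("suspension", "sandwich", "organoplate"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.control_kind not in ("heat_inactivated", "cell_free"):
            raise ValueError(f"unknown control kind {self.control_kind!r}")
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        self.timepoints = tp
        if self.volume <= 0 or self.cells <= 0 or self.replicates < 1:
            raise ValueError("volume, cells and replicates must be positive")
        if not 0 <= self.cv < 1:
            raise ValueError(f"cv must be in [0, 1), got {self.cv}")
        if self.loq < 0:
            raise ValueError("loq must be non-negative")
        if self.abiotic_loss_rate is None:
            self.abiotic_loss_rate = _default_abiotic_rate(self.timepoints)
        if self.abiotic_loss_rate < 0:
            raise ValueError("abiotic loss rate must be non-negative")


def suspension_design(**overrides) -> ModelDesign:
    """Suspension assay: 1 mL, 5x10^5 cells, sampled at 0/60/120/240 min."""
    base = dict(
        model="suspension",
        timepoints=(0.0, 60.0, 120.0, 240.0),
        volume=1000.0,
        cells=5e5,
        control_kind="heat_inactivated",
    )
    base.update(overrides)
    return ModelDesign(**base)


def sandwich_design(**overrides) -> ModelDesign:
    """2D sandwich culture: 100 µL, 1x10^5 cells/well, one 48-h interval."""
    base = dict(
        model="sandwich",
        timepoints=(0.0, 2880.0),
        volume=100.0,
        cells=1e5,
        control_kind="cell_free",
    )
    base.update(overrides)
    return ModelDesign(**base)


def organoplate_design(**overrides) -> ModelDesign:
    """Microfluidic co-culture: 100 µL total media (50 µL inlet + 50 µL
    outlet), 2x10^4 hepatocytes per device (2.5 µL gel at 8x10^6 cells/mL),
    one 48-h interval."""
    base = dict(
        model="organoplate",
        timepoints=(0.0, 2880.0),
        volume=100.0,
        cells=2e4,
        control_kind="cell_free",
    )
    base.update(overrides)
    return ModelDesign(**base)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise at fractional CV."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_depletion(
    design: ModelDesign,
    true_k: Mapping[str, float],
    c0: float | Mapping[str, float],
) -> pd.DataFrame:
    """Simulate a concentration–time table for one culture format.

    Treated wells follow ``c0 * exp(-(k + abiotic) * t)``, controls
    ``c0 * exp(-abiotic * t)``; both receive mean-one lognormal noise at the
    design CV and LOQ censoring.  Deterministic for a given ``design.seed``.

    Returns a tidy table with columns compound, model, condition, replicate,
    time_min, concentration_um, censored.
    """
    for compound, k in true_k.items():
        if k < 0:
            raise ValueError(f"negative elimination rate for {compound}: {k}")
    c0_map = {c: float(c0) for c in true_k} if np.isscalar(c0) else dict(c0)
    for compound, value in c0_map.items():
        if value <= 0:
            raise ValueError(f"non-positive initial concentration for {compound}: {value}")
    rng = np.random.default_rng(design.seed)
    a = design.abiotic_loss_rate
    times = np.asarray(design.timepoints)
    records = []
    for compound in true_k:  # insertion order: deterministic
        k = true_k[compound]
        c_init = c0_map[compound]
        for condition, rate in (("treated", k + a), ("control", a)):
            mean = c_init * np.exp(-rate * times)
            for rep in range(1, design.replicates + 1):
                noisy = mean * _lognormal_factors(rng, design.cv, len(times))
                for t, c in zip(times, noisy):
                    censored = c < design.loq
                    records.append(
                        (
                            compound,
                            design.model,
                            condition,
                            rep,
                            t,
                            design.loq if censored else c,
                            censored,
                        )
                    )
    return pd.DataFrame(
        records,
        columns=[
            "compound",
            "model",
            "condition",
            "replicate",
            "time_min",
            "concentration_um",
            "censored",
        ],
    )


def _metabolic_loss(timecourse: pd.DataFrame, parent: str) -> pd.Series:
    """Per-time metabolically lost concentration (µM) for one parent.

    Estimated from the data as ``c0 * (1 - mean_treated/mean_control)`` so a
    parent with zero clearance forms no metabolite even under abiotic loss.
    Clipped at zero against noise.
    """
    sub = timecourse[timecourse["compound"] == parent]
    means = sub.groupby(["condition", "time_min"])["concentration_um"].mean()
    treated = means.loc["treated"]
    control = means.loc["control"]
    c0 = control.loc[0.0]
    ratio = (treated / control).clip(upper=1.0)
    return c0 * (1.0 - ratio)


def simulate_feature_table(
    timecourse: pd.DataFrame,
    library: ReferenceLibrary,
    metabolite_yields: Mapping[str, Mapping[str, float]],
    mz_sd: float = 0.005,
    ccs_sd_pct: float = 0.3,
    n_decoys: int = 20,
    seed: int = 0,
    validation: bool = False,
    decoy_exclusion_mz: float = 0.06,
    decoy_exclusion_ccs_pct: float = 3.0,
) -> pd.DataFrame:
    """Simulate an IMS-MS feature table from a concentration–time table.

    Parent features carry abundance proportional to the remaining parent
    concentration in each well; metabolite features accumulate as
    ``yield x cumulative metabolic parent loss`` summed over contributing
    parents, so they are non-decreasing in time whenever the parent is being
    cleared.  m/z is jittered N(library m/z, ``mz_sd``) and CCS
    N(library CCS, ``ccs_sd_pct`` % of the value); in ``validation`` mode the
    jitter is truncated at ±2 SD and a ``truth_label`` column is emitted.
    ``n_decoys`` decoy species are drawn uniformly over the observed m/z and
    CCS ranges, rejected while they fall within the exclusion window of any
    library entry.

    Columns: sample_id, condition, replicate, time_min, mz, ccs,
    drift_time_ms, abundance (+ truth_label in validation mode).
    """
    for parent, yields in metabolite_yields.items():
        if any(not 0 <= y <= 1 for y in yields.values()):
            raise ValueError(f"{parent}: yields must lie in [0, 1]")
        if sum(yields.values()) > 1.0 + 1e-12:
            raise ValueError(f"{parent}: total metabolite yield exceeds 1")
        for met in yields:
            if parent not in library.parents_of(met):
                raise ValueError(f"{met} is not a registered metabolite of {parent}")
    rng = np.random.default_rng(seed)
    model = timecourse["model"].iloc[0]
    compounds = set(timecourse["compound"].unique())
    detectable_parents = [e for e in library.detectable("parent") if e.name in compounds]

    loss = {p: _metabolic_loss(timecourse, p) for p in metabolite_yields if p in compounds}

    def jitter(mz0: float, ccs0: float) -> tuple[float, float]:
        ccs_sd = ccs0 * ccs_sd_pct / 100.0
        if validation:  # truncated jitter: feature stays within ±2 SD of truth
            dm = _truncnorm(rng, mz_sd, 2.0)
            dc = _truncnorm(rng, ccs_sd, 2.0)
        else:
            dm = rng.normal(0.0, mz_sd) if mz_sd > 0 else 0.0
            dc = rng.normal(0.0, ccs_sd) if ccs_sd > 0 else 0.0
        return mz0 + dm, ccs0 + dc

    rows = []

    def emit(sample_id, condition, rep, t, entry, abundance):
        if abundance <= 0:
            return
        mz, ccs = jitter(entry.library_mz, entry.library_ccs)
        rows.append((sample_id, condition, rep, t, mz, ccs, 0.1 * ccs, abundance, entry.name))

    treated = timecourse[timecourse["condition"] == "treated"]
    control = timecourse[timecourse["condition"] == "control"]
    for condition, sub in (("treated", treated), ("control", control)):
        for rep, rep_rows in sub.groupby("replicate"):
            sample_id = f"{model}_{condition}_r{rep}"
            conc = rep_rows.set_index(["compound", "time_min"])["concentration_um"]
            for t in sorted(rep_rows["time_min"].unique()):
                for entry in detectable_parents:
                    emit(sample_id, condition, rep, t, entry, RESPONSE_FACTOR * conc.get((entry.name, t), 0.0))
                if condition == "treated":  # no metabolism in dead-cell / cell-free controls
                    met_amount: dict[str, float] = {}
                    for parent, yields in metabolite_yields.items():
                        if parent not in loss:
                            continue
                        lost = float(loss[parent].get(t, 0.0))
                        for met, y in yields.items():
                            met_amount[met] = met_amount.get(met, 0.0) + y * lost
                    for met, amount in met_amount.items():
                        entry = library.get(met)
                        if entry.library_mz is None:
                            continue
                        emit(sample_id, condition, rep, t, entry, RESPONSE_FACTOR * amount)

    frame = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "condition",
            "replicate",
            "time_min",
            "mz",
            "ccs",
            "drift_time_ms",
            "abundance",
            "truth_label",
        ],
    )

    # Decoy species: uniform over the observed windows, kept clear of every
    # library entry by the exclusion window in both dimensions jointly.
    if n_decoys > 0 and not frame.empty:
        lib_entries = library.detectable()
        mz_lo, mz_hi = frame["mz"].min(), frame["mz"].max()
        ccs_lo, ccs_hi = frame["ccs"].min(), frame["ccs"].max()
        ab_lo, ab_hi = frame["abundance"].min(), frame["abundance"].max()
        decoys = []
        while len(decoys) < n_decoys:
            mz = rng.uniform(mz_lo, mz_hi)
            ccs = rng.uniform(ccs_lo, ccs_hi)
            near = any(
                abs(mz - e.library_mz) <= decoy_exclusion_mz
                and abs(ccs - e.library_ccs) / e.library_ccs * 100.0 <= decoy_exclusion_ccs_pct
                for e in lib_entries
            )
            if not near:
                decoys.append((mz, ccs))
        decoy_rows = []
        for sample_id, sample in frame.groupby("sample_id", sort=True):
            condition = sample["condition"].iloc[0]
            rep = sample["replicate"].iloc[0]
            for t in sorted(sample["time_min"].unique()):
                for mz, ccs in decoys:
                    decoy_rows.append(
                        (
                            sample_id,
                            condition,
                            rep,
                            t,
                            mz,
                            ccs,
                            0.1 * ccs,
                            rng.uniform(ab_lo, ab_hi),
                            "decoy",
                        )
                    )
        frame = pd.concat([frame, pd.DataFrame(decoy_rows, columns=frame.columns)], ignore_index=True)

    if not validation:
        frame = frame.drop(columns=["truth_label"])
    return frame.reset_index(drop=True)


def _truncnorm(rng: np.random.Generator, sd: float, n_sd: float) -> float:
    """One draw of N(0, sd) truncated at ±n_sd * sd (rejection sampling)."""
    if sd == 0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= n_sd * sd:
            return x


@dataclass
class Scenario:
    """A complete simulated study: per-model designs and true parameters."""

    mixture_level_um: float
    designs: dict[str, ModelDesign]
    true_k: dict[str, dict[str, float]]  # model -> compound -> per-minute rate
    metabolite_yields: Mapping[str, Mapping[str, float]] = field(default_factory=lambda: DEFAULT_YIELDS)
    seed: int = 0

    def true_cl_in_vitro(self, model: str) -> dict[str, float]:
        """Ground-truth in vitro clearance (µL/min/10^6 cells) per compound."""
        d = self.designs[model]
        return {c: k * d.volume / (d.cells / 1e6) for c, k in self.true_k[model].items()}


def paper_like_scenario(mixture_level: str = "1uM", seed: int = 0) -> Scenario:
    """Default study conditions across the three culture formats.

    Five designated suspension-cleared compounds (2,4-dinitrophenol,
    azinphos-methyl, disulfoton, chlorpyrifos, ethion) get first-order rates
    placing their true suspension clearance in 5–14 µL/min/10^6 cells; every
    other compound sits below 1.  In the 48-h batch formats every compound
    clears below 1 µL/min/10^6 cells (all-compound slow clearance in the
    monolayer and microfluidic formats), keeping 48-h depletion above the
    limit of quantitation.  The 5 µM arm scales rates by 0.6 to emulate
    reduced metabolic capacity at the higher exposure.
    """
    if mixture_level not in ("1uM", "5uM"):
        raise ValueError(f"mixture level must be '1uM' or '5uM', got {mixture_level!r}")
    level = 1.0 if mixture_level == "1uM" else 5.0
    rng = np.random.default_rng(seed)
    from .chem import load_library

    library = load_library()
    all_parents = [e.name for e in library.parents]
    slow = [p for p in all_parents if p not in FAST_COMPOUNDS]

    designs = {
        "suspension": suspension_design(seed=int(rng.integers(2**31))),
        "sandwich": sandwich_design(seed=int(rng.integers(2**31))),
        "organoplate": organoplate_design(seed=int(rng.integers(2**31))),
    }

    capacity = 1.0 if level == 1.0 else 0.6

    def k_from_cl(cl: float, design: ModelDesign) -> float:
        return cl * (design.cells / 1e6) / design.volume

    true_k: dict[str, dict[str, float]] = {}
    d = designs["suspension"]
    fast_cl = rng.uniform(6.0, 13.0, size=len(FAST_COMPOUNDS))
    slow_cl = rng.uniform(0.1, 0.8, size=len(slow))
    true_k["suspension"] = {
        **{c: k_from_cl(cl * capacity, d) for c, cl in zip(FAST_COMPOUNDS, fast_cl)},
        **{c: k_from_cl(cl * capacity, d) for c, cl in zip(slow, slow_cl)},
    }
    for model in ("sandwich", "organoplate"):
        d = designs[model]
        fast_cl = rng.uniform(0.3, 0.9, size=len(FAST_COMPOUNDS))
        slow_cl = rng.uniform(0.05, 0.35, size=len(slow))
        true_k[model] = {
            **{c: k_from_cl(cl * capacity, d) for c, cl in zip(FAST_COMPOUNDS, fast_cl)},
            **{c: k_from_cl(cl * capacity, d) for c, cl in zip(slow, slow_cl)},
        }
    return Scenario(
        mixture_level_um=level,
        designs=designs,
        true_k=true_k,
        metabolite_yields=DEFAULT_YIELDS,
        seed=seed,
    )
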