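"""First-order clearance estimation and whole-liver IVIVE scaling.

The elimination rate constant k (per minute) is estimated by the substrate
depletion approach: ordinary least squares of log control-normalized treated
concentration against time.  Normalizing each treated measurement by the
mean control concentration at the same timepoint cancels any loss shared
between treated wells and the heat-inactivated / cell-free controls (abiotic
degradation, binding to plasticware), leaving the metabolic component.

In vitro clearance follows Cl_in_vitro = k V / N (µL/min per 10^6 cells) and
scales to whole-liver intrinsic clearance as

    Cl_int = Cl_in_vitro x HPGL x V_l

with HPGL = 137 x 10^6 hepatocytes per gram liver and V_l = 1820 g,
reported in mL/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScalingConstants",
    "ClearanceResult",
    "InsufficientDataError",
    "AllCensoredError",
    "fit_elimination_rate",
    "two_point_rate",
    "cl_in_vitro",
    "cl_int",
    "censor_clearance",
    "clearance_table",
    "merge_comparison",
]

# Unit convention, asserted throughout: k per minute, V in µL, N in cells,
# Cl_in_vitro in µL/min/10^6 cells, Cl_int in mL/min whole liver.


class InsufficientDataError(ValueError):
    """Fewer than two usable (uncensored) distinct timepoints."""


class AllCensoredError(ValueError):
    """Every treated observation fell below the limit of quantitation."""


@dataclass(frozen=True)
class ScalingConstants:
    """Whole-liver scaling factors.

    ``hpgl`` is hepatocellularity in 10^6 cells per gram liver; ``liver_mass``
    the whole-liver mass in grams.
    """

    hpgl: float = 137.0
    liver_mass: float = 1820.0

    def __post_init__(self) -> None:
        if self.hpgl <= 0 or self.liver_mass <= 0:
            raise ValueError("scaling constants must be strictly positive")


@dataclass
class ClearanceResult:
    """Fitted clearance for one compound in one culture format.

    ``censored`` marks depletion not distinguishable from zero; the raw
    fitted ``k`` (and its standard error) is retained in all cases, while
    ``cl_in_vitro``/``cl_int`` are reported as 0 for censored results.
    """

    compound: str
    model: str
    k: float
    k_se: float
    cl_in_vitro: float
    cl_int: float
    censored: bool
    n_points: int


def fit_elimination_rate(timecourse: pd.DataFrame) -> tuple[float, float]:
    """Fit k (per minute) for one compound/model by log-linear regression.

    ``timecourse`` holds the rows of a single compound and model with columns
    condition, replicate, time_min, concentration_um, censored.  The response
    is ln(C_treated / mean C_control at the same timepoint), pooled across
    replicates, with censored observations excluded; k = -slope with the
    intercept left free.  Returns (k, standard error).

    The reported standard error is the OLS slope error augmented by the
    delta-method variance of the log control means: the control normalizer
    is itself estimated from replicates and is shared by every treated
    observation at the same timepoint, a variance component plain OLS treats
    as fixed (and hence underestimates).
    """
    treated = timecourse[timecourse["condition"] == "treated"]
    control = timecourse[timecourse["condition"] == "control"]
    if treated.empty or control.empty:
        raise InsufficientDataError("need both treated and control rows")
    if treated["censored"].all():
        raise AllCensoredError("all treated observations censored (below LOQ)")
    control_ok = control[~control["censored"]]
    control_mean = control_ok.groupby("time_min")["concentration_um"].mean()
    usable = treated[~treated["censored"]].copy()
    usable = usable[usable["time_min"].isin(control_mean.index)]
    if usable["time_min"].nunique() < 2:
        raise InsufficientDataError(
            f"need >=2 distinct usable timepoints, have {usable['time_min'].nunique()}"
        )
    y = np.log(usable["concentration_um"].to_numpy() / control_mean.loc[usable["time_min"]].to_numpy())
    t = usable["time_min"].to_numpy()
    fit = stats.linregress(t, y)
    if len(t) <= 2:
        return -float(fit.slope), float("nan")

    # control-normalizer variance: Var(ln mean control at t) ~ var(ln C)/n_t,
    # shared across all treated points at t, so it propagates to the slope as
    # (sum of that timepoint's slope weights)^2 * variance.
    sxx = float(((t - t.mean()) ** 2).sum())
    log_control = control_ok.assign(log_c=np.log(control_ok["concentration_um"]))
    per_time_var = log_control.groupby("time_min")["log_c"].var(ddof=1)
    per_time_n = log_control.groupby("time_min")["log_c"].count()
    pooled_var = float(per_time_var.dropna().mean()) if per_time_var.notna().any() else 0.0
    var_control = 0.0
    for tp, m_t in zip(*np.unique(t, return_counts=True)):
        v = per_time_var.get(tp)
        v = pooled_var if (v is None or np.isnan(v)) else float(v)
        weight = m_t * (tp - t.mean()) / sxx
        var_control += weight**2 * v / float(per_time_n.get(tp, 1))
    se = math.sqrt(float(fit.stderr) ** 2 + var_control)
    return -float(fit.slope), se


def two_point_rate(c_treated: float, c_control: float, interval: float) -> float:
    """k (per minute) from a single exposure interval (e.g. the 48-h batch
    formats): k = ln(c_control / c_treated) / interval.

    Negative results (treated above control) pass through; censoring is
    decided downstream.
    """
    if c_treated <= 0 or c_control <= 0:
        raise ValueError("concentrations must be positive")
    if interval <= 0:
        raise ValueError("interval must be positive")
    return math.log(c_control / c_treated) / interval


def cl_in_vitro(k: float, volume: float, cells: float) -> float:
    """In vitro clearance, µL/min per 10^6 cells: k [1/min] x V [µL] / N [10^6 cells]."""
    if volume <= 0 or cells <= 0:
        raise ValueError("volume and cell number must be positive")
    return k * volume / (cells / 1e6)


def cl_int(cl_vitro: float, constants: ScalingConstants = ScalingConstants()) -> float:
    """Whole-liver intrinsic clearance in mL/min.

    Cl_in_vitro [µL/min/10^6 cells] x HPGL [10^6 cells/g] x liver mass [g],
    converted µL -> mL.
    """
    return cl_vitro * constants.hpgl * constants.liver_mass / 1000.0


def censor_clearance(
    compound: str,
    model: str,
    k: float,
    k_se: float,
    volume: float,
    cells: float,
    constants: ScalingConstants = ScalingConstants(),
    z: float = 1.645,
    n_points: int = 0,
) -> ClearanceResult:
    """Assemble a ClearanceResult, censoring depletion indistinguishable from 0.

    A fit is censored when k <= 0 or k < z * se (one-sided test at the level
    implied by ``z``; default 1.645 ~ 5%).  A non-finite standard error (two
    distinct timepoints with no residual degrees of freedom) censors on the
    sign of k only.
    """
    censored = k <= 0 or (math.isfinite(k_se) and k < z * k_se)
    cl_v = 0.0 if censored else cl_in_vitro(k, volume, cells)
    return ClearanceResult(
        compound=compound,
        model=model,
        k=k,
        k_se=k_se,
        cl_in_vitro=cl_v,
        cl_int=cl_int(cl_v, constants),
        censored=censored,
        n_points=n_points,
    )


def clearance_table(
    timecourse: pd.DataFrame,
    volume: float,
    cells: float,
    constants: ScalingConstants = ScalingConstants(),
    z: float = 1.645,
) -> pd.DataFrame:
    """Fit every compound in a single-model concentration–time table.

    Returns one row per compound: compound, model, k, se, cl_in_vitro,
    cl_int, censored, n_points.
    """
    models = timecourse["model"].unique()
    if len(models) != 1:
        raise ValueError(f"expected a single-model table, found {list(models)}")
    model = models[0]
    results = []
    for compound, sub in timecourse.groupby("compound", sort=True):
        n_points = int((~sub[sub["condition"] == "treated"]["censored"]).sum())
        k, se = fit_elimination_rate(sub)
        results.append(censor_clearance(compound, model, k, se, volume, cells, constants, z, n_points))
    return pd.DataFrame(
        [
            (r.compound, r.model, r.k, r.k_se, r.cl_in_vitro, r.cl_int, r.censored, r.n_points)
            for r in results
        ],
        columns=["compound", "model", "k", "se", "cl_in_vitro", "cl_int", "censored", "n_points"],
    )


def merge_comparison(
    clearance: pd.DataFrame, comparison: pd.DataFrame, column: str = "comparison"
) -> pd.DataFrame:
    """Merge an external clearance column (e.g. literature values) by compound.

    ``comparison`` needs columns ``compound`` and ``value``; compounds absent
    from it get a missing marker, never an imputed value.
    """
    if not {"compound", "value"}.issubset(comparison.columns):
        raise ValueError("comparison table needs 'compound' and 'value' columns")
    out = clearance.merge(
        comparison.rename(columns={"value": column})[["compound", column]],
        on="compound",
        how="left",
    )
    return out
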