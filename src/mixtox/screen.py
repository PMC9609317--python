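"""Nontargeted IMS-MS screening: feature matching, percent remaining,
metabolite detection, and abundance-based mass balance.

Features are matched against the reference library in two dimensions jointly:
an absolute m/z window (default ±0.02 Da, the precision at which library
values are recorded) and a relative CCS window (default ±1%, typical
drift-tube reproducibility).  Among multiple in-window candidates the one
with the smallest combined normalized error wins; each feature is assigned
to at most one compound and unmatched features pass through labeled
``unknown``.

Mass balance decomposes each parent's control-referenced signal into
remaining parent, detected metabolites, and unaccounted "other".  Abundances
are used without response-factor correction, so this is an abundance-based
(not molar) balance.  Metabolites that can arise from several parents are
attributed by a configurable rule: ``equal_split`` (default) divides the
percentage evenly among the registered parents, ``full_to_each`` counts it
fully under every parent (double-counting by design), and ``joint`` keeps it
out of the per-parent attribution and reports it once for the parent group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .chem import ReferenceLibrary

__all__ = [
    "MassBalanceReport",
    "ClosureWarning",
    "match_features",
    "percent_remaining",
    "percent_remaining_table",
    "replicate_mean_abundance",
    "detect_metabolites",
    "mass_balance",
    "ATTRIBUTION_RULES",
]

ATTRIBUTION_RULES = ("equal_split", "full_to_each", "joint")


class ClosureWarning(UserWarning):
    """Mass-balance components exceeded 100% and 'other' was floored at 0."""


def match_features(
    features: pd.DataFrame,
    library: ReferenceLibrary,
    mz_tol: float = 0.02,
    ccs_tol_pct: float = 1.0,
) -> pd.DataFrame:
    """Assign each feature to the best-matching library compound.

    A feature matches an entry iff |Δm/z| <= ``mz_tol`` AND
    |ΔCCS|/CCS_lib x 100 <= ``ccs_tol_pct``; the candidate minimizing
    ``|Δm/z|/mz_tol + |ΔCCS%|/ccs_tol_pct`` wins.  Returns the feature table
    with added columns compound ("unknown" when unmatched), mz_error,
    ccs_error_pct and score.
    """
    if mz_tol <= 0 or ccs_tol_pct <= 0:
        raise ValueError("tolerances must be positive")
    entries = library.detectable()
    if not entries:
        raise ValueError("library has no entries with m/z and CCS values")
    lib_mz = np.array([e.library_mz for e in entries])
    lib_ccs = np.array([e.library_ccs for e in entries])
    names = [e.name for e in entries]

    mz = features["mz"].to_numpy()[:, None]
    ccs = features["ccs"].to_numpy()[:, None]
    dmz = mz - lib_mz[None, :]
    dccs_pct = (ccs - lib_ccs[None, :]) / lib_ccs[None, :] * 100.0
    in_window = (np.abs(dmz) <= mz_tol) & (np.abs(dccs_pct) <= ccs_tol_pct)
    score = np.abs(dmz) / mz_tol + np.abs(dccs_pct) / ccs_tol_pct
    score = np.where(in_window, score, np.inf)
    best = np.argmin(score, axis=1)
    matched = np.isfinite(score[np.arange(len(features)), best])

    out = features.copy()
    out["compound"] = [names[j] if ok else "unknown" for j, ok in zip(best, matched)]
    out["mz_error"] = np.where(matched, dmz[np.arange(len(features)), best], np.nan)
    out["ccs_error_pct"] = np.where(matched, dccs_pct[np.arange(len(features)), best], np.nan)
    out["score"] = np.where(matched, score[np.arange(len(features)), best], np.nan)
    return out


def percent_remaining(abundance_treated: float, abundance_control: float) -> float:
    """Control-normalized percent remaining: 100 x treated/control.

    Values above 100 are permitted (measurement noise) — flag them at table
    level with :func:`percent_remaining_table`.
    """
    if abundance_control <= 0:
        raise ValueError(f"control abundance must be positive, got {abundance_control}")
    if abundance_treated < 0:
        raise ValueError(f"treated abundance must be non-negative, got {abundance_treated}")
    return 100.0 * abundance_treated / abundance_control


def percent_remaining_table(
    assignments: pd.DataFrame, time_min: Optional[float] = None
) -> pd.DataFrame:
    """Percent remaining per matched compound at one timepoint.

    Replicate abundances are averaged before the ratio (ratio of averages,
    not average of ratios).  ``time_min`` defaults to the latest timepoint.
    Rows: compound, time_min, abundance_treated, abundance_control,
    percent_remaining, above_100.
    """
    sub = assignments[assignments["compound"] != "unknown"]
    if time_min is None:
        time_min = sub["time_min"].max()
    sub = sub[sub["time_min"] == time_min]
    means = sub.groupby(["compound", "condition"])["abundance"].mean().unstack("condition")
    means = means.dropna(subset=["control"])
    rows = []
    for compound, row in means.iterrows():
        treated = row.get("treated", 0.0)
        treated = 0.0 if pd.isna(treated) else float(treated)
        pct = percent_remaining(treated, float(row["control"]))
        rows.append((compound, time_min, treated, float(row["control"]), pct, pct > 100.0))
    return pd.DataFrame(
        rows,
        columns=[
            "compound",
            "time_min",
            "abundance_treated",
            "abundance_control",
            "percent_remaining",
            "above_100",
        ],
    )


def replicate_mean_abundance(
    assignments: pd.DataFrame, time_min: Optional[float] = None
) -> pd.Series:
    """Matched abundance per (compound, condition) at one timepoint, averaged
    over replicates.

    Abundance is summed within each replicate and divided by the number of
    replicate samples in the condition, so a replicate in which a compound
    was not matched contributes zero rather than being silently dropped —
    the aggregation an honest ratio-of-averages requires.  ``time_min``
    defaults to the latest timepoint.
    """
    sub = assignments[assignments["compound"] != "unknown"]
    if time_min is None:
        time_min = sub["time_min"].max()
    sub = sub[sub["time_min"] == time_min]
    n_reps = sub.groupby("condition")["replicate"].nunique()
    sums = sub.groupby(["compound", "condition"])["abundance"].sum()
    denom = sums.index.get_level_values("condition").map(n_reps).to_numpy(dtype=float)
    return sums / denom


def detect_metabolites(
    assignments: pd.DataFrame,
    library: ReferenceLibrary,
    min_abundance: float = 0.0,
    require_increase: bool = True,
) -> pd.DataFrame:
    """Detect metabolites among matched treated features.

    A metabolite is detected iff it was matched at >=1 timepoint with mean
    treated abundance above ``min_abundance``; with ``require_increase`` its
    maximum abundance must additionally occur at the final timepoint
    (time-dependent formation).  Returns one row per detected metabolite:
    metabolite, first_detection_time_min, max_abundance, time_of_max,
    parents (semicolon-joined contributing parents from the library).
    """
    treated = assignments[
        (assignments["condition"] == "treated") & (assignments["compound"] != "unknown")
    ]
    if treated["time_min"].nunique() < 2:
        raise ValueError("need >=2 timepoints to assess metabolite formation")
    last_time = treated["time_min"].max()
    metabolite_names = {e.name for e in library.metabolites}
    rows = []
    for compound, sub in treated.groupby("compound", sort=True):
        if compound not in metabolite_names:
            continue
        by_time = sub.groupby("time_min")["abundance"].mean()
        above = by_time[by_time > min_abundance]
        if above.empty:
            continue
        t_max = by_time.idxmax()
        if require_increase and t_max != last_time:
            continue
        rows.append(
            (
                compound,
                float(above.index.min()),
                float(by_time.max()),
                float(t_max),
                ";".join(sorted(library.parents_of(compound))),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["metabolite", "first_detection_time_min", "max_abundance", "time_of_max", "parents"],
    )


@dataclass
class MassBalanceReport:
    """Parent/metabolite/other decomposition for one parent compound.

    All percentages are relative to the parent's control abundance.  Under
    ``equal_split`` and ``joint`` the components sum to 100 unless flooring
    fired (``floored``); ``full_to_each`` double-counts multi-parent
    metabolites by design and carries no closure guarantee.
    ``joint_unattributed`` holds multi-parent metabolite percentages kept out
    of the per-parent attribution under the ``joint`` rule.
    """

    parent: str
    parent_pct: float
    metabolite_pct: dict[str, float]
    other_pct: float
    attribution_rule: str
    floored: bool = False
    joint_unattributed: dict[str, float] = field(default_factory=dict)

    @property
    def total_pct(self) -> float:
        return self.parent_pct + sum(self.metabolite_pct.values()) + self.other_pct


def mass_balance(
    parent: str,
    parent_abundance: float,
    metabolite_abundances: Mapping[str, float],
    parent_abundance_control: float,
    library: ReferenceLibrary,
    rule: str = "equal_split",
) -> MassBalanceReport:
    """Decompose a parent's control-referenced abundance into parent,
    metabolites, and other.

    ``metabolite_abundances`` maps metabolite name to (treated) abundance at
    the timepoint of interest; each must be a registered metabolite of
    ``parent``.  ``other_pct`` closes the balance to 100 and is floored at 0
    with a :class:`ClosureWarning` if the named components overshoot.
    """
    if rule not in ATTRIBUTION_RULES:
        raise ValueError(f"unknown attribution rule {rule!r}")
    if parent_abundance_control <= 0:
        raise ValueError("parent control abundance must be positive")
    parent_pct = 100.0 * parent_abundance / parent_abundance_control

    attributed: dict[str, float] = {}
    joint_unattributed: dict[str, float] = {}
    for met, abundance in metabolite_abundances.items():
        parents = library.parents_of(met)
        if not parents:
            raise ValueError(f"{met} has no registered parent")
        if parent not in parents:
            raise ValueError(f"{met} is not a registered metabolite of {parent}")
        pct = 100.0 * abundance / parent_abundance_control
        if rule == "equal_split":
            attributed[met] = pct / len(parents)
        elif rule == "full_to_each":
            attributed[met] = pct
        else:  # joint
            if len(parents) == 1:
                attributed[met] = pct
            else:
                joint_unattributed[met] = pct

    other = 100.0 - parent_pct - sum(attributed.values())
    floored = other < 0
    if floored:
        warnings.warn(
            f"{parent}: mass-balance components exceed 100% "
            f"(parent {parent_pct:.1f}% + metabolites {sum(attributed.values()):.1f}%); "
            "'other' floored at 0",
            ClosureWarning,
            stacklevel=2,
        )
        other = 0.0
    return MassBalanceReport(
        parent=parent,
        parent_pct=parent_pct,
        metabolite_pct=attributed,
        other_pct=other,
        attribution_rule=rule,
        floored=floored,
        joint_unattributed=joint_unattributed,
    )
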