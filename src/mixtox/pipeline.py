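"""End-to-end pipeline: generate -> fit -> screen -> report.

Orchestrates the synthetic study, clearance estimation, nontargeted
screening, targeted-vs-nontargeted rank concordance and cross-model
comparison, writing every stage's table to an output directory together with
a run manifest.  The whole pipeline is a pure function of (config, seed):
identical inputs give byte-identical numeric outputs.

"Targeted" clearance is fitted on concentrations; "nontargeted" clearance is
fitted on matched IMS-MS feature abundances of the same compounds.  Their
agreement is summarized by Spearman rank correlation with rank 1 assigned to
the highest clearance.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .chem import load_library
from .kinetics import ScalingConstants, clearance_table
from .screen import detect_metabolites, mass_balance, match_features, replicate_mean_abundance
from .simulate import (
    FAST_COMPOUNDS,
    paper_like_scenario,
    simulate_depletion,
    simulate_feature_table,
)

__all__ = [
    "PipelineConfig",
    "ConcordanceResult",
    "spearman_rank",
    "compare_models",
    "run_pipeline",
]

logger = logging.getLogger("mixtox")


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    mixture_level: Literal["1uM", "5uM"] = "1uM"
    seed: int = 0
    library: str = "packaged"
    mz_tol: float = Field(default=0.02, gt=0)
    ccs_tol_pct: float = Field(default=1.0, gt=0)
    censor_z: float = Field(default=1.645, ge=0)
    attribution_rule: Literal["equal_split", "full_to_each", "joint"] = "equal_split"
    mz_sd: float = Field(default=0.005, ge=0)
    ccs_sd_pct: float = Field(default=0.3, ge=0)
    n_decoys: int = Field(default=20, ge=0)
    validation: bool = False
    outdir: str = "mixtox_out"


def _average_ranks(values: Sequence[float]) -> np.ndarray:
    """Average (midrank) ranks, 1-based; ties share the mean of their ranks."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return float("nan")
    return float(a @ b) / denom


@dataclass
class ConcordanceResult:
    """Spearman rank concordance between two orderings of the same compounds."""

    n: int
    rho: float
    p_value: float
    rank_table: pd.DataFrame


def spearman_rank(
    x: Sequence[float],
    y: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> ConcordanceResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors.  The two-sided
    p-value is computed by exact enumeration of all n! rank permutations for
    n <= 8 and by the t-approximation otherwise.  Ranks in the returned table
    follow the convention rank 1 = highest value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    rx = _average_ranks(x)
    ry = _average_ranks(y)
    rho = _pearson(rx, ry)

    if n <= 8:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            from scipy import stats as _st

            p = 2.0 * float(_st.t.sf(abs(t), df=n - 2))

    # rank 1 = highest value
    rank_hi_x = _average_ranks(-x)
    rank_hi_y = _average_ranks(-y)
    table = pd.DataFrame(
        {
            "compound": list(labels) if labels is not None else [f"item_{i}" for i in range(n)],
            "targeted_rank": rank_hi_x,
            "nontargeted_rank": rank_hi_y,
        }
    )
    return ConcordanceResult(n=n, rho=rho, p_value=p, rank_table=table)


def compare_models(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-to-wide comparison of clearance across culture formats.

    ``tables`` maps model name to a clearance table (columns compound,
    cl_in_vitro, censored).  Returns one row per compound with per-model
    clearance and censoring columns; compounds absent from a model keep
    missing markers, never imputed values.
    """
    if len(tables) < 2:
        raise ValueError("need at least two models to compare")
    pieces = []
    for model, table in tables.items():
        piece = table[["compound", "cl_in_vitro", "censored"]].copy()
        piece.columns = ["compound", f"cl_in_vitro_{model}", f"censored_{model}"]
        pieces.append(piece)
    out = pieces[0]
    for piece in pieces[1:]:
        out = out.merge(piece, on="compound", how="outer")
    value_cols = [c for c in out.columns if c.startswith("cl_in_vitro_")]
    shared = out[value_cols].notna().all(axis=1)
    if not shared.any():
        raise ValueError("no compound is shared by all models")
    return out.sort_values("compound").reset_index(drop=True)


def _abundance_timecourse(assignments: pd.DataFrame, compounds: Sequence[str]) -> pd.DataFrame:
    """Recast matched feature abundances as a concentration-like table so the
    depletion fit can run on nontargeted data."""
    sub = assignments[assignments["compound"].isin(compounds)]
    agg = (
        sub.groupby(["compound", "condition", "replicate", "time_min"], sort=True)["abundance"]
        .mean()
        .reset_index()
    )
    agg = agg.rename(columns={"abundance": "concentration_um"})
    agg["model"] = "suspension"
    agg["censored"] = False
    return agg


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write all artifacts under ``config.outdir``.

    Writes timecourse.csv, clearance.csv, assignments.csv, detections.csv,
    mass_balance.csv, concordance.csv, model_comparison.csv and
    manifest.json; returns the manifest as a dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = load_library(None if config.library == "packaged" else config.library)
    constants = ScalingConstants()

    logger.info("[scenario] mixture %s, seed %d", config.mixture_level, config.seed)
    scenario = paper_like_scenario(config.mixture_level, seed=config.seed)

    # --- simulate + fit ---------------------------------------------------
    timecourses: dict[str, pd.DataFrame] = {}
    clearances: dict[str, pd.DataFrame] = {}
    for model, design in scenario.designs.items():
        try:
            tc = simulate_depletion(design, scenario.true_k[model], scenario.mixture_level_um)
            timecourses[model] = tc
            ct = clearance_table(tc, design.volume, design.cells, constants, config.censor_z)
        except Exception as exc:
            raise RuntimeError(f"stage simulate/fit failed for model {model!r}: {exc}") from exc
        ct["flag"] = "interpret_with_caution" if config.mixture_level == "5uM" else ""
        clearances[model] = ct
        logger.info("[fit] %s: %d compounds fitted", model, len(ct))

    timecourse_all = pd.concat(timecourses.values(), ignore_index=True)
    clearance_all = pd.concat(clearances.values(), ignore_index=True)

    # --- nontargeted screen (suspension) ----------------------------------
    try:
        features = simulate_feature_table(
            timecourses["suspension"],
            library,
            scenario.metabolite_yields,
            mz_sd=config.mz_sd,
            ccs_sd_pct=config.ccs_sd_pct,
            n_decoys=config.n_decoys,
            seed=(config.seed + 1) % 2**31,
            validation=config.validation,
        )
        assignments = match_features(features, library, config.mz_tol, config.ccs_tol_pct)
    except Exception as exc:
        raise RuntimeError(f"stage screen failed: {exc}") from exc
    logger.info(
        "[screen] %d features, %d matched",
        len(assignments),
        int((assignments["compound"] != "unknown").sum()),
    )

    try:
        detections = detect_metabolites(assignments, library)
    except Exception as exc:
        raise RuntimeError(f"stage detect failed: {exc}") from exc
    logger.info("[detect] %d metabolites detected", len(detections))

    # --- mass balance for the designated cleared parents -------------------
    mean_ab = replicate_mean_abundance(assignments)
    metabolite_names = {e.name for e in library.metabolites}
    balance_rows = []
    for parent in FAST_COMPOUNDS:
        try:
            parent_treated = float(mean_ab.get((parent, "treated"), 0.0))
            parent_control = float(mean_ab.get((parent, "control"), np.nan))
            if not np.isfinite(parent_control):
                raise ValueError(f"no control abundance for {parent}")
            mets = {
                met: float(mean_ab.get((met, "treated"), 0.0))
                for met in sorted(metabolite_names)
                if parent in library.parents_of(met) and (met, "treated") in mean_ab.index
            }
            report = mass_balance(
                parent, parent_treated, mets, parent_control, library, config.attribution_rule
            )
        except Exception as exc:
            raise RuntimeError(f"stage balance failed for parent {parent!r}: {exc}") from exc
        balance_rows.append(
            {
                "parent": report.parent,
                "parent_pct": report.parent_pct,
                "metabolite_pct_total": sum(report.metabolite_pct.values()),
                "metabolites": ";".join(
                    f"{m}={v:.4f}" for m, v in sorted(report.metabolite_pct.items())
                ),
                "other_pct": report.other_pct,
                "attribution_rule": report.attribution_rule,
                "floored": report.floored,
            }
        )
    balance = pd.DataFrame(balance_rows)
    logger.info("[balance] %d parents decomposed", len(balance))

    # --- targeted vs nontargeted concordance -------------------------------
    detectable_parents = sorted(
        e.name for e in library.detectable("parent") if e.name in scenario.true_k["suspension"]
    )
    try:
        nt_tc = _abundance_timecourse(assignments, detectable_parents)
        d = scenario.designs["suspension"]
        nt_clearance = clearance_table(nt_tc, d.volume, d.cells, constants, config.censor_z)
        targeted = (
            clearances["suspension"]
            .set_index("compound")
            .loc[detectable_parents, "cl_in_vitro"]
        )
        nontargeted = nt_clearance.set_index("compound").loc[detectable_parents, "cl_in_vitro"]
        concordance = spearman_rank(
            targeted.to_numpy(), nontargeted.to_numpy(), labels=detectable_parents
        )
    except Exception as exc:
        raise RuntimeError(f"stage concordance failed: {exc}") from exc
    conc_table = concordance.rank_table.copy()
    conc_table["targeted_cl"] = targeted.to_numpy()
    conc_table["nontargeted_cl"] = nontargeted.to_numpy()
    logger.info(
        "[concord] n=%d rho=%.3f p=%.2g", concordance.n, concordance.rho, concordance.p_value
    )

    comparison = compare_models(clearances)

    # --- write artifacts ----------------------------------------------------
    artifacts = {
        "timecourse": timecourse_all,
        "clearance": clearance_all,
        "assignments": assignments,
        "detections": detections,
        "mass_balance": balance,
        "concordance": conc_table,
        "model_comparison": comparison,
    }
    paths = {}
    for name, frame in artifacts.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.10g")
        paths[name] = str(path)

    config_dict = config.model_dump()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode("utf-8")
    ).hexdigest()
    manifest = {
        "package": "mixtox",
        "version": __version__,
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": config.seed,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "spearman_rho": concordance.rho,
        "spearman_p": concordance.p_value,
        "spearman_n": concordance.n,
        "n_metabolites_detected": int(len(detections)),
        "artifacts": paths,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("[report] wrote %d artifacts to %s", len(paths) + 1, outdir)
    return manifest
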