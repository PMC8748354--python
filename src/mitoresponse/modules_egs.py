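"""Projection of expression changes onto predefined co-expression modules.

Gene co-expression modules built previously from primary human hepatocyte
data (WGCNA-style: member genes with positive loadings and a hub gene per
module) serve as a fixed coordinate system.  A treatment's differential
expression profile is summarised per module by an eigengene score (EGS): the
loading-weighted mean of per-gene z-scores (z = log2fc / se, or the
per-condition standardized log2fc when no standard error is available).
Coverage records the fraction of each module's members that the measured
probe panel actually contains — targeted panels typically cover 30-50% of a
module, which the score tolerates by averaging over the measured members
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
import scipy.stats

__all__ = [
    "ModuleMap",
    "EGSMatrix",
    "egs_project",
    "module_coverage",
    "egs_correlation",
    "egs_heatmap_select",
]


@dataclass
class ModuleMap:
    """Module membership table: columns module, gene, loading, is_hub.

    Each module is non-empty, loadings lie in (0, 1], and exactly one member
    per module carries the hub flag.
    """

    table: pd.DataFrame

    def __post_init__(self):
        required = {"module", "gene", "loading", "is_hub"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"module map misses columns: {sorted(missing)}")
        loadings = self.table["loading"].to_numpy(float)
        if np.any(loadings <= 0) or np.any(loadings > 1):
            raise ValueError("loadings must lie in (0, 1]")
        hubs = self.table.groupby("module")["is_hub"].sum()
        bad = hubs[hubs != 1]
        if len(bad):
            raise ValueError(f"modules must have exactly one hub gene: {dict(bad)}")

    @property
    def modules(self) -> list:
        return sorted(self.table["module"].unique())

    def members(self, module) -> pd.DataFrame:
        return self.table[self.table["module"] == module]


@dataclass
class EGSMatrix:
    """Module x condition eigengene scores with per-module coverage."""

    scores: pd.DataFrame  # modules x conditions; NaN where coverage is 0
    coverage: pd.Series  # fraction of members measured, in [0, 1]


def _z_scores(det: pd.DataFrame) -> pd.DataFrame:
    """Per-condition z per probe: log2fc/se, else standardized log2fc."""
    rows = []
    for cond, sub in det.groupby("condition"):
        lfc = sub["log2fc"].to_numpy(float)
        se = sub["se"].to_numpy(float) if "se" in sub.columns else np.full(len(sub), np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = lfc / se
        no_se = np.isnan(se) | (se == 0)
        if no_se.any():
            sd = np.nanstd(lfc, ddof=1)
            z = np.where(no_se, lfc / sd if sd > 0 else 0.0, z)
        rows.append(pd.DataFrame({"probe": sub["probe"], "condition": cond, "z": z}))
    return pd.concat(rows, ignore_index=True)


def egs_project(det: pd.DataFrame, modules: ModuleMap, mode: str = "loading") -> EGSMatrix:
    """Eigengene scores of each module under each condition.

    ``mode="loading"`` weights each measured member's z-score by its loading
    (EGS = sum w*z / sum w); ``mode="mean"`` is the unweighted mean.  Modules
    with no measured member get NaN scores and coverage 0.
    """
    if mode not in ("loading", "mean"):
        raise ValueError(f"unknown projection mode {mode!r}")
    z = _z_scores(det).pivot(index="probe", columns="condition", values="z")
    conditions = list(z.columns)
    scores = {}
    coverage = {}
    for m in modules.modules:
        mem = modules.members(m)
        measured = mem[mem["gene"].isin(z.index)]
        coverage[m] = len(measured) / len(mem)
        if len(measured) == 0:
            scores[m] = pd.Series(np.nan, index=conditions)
            continue
        zm = z.loc[measured["gene"]].to_numpy(float)
        w = measured["loading"].to_numpy(float) if mode == "loading" else np.ones(len(measured))
        wcol = w[:, None]
        with np.errstate(invalid="ignore"):
            ok = ~np.isnan(zm)
            num = np.nansum(wcol * zm, axis=0)
            den = np.sum(wcol * ok, axis=0)
            egs = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        scores[m] = pd.Series(egs, index=conditions)
    return EGSMatrix(
        scores=pd.DataFrame(scores).T.reindex(modules.modules),
        coverage=pd.Series(coverage, name="coverage"),
    )


def module_coverage(modules: ModuleMap, measured_genes) -> pd.Series:
    """Fraction of each module's members present in the measured gene set."""
    measured = set(measured_genes)
    out = {}
    for m in modules.modules:
        genes = modules.members(m)["gene"]
        out[m] = float(np.mean([g in measured for g in genes]))
    return pd.Series(out, name="coverage")


def egs_correlation(egs: EGSMatrix, condition_a, condition_b) -> tuple[float, float]:
    """Pearson r and r^2 between two conditions' module scores.

    Uses modules with a defined score in both conditions; fewer than 3 shared
    modules is an error.
    """
    a = egs.scores[condition_a]
    b = egs.scores[condition_b]
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError(
            f"only {int(ok.sum())} modules have defined scores in both conditions; need >= 3"
        )
    r = float(scipy.stats.pearsonr(a[ok], b[ok]).statistic)
    return r, r * r


def egs_heatmap_select(egs: EGSMatrix, threshold: float = 2.0) -> pd.DataFrame:
    """Modules whose |EGS| reaches ``threshold`` in at least one condition.

    The retained matrix is row-ordered by hierarchical clustering on Pearson
    correlation distance (1 - r) so that co-varying modules sit together.
    Returns an empty frame (with a warning) when nothing passes.
    """
    scores = egs.scores
    keep = scores.index[(scores.abs() >= threshold).any(axis=1)]
    if len(keep) == 0:
        warnings.warn("no module reaches the |EGS| threshold; empty selection")
        return scores.iloc[0:0]
    sel = scores.loc[keep]
    if len(sel) > 2:
        filled = sel.fillna(0.0).to_numpy(float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(filled)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = ssd.squareform(np.clip(1.0 - corr, 0.0, 2.0), checks=False)
        order = sch.leaves_list(sch.linkage(dist, method="average"))
        sel = sel.iloc[order]
    return sel
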