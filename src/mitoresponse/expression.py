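"""Targeted transcriptomics processing and the mitotoxicity signature algebra.

Covers the count-level pipeline for a targeted (TempO-Seq-style) probe panel:
library-size QC, median-of-ratios size-factor normalization, a documented
stand-in differential test with Benjamini-Hochberg correction, the triple DEG
filter (padj < 0.05, |log2FC| > 0.58, trend p < 0.05), and the set-algebraic
derivation of a gene signature specific to active electron-transport-chain
inhibitors: probes affected by any active inhibitor, minus probes touched by
inactive inhibitors or positive stress-model controls, intersected over every
individual active treatment, and finally refined by effect size or a curated
mitochondria link.

The differential test here is deliberately simple (Welch's t on
log2(normalized + 0.5) with a pseudo-counted log2 fold change); a DE table
computed externally by a negative-binomial GLM can be supplied in the same
schema and flows through all downstream set operations unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "CountExperiment",
    "library_size_filter",
    "median_of_ratios",
    "de_test",
    "bh_adjust",
    "deg_filter",
    "SignatureResult",
    "signature_sets",
    "refine_signature",
    "concordance",
    "geneset_abs_log2fc",
    "DE_COLUMNS",
]

DE_COLUMNS = ["probe", "condition", "log2fc", "se", "p_value", "padj", "trend_p"]


@dataclass
class CountExperiment:
    """Probe x sample raw counts with sample metadata.

    ``counts``: DataFrame (rows = probes, columns = samples), non-negative
    integers.  ``samples``: DataFrame indexed by sample id with at least the
    columns ``compound``, ``concentration``, ``condition`` plus optional
    ``class_label`` (CI/CII/CIII/positive_control/vehicle) and ``activity``
    (active/inactive/control).  ``size_factors``/``normalized`` are filled by
    :func:`median_of_ratios`.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = None
    normalized: pd.DataFrame | None = None

    def __post_init__(self):
        if not self.counts.columns.equals(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("counts columns and sample metadata index disagree")
            self.samples = self.samples.loc[self.counts.columns]
        arr = self.counts.to_numpy()
        if np.any(arr < 0):
            raise ValueError("counts must be non-negative")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def library_size_filter(exp: CountExperiment, min_reads: int = 100_000) -> CountExperiment:
    """Drop samples whose library size is strictly below ``min_reads``.

    Removals are logged; removing every sample is a hard error.
    """
    sizes = exp.library_sizes
    keep = sizes >= min_reads
    dropped = sizes.index[~keep]
    if len(dropped):
        logger.info(
            "library_size_filter: removed %d/%d samples below %d reads: %s",
            len(dropped), len(sizes), min_reads, list(dropped),
        )
    if not keep.any():
        raise ValueError(f"all samples fall below the {min_reads}-read library-size threshold")
    return CountExperiment(
        counts=exp.counts.loc[:, keep.values],
        samples=exp.samples.loc[keep.values],
    )


def median_of_ratios(exp: CountExperiment, pseudo_count: float = 0.0) -> CountExperiment:
    """Median-of-ratios size factors and the normalized matrix.

    For each probe expressed in every sample, compute its geometric mean
    across samples; a sample's size factor is the median over those probes of
    count / geometric mean, and its normalized values are count / size factor.
    ``pseudo_count`` > 0 rescues matrices where no probe is expressed in all
    samples.
    """
    counts = exp.counts.to_numpy(float) + pseudo_count
    expressed = np.all(counts > 0, axis=1)
    if not expressed.any():
        raise ValueError(
            "no probe has nonzero counts in every sample; "
            "re-run with a pseudo_count > 0"
        )
    sub = counts[expressed]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    sf = np.median(ratios, axis=0)
    normalized = exp.counts.to_numpy(float) / sf
    return replace(
        exp,
        size_factors=pd.Series(sf, index=exp.counts.columns, name="size_factor"),
        normalized=pd.DataFrame(normalized, index=exp.counts.index, columns=exp.counts.columns),
    )


def de_test(
    exp: CountExperiment,
    condition: str,
    vehicle: str = "vehicle",
    condition_col: str = "condition",
    allow_unreplicated: bool = False,
) -> pd.DataFrame:
    """Stand-in per-probe differential test of one condition against vehicle.

    log2fc = log2((mean normalized treated + 0.5) / (mean normalized vehicle
    + 0.5)); p from Welch's unequal-variance t-test on log2(normalized + 0.5).
    Requires >= 2 replicates per side unless ``allow_unreplicated`` (then p and
    se are NaN and only log2fc is reported).

    Returns rows with columns probe, condition, log2fc, se, p_value,
    mean_control, mean_treated (padj and trend_p are attached downstream).
    """
    if exp.normalized is None:
        raise ValueError("experiment is not normalized; run median_of_ratios first")
    labels = exp.samples[condition_col]
    t_cols = labels.index[labels == condition]
    c_cols = labels.index[labels == vehicle]
    if len(t_cols) == 0 or len(c_cols) == 0:
        raise ValueError(f"condition {condition!r} or vehicle {vehicle!r} has no samples")
    if (len(t_cols) < 2 or len(c_cols) < 2) and not allow_unreplicated:
        raise ValueError(
            f"condition {condition!r} vs {vehicle!r} has an unreplicated side; "
            "pass allow_unreplicated=True to report fold changes without p-values"
        )
    T = exp.normalized[t_cols].to_numpy(float)
    C = exp.normalized[c_cols].to_numpy(float)
    mean_t = T.mean(axis=1)
    mean_c = C.mean(axis=1)
    log2fc = np.log2((mean_t + 0.5) / (mean_c + 0.5))
    lt = np.log2(T + 0.5)
    lc = np.log2(C + 0.5)
    if len(t_cols) >= 2 and len(c_cols) >= 2:
        vt = lt.var(axis=1, ddof=1)
        vc = lc.var(axis=1, ddof=1)
        se = np.sqrt(vt / T.shape[1] + vc / C.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = scipy.stats.ttest_ind(lt, lc, axis=1, equal_var=False)
        # zero-variance degeneracies: identical groups get p=1, a noiseless
        # shift gets p=0 rather than NaN
        same_mean = np.isclose(lt.mean(axis=1), lc.mean(axis=1))
        p = np.where(np.isnan(p), np.where(same_mean, 1.0, 0.0), p)
    else:
        se = np.full(len(mean_t), np.nan)
        p = np.full(len(mean_t), np.nan)
    return pd.DataFrame(
        {
            "probe": exp.counts.index,
            "condition": condition,
            "log2fc": log2fc,
            "se": se,
            "p_value": p,
            "mean_control": mean_c,
            "mean_treated": mean_t,
        }
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, NaN-safe.

    NaN entries propagate as NaN and do not affect the ranks of the rest.
    """
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        if np.any((p[mask] < 0) | (p[mask] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def deg_filter(
    det: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 0.58,
    trend_max: float = 0.05,
) -> set:
    """Probes passing the triple DEG filter (all inequalities strict).

    padj < ``padj_max`` AND |log2fc| > ``lfc_min`` AND trend p < ``trend_max``.
    Missing trend p-values fail the filter.
    """
    padj = det["padj"].to_numpy(float)
    lfc = det["log2fc"].to_numpy(float)
    trend = det["trend_p"].to_numpy(float)
    ok = (padj < padj_max) & (np.abs(lfc) > lfc_min) & (trend < trend_max)
    ok &= ~np.isnan(padj) & ~np.isnan(lfc) & ~np.isnan(trend)
    return set(det.loc[ok, "probe"])


@dataclass
class SignatureResult:
    """The set-algebra stages of the ETC-inhibitor signature derivation."""

    any_active: set
    unique_ci: set
    unique_ciii: set
    active_not_control: set
    core: set
    refined: set | None = None

    def funnel(self) -> dict:
        out = {
            "any_active": len(self.any_active),
            "unique_ci": len(self.unique_ci),
            "unique_ciii": len(self.unique_ciii),
            "active_not_control": len(self.active_not_control),
            "core": len(self.core),
        }
        if self.refined is not None:
            out["refined"] = len(self.refined)
        return out


def signature_sets(
    deg_sets: dict,
    labels: pd.DataFrame,
    collapse: str = "condition",
) -> SignatureResult:
    """Derive the mitotoxicity signature sets from per-condition DEG sets.

    Parameters
    ----------
    deg_sets : dict
        condition -> set of probes passing the DEG filter.
    labels : pandas.DataFrame
        Indexed by condition with columns ``activity`` (active/inactive/
        control), ``class_label`` (CI/CII/CIII/positive_control) and
        ``compound``.
    collapse : {"condition", "compound"}
        With ``"compound"``, conditions of the same compound are unioned
        before the intersection step, so "affected by every active inhibitor"
        means every active compound rather than every active condition.

    Returns
    -------
    SignatureResult with: the union over active treatments (``any_active``);
    probes seen in >= 1 CI treatment and no CIII treatment (``unique_ci``) and
    vice versa; ``any_active`` minus everything touched by inactive or
    positive-control treatments (``active_not_control``); and the intersection
    over every individual active treatment restricted to
    ``active_not_control`` (``core``).
    """
    for cond in deg_sets:
        if cond not in labels.index:
            raise ValueError(f"condition {cond!r} has no activity/class label")
    if collapse not in ("condition", "compound"):
        raise ValueError(f"unknown collapse mode {collapse!r}")

    def sets_where(mask) -> list[set]:
        conds = [c for c in deg_sets if mask(labels.loc[c])]
        if collapse == "compound":
            by_comp: dict[str, set] = {}
            for c in conds:
                by_comp.setdefault(labels.loc[c, "compound"], set()).update(deg_sets[c])
            return list(by_comp.values())
        return [set(deg_sets[c]) for c in conds]

    active_sets = sets_where(lambda r: r["activity"] == "active")
    if not active_sets:
        empty: set = set()
        return SignatureResult(empty, empty, empty, empty, empty)
    inactive_union: set = set().union(*sets_where(lambda r: r["activity"] == "inactive"), set())
    control_union: set = set().union(
        *sets_where(lambda r: r["class_label"] == "positive_control"), set()
    )
    ci_union: set = set().union(*sets_where(lambda r: r["class_label"] == "CI"), set())
    ciii_union: set = set().union(*sets_where(lambda r: r["class_label"] == "CIII"), set())

    any_active = set().union(*active_sets)
    unique_ci = ci_union - ciii_union
    unique_ciii = ciii_union - ci_union
    active_not_control = any_active - inactive_union - control_union
    core = set.intersection(*active_sets) & active_not_control
    return SignatureResult(any_active, unique_ci, unique_ciii, active_not_control, core)


def refine_signature(
    core: set,
    det: pd.DataFrame,
    annotation: dict,
    active_conditions=None,
    lfc_min: float = 2.0,
) -> set:
    """Refine the core signature by effect size or curated mitochondria link.

    Keeps probes whose maximal |log2fc| over active conditions exceeds
    ``lfc_min``, plus probes flagged in ``annotation`` (probe -> bool).
    Probes absent from ``annotation`` are treated as unflagged (logged).
    """
    sub = det[det["probe"].isin(core)]
    if active_conditions is not None:
        sub = sub[sub["condition"].isin(active_conditions)]
    max_lfc = sub.groupby("probe")["log2fc"].apply(lambda s: np.nanmax(np.abs(s)))
    refined = set()
    for probe in core:
        flagged = annotation.get(probe)
        if flagged is None:
            logger.info("refine_signature: probe %s has no annotation; treated as unflagged", probe)
            flagged = False
        strong = probe in max_lfc.index and max_lfc.loc[probe] > lfc_min
        if strong or flagged:
            refined.add(probe)
    return refined


def concordance(
    det_a: pd.DataFrame,
    det_b: pd.DataFrame,
    padj_max: float = 0.05,
    lfc_min: float = 0.58,
) -> tuple[int, int, int, pd.DataFrame]:
    """Directional concordance of two DE tables on their shared passing probes.

    A probe enters when it passes padj < ``padj_max`` and |log2fc| >
    ``lfc_min`` in both tables; returns (concordant, discordant, total) counts
    plus the merged scatter table.
    """

    def passing(det):
        ok = (det["padj"].to_numpy(float) < padj_max) & (
            np.abs(det["log2fc"].to_numpy(float)) > lfc_min
        )
        return det.loc[ok, ["probe", "log2fc"]]

    a = passing(det_a).set_index("probe")
    b = passing(det_b).set_index("probe")
    shared = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
    if shared.empty:
        warnings.warn("no shared probes pass the filter in both tables")
        return 0, 0, 0, shared.reset_index()
    same = int(np.sum(np.sign(shared["log2fc_a"]) == np.sign(shared["log2fc_b"])))
    total = len(shared)
    return same, total - same, total, shared.reset_index()


def geneset_abs_log2fc(det: pd.DataFrame, gene_set) -> pd.DataFrame:
    """Average |log2fc| inside a gene set versus over all measured genes.

    One row per condition with columns ``set_mean`` and ``overall_mean``;
    NaN log2fc values are ignored.  An empty intersection with the measured
    probes is an error naming the missing genes.
    """
    gene_set = set(gene_set)
    measured = set(det["probe"])
    hit = gene_set & measured
    if not hit:
        raise ValueError(
            f"none of the gene-set members are measured; missing: {sorted(gene_set)}"
        )
    rows = []
    for cond, sub in det.groupby("condition"):
        in_set = sub[sub["probe"].isin(hit)]
        rows.append(
            {
                "condition": cond,
                "set_mean": float(np.nanmean(np.abs(in_set["log2fc"].to_numpy(float)))),
                "overall_mean": float(np.nanmean(np.abs(sub["log2fc"].to_numpy(float)))),
                "n_set": len(in_set),
                "n_total": len(sub),
            }
        )
    return pd.DataFrame(rows)
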