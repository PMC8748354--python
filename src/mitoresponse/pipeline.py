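"""End-to-end orchestration of the synthetic-data analysis pipeline.

Chains the stages simulate -> library filter -> normalize -> trend test ->
differential expression -> signature -> module projection -> endpoints and
records a manifest (seeds, per-stage row counts, funnel sizes) so that every
filter's input/output counts are visible.  Re-running with an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dose_response, expression, imaging, modules_egs, synth
from .kinetics import fit_decay

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline", "trend_table", "build_de_table"]

STAGES = ("simulate", "mmp_fit", "normalize", "trend", "de", "signature", "egs", "endpoints")


@dataclass
class RunConfig:
    """Stage toggles, paths and analysis thresholds.

    Threshold defaults are the study's: padj < 0.05, |log2FC| > 0.58, trend
    p < 0.05, benchmark response of 1 vehicle SD, 10,000 permutations,
    100,000-read library floor, |EGS| >= 2, PI overlap > 0.10, GFP factor 2.
    """

    out_dir: str = "mitoresponse_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    padj_max: float = 0.05
    lfc_min: float = 0.58
    trend_p_max: float = 0.05
    bmr_factor: float = 1.0
    n_permutations: int = 10000
    min_library: int = 100_000
    egs_threshold: float = 2.0
    pi_overlap: float = 0.10
    gfp_factor: float = 2.0
    n_mmp_starts: int = 100
    synth: dict = field(default_factory=dict)  # overrides for SynthConfig
    module_map: str | None = None  # path; None = simulate one
    n_modules: int = 8
    genes_per_module: int = 10

    @classmethod
    def from_yaml(cls, path, overrides=()) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.apply_overrides(overrides)
        return cfg

    def apply_overrides(self, overrides=()) -> "RunConfig":
        """Apply ``key=value`` strings, coercing to the field's current type."""
        for ov in overrides:
            key, _, value = ov.partition("=")
            if not hasattr(self, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(self, key)
            if isinstance(current, bool):
                value = value.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                value = int(value)
            elif isinstance(current, float):
                value = float(value)
            setattr(self, key, value)
        return self


def validate_config(cfg: RunConfig) -> list[str]:
    """Aggregate all configuration errors (empty list means valid)."""
    errors = []
    for name in ("padj_max", "lfc_min", "trend_p_max", "bmr_factor", "egs_threshold",
                 "pi_overlap", "gfp_factor"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be positive")
    for name in ("n_permutations", "min_library", "n_mmp_starts", "n_modules",
                 "genes_per_module"):
        if getattr(cfg, name) <= 0:
            errors.append(f"{name} must be a positive integer")
    unknown = set(cfg.stages) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    on = {s for s in STAGES if cfg.stages.get(s, False)}
    deps = {
        "mmp_fit": {"simulate"},
        "normalize": {"simulate"},
        "trend": {"normalize"},
        "de": {"normalize"},
        "signature": {"de", "trend"},
        "egs": {"de"},
    }
    for stage, needs in deps.items():
        if stage in on:
            for need in needs - on:
                errors.append(f"stage {stage!r} requires stage {need!r} to be enabled")
    if cfg.module_map is not None and not Path(cfg.module_map).exists():
        errors.append(f"module map path does not exist: {cfg.module_map}")
    return errors


def trend_table(exp: expression.CountExperiment, n_permutations: int = 10000,
                seed: int | None = None) -> pd.DataFrame:
    """Williams trend p per probe per compound from log2 normalized counts.

    For each compound, pools its samples with the vehicle wells and runs the
    batch permutation trend test across the concentration series.
    """
    if exp.normalized is None:
        raise ValueError("experiment is not normalized")
    meta = exp.samples
    vehicle_cols = meta.index[meta["condition"] == "vehicle"]
    rows = []
    compounds = sorted(set(meta.loc[meta["condition"] != "vehicle", "compound"]))
    log2n = np.log2(exp.normalized + 0.5)
    for i, comp in enumerate(compounds):
        cols = list(vehicle_cols) + list(meta.index[meta["compound"] == comp])
        conc = meta.loc[cols, "concentration"].to_numpy(float)
        sub_seed = None if seed is None else int(np.random.SeedSequence([seed, 7, i]).generate_state(1)[0] % (2**31))
        res = dose_response.williams_test_batch(
            log2n[cols].to_numpy(float), conc,
            n_permutations=n_permutations, seed=sub_seed,
        )
        res.insert(0, "probe", exp.counts.index)
        res.insert(1, "compound", comp)
        rows.append(res)
    return pd.concat(rows, ignore_index=True)


def build_de_table(exp: expression.CountExperiment, trend: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-condition DE table with BH adjustment and merged trend p-values."""
    meta = exp.samples
    conditions = sorted(set(meta["condition"]) - {"vehicle"})
    tables = []
    for cond in conditions:
        det = expression.de_test(exp, cond)
        det["padj"] = expression.bh_adjust(det["p_value"])
        comp = meta.loc[meta["condition"] == cond, "compound"].iloc[0]
        if trend is not None:
            tp = trend[trend["compound"] == comp].set_index("probe")["p_value"]
            det["trend_p"] = tp.reindex(det["probe"]).to_numpy()
        else:
            det["trend_p"] = np.nan
        tables.append(det)
    return pd.concat(tables, ignore_index=True)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write artifacts.

    Returns the manifest (also written to ``manifest.json``); a stage failure
    aborts with the failing stage named and renames its partial outputs with a
    ``.partial`` suffix.
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "config": _config_dict(cfg)}
    on = {s for s in STAGES if cfg.stages.get(s, False)}
    state: dict = {}

    def record(stage, **info):
        manifest["stages"][stage] = info

    current = None
    try:
        if "simulate" in on:
            current = "simulate"
            scfg = synth.SynthConfig(seed=cfg.seed, **cfg.synth)
            truth = synth.signature_ground_truth(scfg)
            ts = synth.gen_mmp_timeseries(scfg, truth)
            exp = expression.library_size_filter(
                synth.gen_counts(scfg, truth), cfg.min_library
            )
            cells = synth.gen_cell_table(scfg, positive_fraction=0.25)
            ts.to_csv(out / "mmp_timeseries.tsv", sep="\t", index=False)
            (out / "ground_truth.json").write_text(truth.to_json())
            state.update(truth=truth, ts=ts, exp=exp, cells=cells, scfg=scfg)
            record("simulate", n_trajectory_rows=len(ts),
                   n_probes=exp.counts.shape[0], n_samples=exp.counts.shape[1],
                   n_cells=len(cells))

        if "mmp_fit" in on:
            current = "mmp_fit"
            fits = []
            for comp, sub in state["ts"].groupby("compound"):
                fits.append(fit_decay(sub, n_starts=cfg.n_mmp_starts, seed=cfg.seed))
            amat = pd.DataFrame({f.compound: f.a_by_concentration for f in fits}).T
            amat.to_csv(out / "a_matrix.tsv", sep="\t")
            from .io import write_fits
            write_fits(fits, out / "mmp_fits.json")
            state["fits"] = fits
            record("mmp_fit", n_compounds=len(fits),
                   taus={f.compound: round(f.tau, 4) for f in fits})

        if "normalize" in on:
            current = "normalize"
            exp = expression.median_of_ratios(state["exp"])
            state["exp"] = exp
            exp.normalized.to_csv(out / "normalized.tsv", sep="\t")
            record("normalize", n_samples=exp.counts.shape[1],
                   size_factor_range=[float(exp.size_factors.min()),
                                      float(exp.size_factors.max())])

        if "trend" in on:
            current = "trend"
            trend = trend_table(state["exp"], n_permutations=cfg.n_permutations,
                                seed=cfg.seed)
            trend.to_csv(out / "trend.tsv", sep="\t", index=False)
            state["trend"] = trend
            record("trend", n_rows=len(trend),
                   n_significant=int((trend["p_value"] < cfg.trend_p_max).sum()))

        if "de" in on:
            current = "de"
            det = build_de_table(state["exp"], state.get("trend"))
            det.to_csv(out / "de_table.tsv", sep="\t", index=False)
            state["det"] = det
            record("de", n_rows=len(det),
                   n_conditions=det["condition"].nunique())

        if "signature" in on:
            current = "signature"
            det = state["det"]
            meta = state["exp"].samples
            deg_sets = {
                cond: expression.deg_filter(sub, cfg.padj_max, cfg.lfc_min, cfg.trend_p_max)
                for cond, sub in det.groupby("condition")
            }
            labels = (
                meta[meta["condition"] != "vehicle"]
                [["condition", "compound", "class_label", "activity"]]
                .drop_duplicates("condition")
                .set_index("condition")
            )
            sig = expression.signature_sets(deg_sets, labels, collapse="compound")
            from .io import write_signature
            write_signature(sig, out / "signature.json")
            state["signature"] = sig
            record("signature", **sig.funnel())

        if "egs" in on:
            current = "egs"
            if cfg.module_map is not None:
                from .io import read_module_map
                modules = read_module_map(cfg.module_map)
            else:
                universe = list(state["exp"].counts.index)
                gpm = min(cfg.genes_per_module, max(1, len(universe) // cfg.n_modules))
                modules = synth.gen_module_map(
                    cfg.n_modules, gpm, probe_universe=universe, seed=cfg.seed,
                )
            egs = modules_egs.egs_project(state["det"], modules)
            egs.scores.to_csv(out / "egs.tsv", sep="\t")
            (out / "egs_coverage.json").write_text(egs.coverage.to_json(indent=1))
            selected = modules_egs.egs_heatmap_select(egs, cfg.egs_threshold)
            state["egs"] = egs
            record("egs", n_modules=len(egs.scores),
                   coverage_mean=float(egs.coverage.mean()),
                   n_selected=len(selected))

        if "endpoints" in on:
            current = "endpoints"
            cells = state["cells"]
            summary = imaging.well_summary(cells, vehicle_reference=1000.0)
            summary.to_csv(out / "well_summary.tsv", sep="\t", index=False)
            record("endpoints", n_wells=len(summary),
                   pi_positive_fraction=float(summary["pi_positive_fraction"].iloc[0]))
    except Exception as exc:
        for p in out.glob("*"):
            if p.suffix != ".partial" and p.stat().st_size == 0:
                p.rename(p.with_suffix(p.suffix + ".partial"))
        logger.error("pipeline failed in stage %r", current)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _config_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
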