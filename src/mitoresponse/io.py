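"""Plain-text readers and writers for the pipeline's tables.

Conventions: TSV for matrices and long tables, CSV for per-object cell
tables, JSON for fit records, ground truth and signature sets.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .expression import CountExperiment, SignatureResult
from .modules_egs import ModuleMap

__all__ = [
    "read_mmp_timeseries",
    "write_mmp_timeseries",
    "write_fits",
    "read_counts",
    "write_counts",
    "read_de_table",
    "write_de_table",
    "read_module_map",
    "write_module_map",
    "read_cell_table",
    "write_signature",
]


def read_mmp_timeseries(path) -> pd.DataFrame:
    """Long-format TSV: compound, concentration, replicate, time_h, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"compound", "concentration", "replicate", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_mmp_timeseries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fits(fits, path) -> None:
    """JSON array of per-compound decay-fit records."""
    payload = [f.to_dict() for f in fits]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_counts(counts_path, samples_path) -> CountExperiment:
    """Counts TSV (probes x samples, first column = probe id) + sample TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return CountExperiment(counts=counts, samples=samples)


def write_counts(exp: CountExperiment, counts_path, samples_path) -> None:
    exp.counts.to_csv(counts_path, sep="\t")
    exp.samples.to_csv(samples_path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"probe", "condition", "log2fc"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_de_table(det: pd.DataFrame, path) -> None:
    det.to_csv(path, sep="\t", index=False)


def read_module_map(path) -> ModuleMap:
    """TSV with columns module, gene, loading, is_hub."""
    return ModuleMap(pd.read_csv(path, sep="\t"))


def write_module_map(modules: ModuleMap, path) -> None:
    modules.table.to_csv(path, sep="\t", index=False)


def read_cell_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_signature(sig: SignatureResult, path) -> None:
    payload = {
        "any_active": sorted(sig.any_active),
        "unique_ci": sorted(sig.unique_ci),
        "unique_ciii": sorted(sig.unique_ciii),
        "active_not_control": sorted(sig.active_not_control),
        "core": sorted(sig.core),
        "refined": sorted(sig.refined) if sig.refined is not None else None,
        "funnel": sig.funnel(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
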