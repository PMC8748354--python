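"""Imaging-derived endpoint rules on per-object feature tables.

Consumes already-segmented object tables (CellProfiler-style exports: one row
per nucleus/cell with areas and integrated channel intensities) and applies
the study's endpoint definitions:

* a nucleus is PI-positive when its overlap with a propidium-iodide object
  exceeds 10% of the nuclear area (strict >);
* a cell is GFP-positive when its integrated GFP intensity reaches twice the
  vehicle-control mean (inclusive >=, configurable);
* the ATP-biosensor FRET ratio is emission_488 / emission_408 per object
  (orientation configurable);
* plate-reader ATP luminescence is normalized per cell by the nuclear count;
* kinetic intensity readouts are summarised as the geometric mean over
  replicates expressed as a fraction of the matched vehicle control.

Segmentation itself is upstream and out of scope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_TABLE_COLUMNS",
    "pi_positive_fraction",
    "gfp_positive_fraction",
    "fret_ratio",
    "atp_per_cell",
    "fraction_of_control",
    "well_summary",
]

CELL_TABLE_COLUMNS = [
    "nucleus_area",
    "pi_overlap_area",
    "gfp_integrated",
    "em_408",
    "em_488",
    "well",
    "condition",
]


def pi_positive_fraction(cells: pd.DataFrame, overlap_threshold: float = 0.10) -> float:
    """Fraction of nuclei whose PI-object overlap exceeds 10% of nuclear area.

    Strictly greater than the threshold; an empty table yields NaN with a
    warning.
    """
    if len(cells) == 0:
        warnings.warn("empty cell table: PI-positive fraction undefined")
        return float("nan")
    area = cells["nucleus_area"].to_numpy(float)
    overlap = cells["pi_overlap_area"].to_numpy(float)
    if np.any(area <= 0):
        raise ValueError("nucleus areas must be positive")
    if np.any(overlap > area):
        raise ValueError("PI overlap cannot exceed the nucleus area")
    return float(np.mean(overlap / area > overlap_threshold))


def gfp_positive_fraction(
    cells: pd.DataFrame,
    vehicle_reference: float,
    factor: float = 2.0,
    inclusive: bool = True,
) -> float:
    """Fraction of cells at or above ``factor`` times the vehicle GFP mean.

    ``vehicle_reference`` is the mean integrated GFP intensity of the matched
    vehicle wells and must be positive.  The boundary is inclusive by default.
    """
    if vehicle_reference <= 0:
        raise ValueError(f"vehicle reference intensity must be positive, got {vehicle_reference}")
    intens = cells["gfp_integrated"].to_numpy(float)
    cut = factor * vehicle_reference
    return float(np.mean(intens >= cut if inclusive else intens > cut))


def fret_ratio(cells: pd.DataFrame, invert: bool = False) -> tuple[pd.Series, float]:
    """Per-object ATP-biosensor FRET ratio and the well mean.

    Default orientation is emission_488 / emission_408 (acceptor over donor
    for the 408-excited probe); ``invert`` swaps it.  Objects with a zero
    denominator are dropped and logged; all-zero denominators are an error.
    """
    num_col, den_col = ("em_408", "em_488") if invert else ("em_488", "em_408")
    den = cells[den_col].to_numpy(float)
    num = cells[num_col].to_numpy(float)
    ok = den > 0
    if not ok.any():
        raise ValueError(f"all {den_col} denominators are zero; no FRET ratio defined")
    if (~ok).any():
        logger.info("fret_ratio: dropped %d objects with zero %s", int((~ok).sum()), den_col)
    ratios = pd.Series(num[ok] / den[ok], index=cells.index[ok], name="fret_ratio")
    return ratios, float(ratios.mean())


def atp_per_cell(luminescence: float, nuclear_count: int) -> float:
    """ATP luminescence normalized to the imaged nuclear count."""
    if nuclear_count <= 0:
        raise ValueError(f"nuclear count must be positive, got {nuclear_count}")
    return float(luminescence) / nuclear_count


def fraction_of_control(series, control) -> np.ndarray:
    """Geometric-mean replicate summary expressed as fraction of control.

    ``series`` and ``control`` are replicate x timepoint arrays (or 1-D
    replicate vectors) of positive intensities; the result per timepoint is
    geomean(series) / geomean(control).
    """
    series = np.asarray(series, dtype=float)
    control = np.asarray(control, dtype=float)
    # 1-D inputs are replicate vectors at a single timepoint
    if series.ndim == 1:
        series = series[:, None]
    if control.ndim == 1:
        control = control[:, None]
    for name, arr in (("treated", series), ("control", control)):
        bad = np.nonzero(~(arr > 0))
        if len(bad[0]):
            raise ValueError(
                f"non-positive intensity in {name} replicate {int(bad[0][0])}"
            )
    gm_s = np.exp(np.mean(np.log(series), axis=0))
    gm_c = np.exp(np.mean(np.log(control), axis=0))
    out = gm_s / gm_c
    return out if out.size > 1 else float(out[0])


def well_summary(
    cells: pd.DataFrame,
    vehicle_reference: float | None = None,
    luminescence: float | None = None,
) -> pd.DataFrame:
    """Per-well endpoint summary of a cell table.

    Computes the PI-positive fraction, GFP-positive fraction (when a vehicle
    reference is supplied), mean FRET ratio, nuclear count and, when a
    luminescence reading is supplied, the per-cell ATP.
    """
    rows = []
    for well, sub in cells.groupby("well"):
        row = {
            "well": well,
            "condition": sub["condition"].iloc[0] if "condition" in sub.columns else None,
            "nuclear_count": len(sub),
            "pi_positive_fraction": pi_positive_fraction(sub),
            "mean_fret_ratio": fret_ratio(sub)[1],
        }
        if vehicle_reference is not None:
            row["gfp_positive_fraction"] = gfp_positive_fraction(sub, vehicle_reference)
        if luminescence is not None:
            row["atp_per_cell"] = atp_per_cell(luminescence, len(sub))
        rows.append(row)
    return pd.DataFrame(rows)
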