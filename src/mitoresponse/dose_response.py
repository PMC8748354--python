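"""Concentration-response statistics: Williams trend test, BMD and BMC.

Implements the monotone-trend and benchmark-dose machinery applied to log2
normalized probe counts (or any per-sample endpoint) across an ordered
concentration series that includes a vehicle (0 µM) group:

* :func:`williams_test` — Williams-type trend statistic using amalgamated
  (isotonic) dose-group means, with a label-permutation null.  The statistic is
  T = (amalgamated mean of the highest dose group - vehicle mean) / pooled SE,
  evaluated for both monotone directions; the larger |T| is reported.
* :class:`BenchmarkDoseModel` — least-squares fits of the standard benchmark
  dose model suite (power, linear, 2nd-order polynomial, Hill, exponential
  2-5), model selection by AIC = n*ln(SSE/n) + 2k, and the benchmark dose at a
  benchmark response of one vehicle standard deviation.
* :func:`bmc_per_probe` — the empirical benchmark concentration: the lowest
  tested concentration whose mean response deviates from the vehicle mean by
  more than one vehicle SD in either direction.

The amalgamated mean of the top dose group has a closed form: it is the
maximum (minimum, for a decreasing trend) over weighted suffix means of the
dose-group means.  The batch permutation test exploits this to vectorise over
probes and permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.isotonic import isotonic_regression

__all__ = [
    "DoseGroups",
    "pava_isotonic",
    "TrendResult",
    "williams_test",
    "williams_test_batch",
    "BenchmarkDoseModel",
    "BMDResults",
    "fit_bmd",
    "bmc_per_probe",
    "bmd_accumulation",
    "BMD_MODELS",
]


@dataclass
class DoseGroups:
    """Per-sample responses across an ordered concentration series.

    ``concentrations`` are the distinct levels in increasing order and must
    include the vehicle (0).  ``values``/``group_index`` are per-sample, with
    ``group_index[i]`` the position of sample i's level in ``concentrations``.
    """

    concentrations: np.ndarray
    values: np.ndarray
    group_index: np.ndarray

    @classmethod
    def from_arrays(cls, concentration_per_sample, values) -> "DoseGroups":
        conc = np.asarray(concentration_per_sample, dtype=float)
        vals = np.asarray(values, dtype=float)
        levels = np.unique(conc)
        if levels[0] != 0.0:
            raise ValueError("vehicle (0) group is required")
        idx = np.searchsorted(levels, conc)
        if np.sum(idx == 0) < 2:
            raise ValueError("need >= 2 vehicle samples for SD estimation")
        return cls(concentrations=levels, values=vals, group_index=idx)

    @property
    def n_groups(self) -> int:
        return len(self.concentrations)

    def group_values(self, g: int) -> np.ndarray:
        return self.values[self.group_index == g]

    @property
    def vehicle_sd(self) -> float:
        return float(np.std(self.group_values(0), ddof=1))

    @property
    def vehicle_mean(self) -> float:
        return float(np.mean(self.group_values(0)))

    def group_means(self) -> np.ndarray:
        return np.array([self.group_values(g).mean() for g in range(self.n_groups)])


def pava_isotonic(means, weights=None, increasing: bool = True) -> np.ndarray:
    """Weighted isotonic (monotone) regression of per-group means.

    Pool-adjacent-violators fit of the weighted least-squares monotone vector;
    idempotent.  Groups must already be ordered by concentration.
    """
    means = np.asarray(means, dtype=float)
    if means.size == 0:
        raise ValueError("empty input")
    if weights is None:
        weights = np.ones_like(means)
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be positive")
    return isotonic_regression(means, sample_weight=weights, increasing=increasing)


@dataclass
class TrendResult:
    """Williams trend-test outcome for one probe/endpoint."""

    statistic: float
    direction: str  # "up" or "down"
    p_value: float
    n_permutations: int


def _amalgamated_top(means: np.ndarray, weights: np.ndarray, increasing: bool) -> np.ndarray:
    """Amalgamated mean of the highest dose group.

    ``means``/``weights`` have the treated groups along the last axis (vehicle
    excluded).  Equals max (increasing) or min (decreasing) over weighted
    suffix means — the isotonic-regression value at the last group.
    """
    wsum = np.cumsum(weights[..., ::-1], axis=-1)[..., ::-1]
    wm = np.cumsum((weights * means)[..., ::-1], axis=-1)[..., ::-1]
    suffix_means = wm / wsum
    return suffix_means.max(axis=-1) if increasing else suffix_means.min(axis=-1)


def _williams_stats(values: np.ndarray, group_index: np.ndarray, n_groups: int):
    """Williams T for each row of ``values`` (rows = probes).

    Returns (statistic, direction_is_up) arrays.  Pooled within-group variance
    with n - K degrees of freedom; SE = s * sqrt(1/n_top + 1/n_vehicle).
    """
    values = np.atleast_2d(values)
    n = values.shape[1]
    counts = np.bincount(group_index, minlength=n_groups).astype(float)
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), group_index] = 1.0
    sums = values @ onehot
    means = sums / counts
    sumsq = (values**2) @ onehot
    ss_within = np.sum(sumsq - sums**2 / counts, axis=-1)
    dof = n - n_groups
    s2 = ss_within / max(dof, 1)
    se = np.sqrt(s2 * (1.0 / counts[-1] + 1.0 / counts[0]))
    treated_means = means[..., 1:]
    treated_w = counts[1:]
    up = _amalgamated_top(treated_means, treated_w, True) - means[..., 0]
    down = _amalgamated_top(treated_means, treated_w, False) - means[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = np.where(se > 0, up / np.where(se > 0, se, 1.0), np.where(up != 0, np.inf * np.sign(up), 0.0))
        t_down = np.where(se > 0, down / np.where(se > 0, se, 1.0), np.where(down != 0, np.inf * np.sign(down), 0.0))
    use_up = np.abs(t_up) >= np.abs(t_down)
    stat = np.where(use_up, t_up, t_down)
    return stat, use_up


def williams_test_batch(
    values: np.ndarray,
    concentration_per_sample,
    n_permutations: int = 10000,
    seed: int | None = None,
    chunk: int = 500,
) -> pd.DataFrame:
    """Williams trend test for many probes sharing one design.

    Parameters
    ----------
    values : ndarray, shape (n_probes, n_samples)
        Per-sample responses (e.g. log2 normalized counts).
    concentration_per_sample : array_like
        Concentration of each sample; must include a vehicle (0) group with
        >= 2 samples and >= 2 non-vehicle levels.
    n_permutations : int
        Label permutations for the null; p = (1 + #{|T*| >= |T|}) / (1 + B).
    seed : int, optional
        Seed for the permutation stream.

    Returns
    -------
    pandas.DataFrame with columns statistic, direction, p_value, n_permutations.
    """
    conc = np.asarray(concentration_per_sample, dtype=float)
    levels = np.unique(conc)
    if levels[0] != 0.0:
        raise ValueError("vehicle (0) group is required")
    if len(levels) < 3:
        raise ValueError("need >= 2 non-vehicle concentration groups")
    gidx = np.searchsorted(levels, conc)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_probes, n = values.shape
    K = len(levels)

    stat, use_up = _williams_stats(values, gidx, K)
    abs_stat = np.abs(stat)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_probes)
    done = 0
    while done < n_permutations:
        b = min(chunk, n_permutations - done)
        perm_stats = np.empty((n_probes, b))
        for j in range(b):
            pg = rng.permutation(gidx)
            ps, _ = _williams_stats(values, pg, K)
            perm_stats[:, j] = ps
        finite = np.abs(perm_stats)
        exceed += np.sum(finite >= abs_stat[:, None], axis=1)
        done += b
    # identical-value rows: statistic 0, p 1 by convention
    const_rows = np.all(values == values[:, [0]], axis=1)
    p = (1.0 + exceed) / (1.0 + n_permutations)
    p = np.where(const_rows, 1.0, p)
    stat = np.where(const_rows, 0.0, stat)
    return pd.DataFrame(
        {
            "statistic": stat,
            "direction": np.where(use_up, "up", "down"),
            "p_value": p,
            "n_permutations": n_permutations,
        }
    )


def williams_test(
    groups: DoseGroups, n_permutations: int = 10000, seed: int | None = None
) -> TrendResult:
    """Permutation Williams trend test for a single probe/endpoint."""
    if groups.n_groups < 3:
        raise ValueError("need >= 2 non-vehicle concentration groups")
    conc = groups.concentrations[groups.group_index]
    df = williams_test_batch(
        groups.values[None, :], conc, n_permutations=n_permutations, seed=seed
    )
    row = df.iloc[0]
    return TrendResult(
        statistic=float(row["statistic"]),
        direction=str(row["direction"]),
        p_value=float(row["p_value"]),
        n_permutations=n_permutations,
    )


# --------------------------------------------------------------------------
# Benchmark dose model suite
# --------------------------------------------------------------------------


def _f_linear(c, b0, b1):
    return b0 + b1 * c


def _f_power(c, b0, b1, p):
    return b0 + b1 * np.power(c, p)


def _f_poly2(c, b0, b1, b2):
    return b0 + b1 * c + b2 * c**2


def _f_hill(c, b0, v, k, nh):
    return b0 + v * c**nh / (k**nh + c**nh)


def _f_exp2(c, a, b):
    return a * np.exp(b * c)


def _f_exp3(c, a, b, d):
    return a * np.exp(np.sign(b) * np.power(np.abs(b) * c, d))


def _f_exp4(c, a, c0, b):
    return a * (c0 - (c0 - 1.0) * np.exp(-b * c))


def _f_exp5(c, a, c0, b, d):
    return a * (c0 - (c0 - 1.0) * np.exp(-np.power(b * c, d)))


BMD_MODELS: dict[str, dict] = {
    "linear": {"f": _f_linear, "k": 2},
    "power": {"f": _f_power, "k": 3},
    "poly2": {"f": _f_poly2, "k": 3},
    "hill": {"f": _f_hill, "k": 4},
    "exp2": {"f": _f_exp2, "k": 2},
    "exp3": {"f": _f_exp3, "k": 3},
    "exp4": {"f": _f_exp4, "k": 3},
    "exp5": {"f": _f_exp5, "k": 4},
}


def _initial_params(name: str, groups: DoseGroups):
    """Data-driven starting values and bounds per model."""
    means = groups.group_means()
    cmax = groups.concentrations[-1]
    pos = groups.concentrations[groups.concentrations > 0]
    cmid = float(np.median(pos))
    b0 = means[0]
    span = means[-1] - means[0]
    if span == 0:
        span = 1e-8
    big = np.inf
    if name == "linear":
        return [b0, span / cmax], ([-big, -big], [big, big])
    if name == "power":
        return [b0, span / cmax, 1.0], ([-big, -big, 1e-2], [big, big, 18.0])
    if name == "poly2":
        return [b0, span / cmax, 0.0], ([-big] * 3, [big] * 3)
    if name == "hill":
        return [b0, span, cmid, 1.0], ([-big, -big, 1e-8, 1e-2], [big, big, cmax * 100, 18.0])
    if name == "exp2":
        rate = np.log(max(abs(means[-1]), 1e-8) / max(abs(b0), 1e-8)) / cmax if b0 != 0 else 0.0
        return [b0 if b0 != 0 else 1e-3, rate], ([-big, -big], [big, big])
    if name == "exp3":
        return [b0 if b0 != 0 else 1e-3, 1.0 / cmid, 1.0], ([-big, -1e6, 1.0], [big, 1e6, 18.0])
    if name == "exp4":
        c0 = means[-1] / b0 if b0 != 0 else 2.0
        return [b0 if b0 != 0 else 1e-3, c0, 1.0 / cmid], ([-big, 1e-8, 1e-8], [big, big, big])
    if name == "exp5":
        c0 = means[-1] / b0 if b0 != 0 else 2.0
        return [b0 if b0 != 0 else 1e-3, c0, 1.0 / cmid, 1.0], (
            [-big, 1e-8, 1e-8, 1.0],
            [big, big, big, 18.0],
        )
    raise KeyError(name)


@dataclass
class _ModelFit:
    name: str
    params: np.ndarray
    sse: float
    aic: float
    converged: bool


@dataclass
class BMDResults:
    """Benchmark-dose estimate with AIC model selection.

    ``bmd`` is the concentration at which the best model's response deviates
    from its vehicle prediction by the benchmark response ``bmr`` (one vehicle
    SD); NaN when no model reaches the BMR within the tested range.
    """

    best_model: str | None
    parameters: dict | None
    aic: float
    bmd: float
    bmr: float
    extrapolated: bool
    fits: list = field(default_factory=list, repr=False)

    @property
    def defined(self) -> bool:
        return self.best_model is not None and np.isfinite(self.bmd)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"model": f.name, "k": BMD_MODELS[f.name]["k"], "sse": f.sse,
             "aic": f.aic, "best": f.name == self.best_model}
            for f in self.fits
        ]
        df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
        df.attrs["bmd"] = self.bmd
        df.attrs["bmr"] = self.bmr
        return df


class BenchmarkDoseModel:
    """Least-squares benchmark-dose fitting over the standard model suite.

    Fits each requested model to the per-sample responses, selects the
    converged fit with the lowest AIC (n*ln(SSE/n) + 2k) and inverts the best
    model at a benchmark response of ``bmr_factor`` vehicle standard
    deviations.  Models with at least as many parameters as there are
    concentration groups are skipped.
    """

    def __init__(self, groups: DoseGroups, models=None, max_iterations: int = 250,
                 bmr_factor: float = 1.0):
        self.groups = groups
        self.models = list(models) if models is not None else list(BMD_MODELS)
        self.max_iterations = max_iterations
        self.bmr_factor = bmr_factor

    def fit(self) -> BMDResults:
        g = self.groups
        sd0 = g.vehicle_sd
        if sd0 == 0:
            raise ValueError("vehicle SD is 0: benchmark response undefined")
        bmr = self.bmr_factor * sd0
        c = g.concentrations[g.group_index]
        y = g.values
        fits: list[_ModelFit] = []
        n = len(y)
        for name in self.models:
            spec = BMD_MODELS[name]
            if spec["k"] >= g.n_groups:
                continue
            p0, bounds = _initial_params(name, g)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = scipy.optimize.curve_fit(
                        spec["f"], c, y, p0=p0, bounds=bounds,
                        max_nfev=self.max_iterations * (spec["k"] + 1),
                        method="trf",
                    )
                resid = y - spec["f"](c, *popt)
                sse = float(resid @ resid)
                aic = n * np.log(max(sse, 1e-300) / n) + 2 * spec["k"]
                fits.append(_ModelFit(name, popt, sse, aic, True))
            except (RuntimeError, ValueError):
                continue
        if not fits:
            return BMDResults(None, None, np.nan, np.nan, bmr, False, fits=[])
        best = min(fits, key=lambda f: f.aic)
        bmd, extrapolated = self._invert(best, bmr)
        return BMDResults(
            best_model=best.name,
            parameters={"values": best.params.tolist()},
            aic=best.aic,
            bmd=bmd,
            bmr=bmr,
            extrapolated=extrapolated,
            fits=fits,
        )

    def _invert(self, fit: _ModelFit, bmr: float) -> tuple[float, bool]:
        """Lowest concentration where |f(c) - f(0)| = bmr, by grid + brentq."""
        f = BMD_MODELS[fit.name]["f"]
        g = self.groups
        cmax = float(g.concentrations[-1])
        cmin_pos = float(g.concentrations[g.concentrations > 0][0])
        f0 = f(0.0, *fit.params)

        def dev(c):
            return np.abs(f(c, *fit.params) - f0) - bmr

        grid = np.concatenate([[0.0], np.geomspace(cmin_pos / 1000, cmax, 400)])
        vals = dev(grid)
        cross = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
        if len(cross) == 0:
            return np.nan, False
        i = cross[0]
        if vals[i + 1] == 0:
            bmd = float(grid[i + 1])
        else:
            lo = max(grid[i], 1e-12)
            bmd = float(scipy.optimize.brentq(dev, lo, grid[i + 1], xtol=1e-12, rtol=1e-12))
        extrapolated = bmd < cmin_pos / 10 or bmd > cmax
        return bmd, extrapolated


def fit_bmd(groups: DoseGroups, models=None, max_iterations: int = 250,
            bmr_factor: float = 1.0) -> BMDResults:
    """Fit the BMD model suite and return the AIC-selected benchmark dose."""
    return BenchmarkDoseModel(groups, models=models, max_iterations=max_iterations,
                              bmr_factor=bmr_factor).fit()


def bmc_per_probe(groups: DoseGroups) -> float:
    """Empirical benchmark concentration at one vehicle SD.

    Returns the lowest tested concentration whose mean response deviates from
    the vehicle mean by more than one vehicle SD (up or down); NaN when no
    concentration does, or when the vehicle SD is 0 (warned).
    """
    sd0 = groups.vehicle_sd
    if sd0 == 0:
        warnings.warn("vehicle SD is 0: BMC undefined")
        return np.nan
    m0 = groups.vehicle_mean
    means = groups.group_means()
    for gix in range(1, groups.n_groups):
        if abs(means[gix] - m0) > sd0:
            return float(groups.concentrations[gix])
    return np.nan


def bmd_accumulation(bmds) -> pd.DataFrame:
    """Cumulative count of probes with a benchmark dose at or below each level.

    Only finite BMDs contribute; the curve is a monotone step function whose
    final value equals the number of defined BMDs.
    """
    vals = np.asarray([b for b in np.asarray(bmds, dtype=float).ravel() if np.isfinite(b)])
    if vals.size == 0:
        return pd.DataFrame({"concentration": [], "cumulative_count": []})
    levels = np.unique(vals)
    counts = np.searchsorted(np.sort(vals), levels, side="right")
    return pd.DataFrame({"concentration": levels, "cumulative_count": counts})
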