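"""Phenomenological mitochondrial-membrane-potential (MMP) decay kinetics.

The MMP of cells exposed to an electron-transport-chain inhibitor, measured as a
fraction of the vehicle control, is described by a single-exponential relaxation

    Psi(t) = a * exp(-t / tau) + (1 - a)

where ``a`` in [0, 1] is the maximal reduction of the MMP (chemical- and
concentration-specific) and ``tau`` > 0 is the decay time constant, shared across
all concentrations of one chemical.  Psi(0) = 1 by construction and
Psi(t) -> 1 - a as t -> infinity.

:class:`MMPDecayModel` fits this model to time-resolved fraction-of-control
intensity trajectories of one compound by weighted least squares with a shared
tau, using a seeded multi-start search.  Because ``a`` enters linearly for fixed
tau, the optimal a-vector has a closed form (clipped to [0, 1]); the search
therefore runs over tau only, with ``a`` profiled out exactly.

The module also provides Ward clustering of the fitted maximal-reduction matrix
and per-inhibitor-class ordinary least-squares regression of the summed maximal
reduction on lipophilicity (logP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.optimize
import statsmodels.api as sm

__all__ = [
    "mmp_model",
    "MMPDecayModel",
    "MMPDecayResults",
    "fit_decay",
    "cluster_a_matrix",
    "ClusterResult",
    "logp_regression",
    "LogPRegression",
]

TAU_BOUNDS = (1e-6, 1000.0)  # hours; upper box constraint on the decay constant
TAU_START_RANGE = (0.1, 100.0)  # log-uniform sampling range for tau starts


def mmp_model(t, a, tau):
    """Evaluate the MMP decay curve Psi(t) = a*exp(-t/tau) + (1 - a).

    Parameters
    ----------
    t : array_like
        Time in hours, ``t >= 0``.
    a : float
        Maximal reduction of the MMP, in [0, 1].
    tau : float
        Decay time constant in hours, strictly positive.

    Returns
    -------
    ndarray or float
        Fraction-of-control MMP; equals 1 at ``t = 0`` and approaches
        ``1 - a`` for large ``t``.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a must lie in [0, 1], got {a}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time values must be non-negative")
    out = a * np.exp(-t / tau) + (1.0 - a)
    return out if out.ndim else float(out)


@dataclass
class MMPDecayResults:
    """Fit of the shared-tau MMP decay model for one compound.

    Attributes
    ----------
    compound : str
        Compound identifier.
    a_by_concentration : dict
        Maximal MMP reduction per fitted concentration (µM -> [0, 1]).
    tau : float
        Shared decay time constant in hours.
    cost : float
        Weighted sum of squared residuals at the optimum.
    n_starts : int
        Number of tau starting values used in the multi-start search.
    converged : bool
        True if at least one local optimisation converged.
    seed : int or None
        Seed of the start-value stream.
    """

    compound: str
    a_by_concentration: dict[float, float]
    tau: float
    cost: float
    n_starts: int
    converged: bool
    seed: int | None = None
    model: "MMPDecayModel | None" = field(default=None, repr=False)

    @property
    def a_sum(self) -> float:
        """Sum of the maximal reductions over all concentrations (logP response)."""
        return float(sum(self.a_by_concentration.values()))

    def predict(self, concentration: float, t) -> np.ndarray:
        """Model curve at the fitted parameters for one concentration."""
        return mmp_model(t, self.a_by_concentration[concentration], self.tau)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"parameter": f"a[{c:g} µM]", "estimate": a}
            for c, a in sorted(self.a_by_concentration.items())
        ]
        rows.append({"parameter": "tau [h]", "estimate": self.tau})
        rows.append({"parameter": "cost (weighted SSE)", "estimate": self.cost})
        df = pd.DataFrame(rows)
        df.attrs["compound"] = self.compound
        return df

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "a_by_concentration": {str(k): v for k, v in self.a_by_concentration.items()},
            "tau": self.tau,
            "cost": self.cost,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "seed": self.seed,
        }


class MMPDecayModel:
    """Shared-tau exponential MMP decay model for one compound.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format trajectories with columns ``concentration``, ``replicate``,
        ``time_h``, ``value`` (fraction-of-control, positive).  A ``compound``
        column is optional and must be single-valued if present.
    weights : {"inverse_variance", "equal"}
        Residual weighting.  ``inverse_variance`` weights each
        (concentration, timepoint) cell by the inverse empirical variance
        across replicates, floored at the 10th percentile of the variances so
        that zero-variance cells do not receive infinite weight.

    Notes
    -----
    Missing timepoints are simply absent rows and are skipped, not
    interpolated.  Every concentration must contribute at least two distinct
    timepoints.
    """

    REQUIRED = ("concentration", "time_h", "value")

    def __init__(self, data: pd.DataFrame, weights: str = "inverse_variance"):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if weights not in ("inverse_variance", "equal"):
            raise ValueError(f"unknown weights mode {weights!r}")
        if "compound" in data.columns:
            compounds = data["compound"].unique()
            if len(compounds) > 1:
                raise ValueError(
                    "MMPDecayModel fits one compound at a time; "
                    f"got {list(compounds)}"
                )
            self.compound = str(compounds[0])
        else:
            self.compound = "compound"
        vals = data["value"].to_numpy(float)
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("values must be finite and positive")
        self.data = data
        self.weights_mode = weights
        self._prepare()

    def _prepare(self) -> None:
        df = self.data
        self.concentrations = np.sort(df["concentration"].unique())
        for c in self.concentrations:
            sub = df[df["concentration"] == c]
            if sub["time_h"].nunique() < 2:
                raise ValueError(
                    f"concentration {c} has fewer than 2 timepoints; cannot fit"
                )
        # flatten to per-observation arrays with a concentration index
        self._t = df["time_h"].to_numpy(float)
        self._y = df["value"].to_numpy(float)
        self._conc_idx = np.searchsorted(self.concentrations, df["concentration"].to_numpy(float))
        if self.weights_mode == "equal":
            self._w = np.ones_like(self._y)
        else:
            var = df.groupby(["concentration", "time_h"])["value"].var(ddof=1)
            var = var.fillna(var.median() if np.isfinite(var.median()) else 1.0)
            floor = np.nanpercentile(var.to_numpy(float), 10)
            if not np.isfinite(floor) or floor <= 0:
                # degenerate replicate structure: fall back to equal weights
                self._w = np.ones_like(self._y)
            else:
                var_floored = np.maximum(var, floor)
                key = list(zip(df["concentration"], df["time_h"]))
                self._w = (1.0 / var_floored.loc[key].to_numpy(float))

    # -- profiled inner problem ------------------------------------------------

    def _profile_a(self, tau: float) -> tuple[np.ndarray, float]:
        """Optimal a per concentration and total weighted SSE for fixed tau.

        With x = exp(-t/tau) - 1 the model is value = 1 + a*x, so the weighted
        LS optimum per concentration is a* = sum(w x r)/sum(w x^2) with
        r = value - 1, clipped to [0, 1].
        """
        x = np.exp(-self._t / tau) - 1.0
        r = self._y - 1.0
        wxx = np.bincount(self._conc_idx, self._w * x * x, len(self.concentrations))
        wxr = np.bincount(self._conc_idx, self._w * x * r, len(self.concentrations))
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(wxx > 0, wxr / np.where(wxx > 0, wxx, 1.0), 0.0)
        a = np.clip(a, 0.0, 1.0)
        resid = r - a[self._conc_idx] * x
        cost = float(np.sum(self._w * resid * resid))
        return a, cost

    def _cost_logtau(self, logtau) -> float:
        return self._profile_a(float(np.exp(np.asarray(logtau).ravel()[0])))[1]

    def fit(self, n_starts: int = 1000, seed: int | None = None) -> MMPDecayResults:
        """Multi-start weighted least-squares fit of (tau, a-vector).

        Starting values for tau are drawn log-uniformly from
        ``TAU_START_RANGE`` one at a time from a seeded stream, so the first
        ``k`` starts of a longer run are a prefix of a shorter one and the
        optimal cost is non-increasing in ``n_starts``.  Ties in cost are
        broken toward the smaller tau.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        lo, hi = np.log(TAU_START_RANGE)
        bounds = [(np.log(TAU_BOUNDS[0]), np.log(TAU_BOUNDS[1]))]
        best: tuple[float, float] | None = None  # (cost, tau)
        converged = False
        for _ in range(n_starts):
            logtau0 = rng.uniform(lo, hi)
            res = scipy.optimize.minimize(
                self._cost_logtau,
                x0=[logtau0],
                method="L-BFGS-B",
                bounds=bounds,
            )
            converged = converged or bool(res.success)
            tau = float(np.exp(res.x[0]))
            cost = float(res.fun)
            if (
                best is None
                or cost < best[0] - 1e-12 * (1 + abs(best[0]))
                or (abs(cost - best[0]) <= 1e-12 * (1 + abs(best[0])) and tau < best[1])
            ):
                best = (cost, tau)
        cost, tau = best
        a, _ = self._profile_a(tau)
        return MMPDecayResults(
            compound=self.compound,
            a_by_concentration={float(c): float(ai) for c, ai in zip(self.concentrations, a)},
            tau=tau,
            cost=cost,
            n_starts=n_starts,
            converged=converged,
            seed=seed,
            model=self,
        )


def fit_decay(
    series: pd.DataFrame,
    n_starts: int = 1000,
    seed: int | None = None,
    weights: str = "inverse_variance",
) -> MMPDecayResults:
    """Fit the shared-tau decay model to one compound's trajectories."""
    return MMPDecayModel(series, weights=weights).fit(n_starts=n_starts, seed=seed)


@dataclass
class ClusterResult:
    """Ward clustering of the compound x concentration maximal-reduction matrix."""

    a_matrix: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series  # cluster label per compound at the requested k
    k: int


def cluster_a_matrix(fits, k: int = 2) -> ClusterResult:
    """Ward-linkage hierarchical clustering of maximal MMP reductions.

    Parameters
    ----------
    fits : iterable of MMPDecayResults or pandas.DataFrame
        Either fit results (rows assembled from ``a_by_concentration``) or an
        already-assembled compound x concentration matrix.  Concentrations
        missing for a compound are imputed as 0 with a warning.
    k : int
        Number of clusters at which to cut the tree.
    """
    if isinstance(fits, pd.DataFrame):
        amat = fits.copy()
        if amat.isna().any().any():
            warnings.warn("missing a values imputed as 0 for clustering")
            amat = amat.fillna(0.0)
    else:
        rows = {f.compound: f.a_by_concentration for f in fits}
        amat = pd.DataFrame.from_dict(rows, orient="index").sort_index(axis=1)
        if amat.isna().any().any():
            warnings.warn("missing a values imputed as 0 for clustering")
            amat = amat.fillna(0.0)
    if len(amat) == 1:
        return ClusterResult(
            a_matrix=amat,
            linkage=np.empty((0, 4)),
            labels=pd.Series([1], index=amat.index),
            k=1,
        )
    Z = sch.linkage(amat.to_numpy(float), method="ward")
    k_eff = min(k, len(amat))
    labels = sch.fcluster(Z, t=k_eff, criterion="maxclust")
    return ClusterResult(a_matrix=amat, linkage=Z, labels=pd.Series(labels, index=amat.index), k=k_eff)


@dataclass
class LogPRegression:
    """OLS of summed maximal MMP reduction on logP for one inhibitor class."""

    group: str
    slope: float
    slope_se: float
    intercept: float
    r_squared: float
    n: int


def logp_regression(fits, logp: dict, groups: dict) -> dict[str, LogPRegression]:
    """Per-class OLS of sum-of-a on lipophilicity.

    The response per compound is the sum of the fitted maximal reductions over
    all concentrations; the predictor is the compound's logP.  Each inhibitor
    class (e.g. CI/CII/CIII) is fitted separately and needs at least 3
    compounds.
    """
    per_group: dict[str, list[tuple[float, float]]] = {}
    for f in fits:
        g = groups.get(f.compound)
        if g is None:
            raise ValueError(f"no group label for compound {f.compound!r}")
        if f.compound not in logp:
            raise ValueError(f"no logP value for compound {f.compound!r}")
        per_group.setdefault(g, []).append((logp[f.compound], f.a_sum))
    out = {}
    for g, pairs in per_group.items():
        if len(pairs) < 3:
            raise ValueError(
                f"group {g!r} has only {len(pairs)} compounds; need >= 3 for regression"
            )
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        X = sm.add_constant(x)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.OLS(y, X).fit()
        rsq = float(fit.rsquared)
        # an (effectively) constant response has no variance to explain;
        # OLS then reports a meaningless r^2
        if not np.isfinite(rsq) or rsq < 0 or np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
            rsq = 0.0
        rsq = min(rsq, 1.0)
        out[g] = LogPRegression(
            group=g,
            slope=float(fit.params[1]),
            slope_se=float(fit.bse[1]),
            intercept=float(fit.params[0]),
            r_squared=rsq,
            n=len(pairs),
        )
    return out
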