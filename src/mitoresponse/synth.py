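"""Seeded generators for every input the analysis pipeline consumes.

The study's raw data (time-resolved Rhodamine123 MMP trajectories, targeted
TempO-Seq count matrices, CellProfiler object tables, and the prior
co-expression module map) are not publicly deposited, so this module emulates
them with known ground truth:

* MMP trajectories are simulated from the exponential decay model
  Psi(t) = a*exp(-t/tau) + (1-a) with multiplicative lognormal noise
  (intensities are positive and ratio-scaled, so noise acts on the log scale);
* probe counts are negative-binomial (gamma-Poisson) with sample-specific
  size factors; a planted fraction of probes carries a Hill-shaped
  concentration-dependent log2 fold change restricted to the compounds each
  probe "responds to", which is what the signature set algebra assumes;
* cell tables plant a Bernoulli fraction of objects that satisfy the
  PI/GFP positivity rules exactly;
* module maps draw member genes from the probe universe with positive
  loadings and one hub per module, optionally with planted activations.

All generators are pure functions of (config, truth, seed): rerunning with
the same inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .expression import CountExperiment
from .kinetics import mmp_model
from .modules_egs import ModuleMap

__all__ = [
    "SynthConfig",
    "HillEffect",
    "GroundTruth",
    "default_ground_truth",
    "signature_ground_truth",
    "gen_mmp_timeseries",
    "gen_counts",
    "gen_cell_table",
    "gen_module_map",
    "gen_de_table",
    "default_concentrations",
]


def default_concentrations(n: int = 7, top: float = 10.0, step: float = 5.0) -> tuple:
    """Geometric concentration series ending at ``top`` µM (factor-``step``)."""
    return tuple(top / step ** k for k in reversed(range(n)))


@dataclass(frozen=True)
class SynthConfig:
    """Design parameters shared by the generators.

    Defaults mirror the emulated study design: a 7-point factor-5
    concentration series ending at 10 µM, hourly imaging over 24 h, 4
    biological replicates, and a targeted panel of a few hundred probes.
    """

    seed: int = 0
    n_compounds: int = 5
    concentrations: tuple = field(default_factory=default_concentrations)
    timepoints: tuple = tuple(range(25))
    n_replicates: int = 4
    noise_sd: float = 0.05
    n_probes: int = 500
    de_fraction: float = 0.1
    dispersion: float = 0.02
    mean_library_size: float = 300_000.0
    n_low_library: int = 0

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ValueError("concentrations must be strictly increasing and positive")
        if self.timepoints[0] != 0:
            raise ValueError("timepoints must start at 0")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_replicates < 1 or self.n_probes < 1 or self.n_compounds < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class HillEffect:
    """Concentration-dependent log2 fold change of one planted probe."""

    max_log2fc: float
    ec50: float
    slope: float
    responds_to: frozenset  # compound ids this probe reacts to

    def log2fc(self, concentration: float) -> float:
        c = float(concentration)
        if c <= 0:
            return 0.0
        return self.max_log2fc * c**self.slope / (self.ec50**self.slope + c**self.slope)


@dataclass
class GroundTruth:
    """Planted parameters the recovery tests check against.

    ``true_a`` maps (compound, concentration) to the maximal MMP reduction and
    is monotone non-decreasing in concentration per compound; ``true_tau``
    maps compound to its decay constant.  ``de_probes`` carries per-probe Hill
    effects; ``compound_annotation`` maps compound to its class label
    (CI/CII/CIII/positive_control) and activity (active/inactive/control);
    ``planted_module_activity`` holds signed module activations for the EGS
    recovery loop.
    """

    true_a: dict
    true_tau: dict
    de_probes: dict
    compound_annotation: dict = field(default_factory=dict)
    planted_module_activity: dict = field(default_factory=dict)

    def compounds(self) -> list:
        return sorted(self.true_tau)

    def to_json(self) -> str:
        payload = {
            "true_a": {f"{c}|{conc:g}": a for (c, conc), a in self.true_a.items()},
            "true_tau": self.true_tau,
            "de_probes": {p: {**asdict(e), "responds_to": sorted(e.responds_to)}
                          for p, e in self.de_probes.items()},
            "compound_annotation": self.compound_annotation,
            "planted_module_activity": self.planted_module_activity,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed), stream]))


def default_ground_truth(cfg: SynthConfig) -> GroundTruth:
    """Generic truth: monotone a(c) per compound, shared tau, Hill DE probes."""
    rng = _rng(cfg.seed, 0)
    conc = np.asarray(cfg.concentrations)
    # EC50 sampling range spans the tested concentrations, also when the
    # grid is short or degenerate
    ec_lo = np.log(conc[0] / 2)
    ec_hi = max(np.log(conc[-1] / 2), ec_lo + 0.1)
    compounds = [f"C{i + 1:02d}" for i in range(cfg.n_compounds)]
    true_a, true_tau, annotation = {}, {}, {}
    classes = ["CI", "CIII", "CII", "positive_control"]
    for i, comp in enumerate(compounds):
        amax = rng.uniform(0.3, 0.95)
        ec50 = np.exp(rng.uniform(ec_lo, ec_hi))
        h = rng.uniform(1.0, 2.0)
        for c in conc:
            true_a[(comp, float(c))] = float(amax * c**h / (ec50**h + c**h))
        true_tau[comp] = float(np.exp(rng.uniform(np.log(1.0), np.log(10.0))))
        cls = classes[i % len(classes)]
        activity = {"CI": "active", "CIII": "active", "CII": "inactive",
                    "positive_control": "control"}[cls]
        annotation[comp] = {"class_label": cls, "activity": activity}
    n_de = int(round(cfg.de_fraction * cfg.n_probes))
    de_idx = rng.choice(cfg.n_probes, size=n_de, replace=False)
    de_probes = {}
    for j in sorted(de_idx):
        de_probes[f"P{j:04d}"] = HillEffect(
            max_log2fc=float(rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0])),
            ec50=float(np.exp(rng.uniform(ec_lo, ec_hi))),
            slope=float(rng.uniform(1.0, 2.0)),
            responds_to=frozenset(compounds),
        )
    return GroundTruth(true_a=true_a, true_tau=true_tau, de_probes=de_probes,
                       compound_annotation=annotation)


def signature_ground_truth(
    cfg: SynthConfig,
    n_core: int = 10,
    n_partial: int = 10,
    n_control_responsive: int = 10,
    max_log2fc: float = 3.0,
) -> GroundTruth:
    """Truth for the signature-recovery loop, with a known planted core.

    Compounds: 2 active CI + 2 active CIII inhibitors, 1 inactive CII
    inhibitor and 1 positive stress-model control.  ``n_core`` probes respond
    to every active compound and nothing else (the planted core signature);
    ``n_partial`` respond to a strict subset of the actives; the rest respond
    to the control or the inactive compound and must be excluded by the set
    algebra.  The planted core is stored under ``de_probes`` as the probes
    whose ``responds_to`` equals the full active set.
    """
    rng = _rng(cfg.seed, 5)
    conc = np.asarray(cfg.concentrations)
    compounds = ["CI_a", "CI_b", "CIII_a", "CIII_b", "CII_a", "CTRL_a"]
    annotation = {
        "CI_a": {"class_label": "CI", "activity": "active"},
        "CI_b": {"class_label": "CI", "activity": "active"},
        "CIII_a": {"class_label": "CIII", "activity": "active"},
        "CIII_b": {"class_label": "CIII", "activity": "active"},
        "CII_a": {"class_label": "CII", "activity": "inactive"},
        "CTRL_a": {"class_label": "positive_control", "activity": "control"},
    }
    actives = frozenset(c for c in compounds if annotation[c]["activity"] == "active")
    true_a, true_tau = {}, {}
    for comp in compounds:
        for c in conc:
            true_a[(comp, float(c))] = 0.0
        true_tau[comp] = 3.0
    needed = n_core + n_partial + n_control_responsive
    if needed > cfg.n_probes:
        raise ValueError("n_probes too small for the requested planted structure")
    probes = [f"P{j:04d}" for j in range(cfg.n_probes)]
    de_probes = {}
    ec50 = float(np.median(conc))

    def effect(responds_to):
        return HillEffect(
            max_log2fc=float(max_log2fc * rng.choice([-1.0, 1.0])),
            ec50=ec50,
            slope=1.5,
            responds_to=frozenset(responds_to),
        )

    k = 0
    for _ in range(n_core):
        de_probes[probes[k]] = effect(actives)
        k += 1
    for _ in range(n_partial):
        subset = rng.choice(sorted(actives), size=rng.integers(1, len(actives)), replace=False)
        de_probes[probes[k]] = effect(subset)
        k += 1
    for _ in range(n_control_responsive):
        target = rng.choice(["CTRL_a", "CII_a"])
        de_probes[probes[k]] = effect(set(actives) | {target})
        k += 1
    return GroundTruth(true_a=true_a, true_tau=true_tau, de_probes=de_probes,
                       compound_annotation=annotation)


def planted_core(truth: GroundTruth) -> set:
    """Probes planted to respond to every active compound and nothing else."""
    actives = {c for c, ann in truth.compound_annotation.items() if ann["activity"] == "active"}
    return {
        p for p, e in truth.de_probes.items()
        if set(e.responds_to) == actives
    }


def gen_mmp_timeseries(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate fraction-of-control MMP trajectories from the decay model.

    Long format: compound, concentration, replicate, time_h, value.  Each
    trajectory is Psi(t; a, tau) times lognormal noise with sigma
    ``cfg.noise_sd``; noiseless simulation reproduces the model exactly.
    """
    rng = _rng(cfg.seed, 1)
    t = np.asarray(cfg.timepoints, dtype=float)
    rows = []
    for comp in truth.compounds():
        tau = truth.true_tau[comp]
        for conc in cfg.concentrations:
            key = (comp, float(conc))
            if key not in truth.true_a:
                raise ValueError(f"ground truth misses a value for {key}")
            a = truth.true_a[key]
            curve = mmp_model(t, a, tau)
            for rep in range(1, cfg.n_replicates + 1):
                if cfg.noise_sd > 0:
                    noise = np.exp(rng.normal(0.0, cfg.noise_sd, size=len(t)))
                else:
                    noise = 1.0
                rows.append(pd.DataFrame({
                    "compound": comp,
                    "concentration": float(conc),
                    "replicate": rep,
                    "time_h": t,
                    "value": curve * noise,
                }))
    return pd.concat(rows, ignore_index=True)


def gen_counts(cfg: SynthConfig, truth: GroundTruth) -> CountExperiment:
    """Simulate a probe x sample negative-binomial count experiment.

    Samples: ``n_replicates`` vehicle wells plus one well per compound x
    concentration x replicate.  Baseline probe means are lognormal; planted
    probes get their mean multiplied by 2^log2fc(concentration) in samples of
    compounds they respond to.  Counts are gamma-Poisson with dispersion
    ``cfg.dispersion`` (variance mu + dispersion*mu^2) and lognormal
    sample-specific size factors.  ``cfg.n_low_library`` samples are scaled to
    fall below the 100k-read QC threshold to exercise the library filter.
    """
    rng = _rng(cfg.seed, 2)
    probes = [f"P{j:04d}" for j in range(cfg.n_probes)]
    base = np.exp(rng.normal(np.log(200.0), 1.0, size=cfg.n_probes))
    compounds = truth.compounds()
    sample_ids, meta_rows, mean_cols = [], [], []

    def add_sample(sid, compound, conc, condition, cls, act):
        mu = base.copy()
        if compound is not None and conc > 0:
            for j, p in enumerate(probes):
                eff = truth.de_probes.get(p)
                if eff is not None and compound in eff.responds_to:
                    mu[j] = mu[j] * 2.0 ** eff.log2fc(conc)
        sample_ids.append(sid)
        meta_rows.append({
            "sample": sid, "compound": compound or "vehicle",
            "concentration": conc, "time_h": 24.0,
            "condition": condition, "class_label": cls, "activity": act,
        })
        mean_cols.append(mu)

    for rep in range(1, cfg.n_replicates + 1):
        add_sample(f"vehicle_r{rep}", None, 0.0, "vehicle", "vehicle", "control")
    for comp in compounds:
        ann = truth.compound_annotation.get(comp, {"class_label": "CI", "activity": "active"})
        for conc in cfg.concentrations:
            for rep in range(1, cfg.n_replicates + 1):
                add_sample(
                    f"{comp}_c{conc:g}_r{rep}", comp, float(conc),
                    f"{comp}@{conc:g}", ann["class_label"], ann["activity"],
                )

    M = np.column_stack(mean_cols)  # probes x samples
    n_samples = M.shape[1]
    sf = np.exp(rng.normal(0.0, 0.2, size=n_samples))
    lib_scale = cfg.mean_library_size / M.sum(axis=0)
    M = M * sf * lib_scale
    if cfg.n_low_library > 0:
        low = rng.choice(n_samples, size=min(cfg.n_low_library, n_samples), replace=False)
        M[:, low] *= 50_000.0 / cfg.mean_library_size
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, M / shape)
    counts = rng.poisson(lam)
    exp = CountExperiment(
        counts=pd.DataFrame(counts, index=probes, columns=sample_ids),
        samples=pd.DataFrame(meta_rows).set_index("sample"),
    )
    return exp


def gen_cell_table(
    cfg: SynthConfig,
    positive_fraction: float,
    n_cells: int = 2000,
    well: str = "A1",
    condition: str = "treated",
) -> pd.DataFrame:
    """Simulate a per-object imaging feature table with planted positives.

    Each object is positive with probability ``positive_fraction``
    (independent Bernoulli draws).  Positives satisfy both endpoint rules
    exactly: PI overlap between 15% and 60% of the nuclear area (> 10%) and
    integrated GFP at 2.5-4x the negative mean (>= 2x the vehicle reference,
    which equals the negative-population mean of 1000 a.u.).
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = _rng(cfg.seed, 3)
    pos = rng.random(n_cells) < positive_fraction
    area = rng.uniform(80.0, 200.0, size=n_cells)
    overlap_ratio = np.where(
        pos, rng.uniform(0.15, 0.60, size=n_cells), rng.uniform(0.0, 0.08, size=n_cells)
    )
    gfp = np.where(
        pos,
        rng.uniform(2500.0, 4000.0, size=n_cells),
        rng.uniform(500.0, 1500.0, size=n_cells),  # mean 1000 = vehicle reference
    )
    em_408 = rng.uniform(80.0, 120.0, size=n_cells)
    em_488 = em_408 * rng.uniform(0.8, 1.2, size=n_cells)
    return pd.DataFrame({
        "nucleus_area": area,
        "pi_overlap_area": area * overlap_ratio,
        "gfp_integrated": gfp,
        "em_408": em_408,
        "em_488": em_488,
        "well": well,
        "condition": condition,
    })


def gen_module_map(
    n_modules: int,
    genes_per_module: int,
    truth: GroundTruth | None = None,
    probe_universe=None,
    seed: int = 0,
    overlapping: bool = False,
) -> ModuleMap:
    """Simulate a prior co-expression module map over the probe universe.

    Modules are disjoint by default (overlapping with ``overlapping=True``),
    loadings are uniform in (0.3, 1], and the member with the largest loading
    is flagged as the module's hub gene.
    """
    if probe_universe is None:
        if truth is None:
            raise ValueError("need a probe universe or a ground truth")
        probe_universe = sorted({p for p in truth.de_probes})
    probe_universe = list(probe_universe)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 4]))
    if not overlapping and n_modules * genes_per_module > len(probe_universe):
        raise ValueError(
            f"{n_modules} disjoint modules of {genes_per_module} genes exceed the "
            f"universe of {len(probe_universe)} probes"
        )
    if genes_per_module > len(probe_universe):
        raise ValueError("genes_per_module exceeds the probe universe")
    pool = rng.permutation(probe_universe)
    rows = []
    for m in range(n_modules):
        if overlapping:
            genes = rng.choice(probe_universe, size=genes_per_module, replace=False)
        else:
            genes = pool[m * genes_per_module: (m + 1) * genes_per_module]
        loadings = rng.uniform(0.3, 1.0, size=genes_per_module)
        hub = int(np.argmax(loadings))
        for i, g in enumerate(genes):
            rows.append({"module": f"M{m + 1:02d}", "gene": g,
                         "loading": float(loadings[i]), "is_hub": i == hub})
    return ModuleMap(pd.DataFrame(rows))


def gen_de_table(
    modules: ModuleMap,
    activity: dict,
    conditions=("treated",),
    noise_sd: float = 0.5,
    seed: int = 0,
    n_background: int = 100,
) -> pd.DataFrame:
    """Simulate a DE table with planted module activations for EGS recovery.

    Member probes of a module with planted activity ``s`` get log2fc drawn
    from N(s, noise_sd); background probes and members of inactive modules
    get N(0, noise_sd).  Standard errors are 1, so z = log2fc and the
    loading-weighted module mean recovers ``s``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    shift = {}
    for m in modules.modules:
        s = activity.get(m, 0.0)
        for g in modules.members(m)["gene"]:
            shift[g] = shift.get(g, 0.0) + s
    background = [f"B{j:04d}" for j in range(n_background)]
    rows = []
    for cond in conditions:
        for g in list(shift) + background:
            rows.append({
                "probe": g,
                "condition": cond,
                "log2fc": shift.get(g, 0.0) + rng.normal(0.0, noise_sd),
                "se": 1.0,
                "p_value": np.nan,
                "padj": np.nan,
                "trend_p": np.nan,
            })
    return pd.DataFrame(rows)
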