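# mitoresponse

Dose- and time-resolved analysis of cellular responses to mitochondrial
electron-transport-chain (ETC) inhibitors: mitochondrial-membrane-potential
(MMP) decay kinetics, permutation trend testing and benchmark-dose estimation
for targeted transcriptomics, derivation of an ETC-inhibitor gene signature by
set algebra, projection of expression changes onto prior co-expression
modules, and high-content-imaging endpoint rules. A seeded synthetic-data
generator emulates every input with known ground truth, so each method's
recovery behaviour is testable end to end.

## Who it is for

Toxicologists and computational biologists analysing concentration/time
matrices of live-cell imaging readouts (Rhodamine123 MMP, propidium-iodide
death staining, GFP stress reporters, FRET ATP biosensors) together with
targeted RNA-seq (TempO-Seq-style) count data from the same exposures.

## The models and statistics at the core

**MMP decay kinetics.** Fraction-of-control MMP trajectories follow

    Ψ(t) = a·exp(−t/τ) + (1 − a),        Ψ(0) = 1,  Ψ(∞) = 1 − a

with `a ∈ [0, 1]` the maximal MMP reduction (chemical- and
concentration-specific) and `τ > 0` the decay time constant, shared across all
concentrations of one chemical. `MMPDecayModel.fit()` minimises the weighted
sum of squared residuals jointly over (τ, a-vector) with a seeded multi-start
search; because `a` enters linearly for fixed τ, the inner problem is solved
in closed form. Downstream, the fitted a-matrix feeds Ward hierarchical
clustering and per-inhibitor-class OLS of Σa on lipophilicity (logP).

**Concentration–response statistics.** `williams_test` computes a
Williams-type trend statistic T = (amalgamated mean of the highest dose group
− vehicle mean)/pooled SE, using isotonic (pool-adjacent-violators)
amalgamation in both monotone directions, with p-values from label
permutation. `BenchmarkDoseModel` fits the standard suite (power, linear,
2nd-order polynomial, Hill, exponential 2–5), selects by
AIC = n·ln(SSE/n) + 2k, and inverts the best model at a benchmark response of
one vehicle standard deviation; `bmc_per_probe` is the empirical analogue
(lowest tested concentration deviating > 1 vehicle SD).

**Signature set algebra.** Per-condition differentially expressed probe sets
(padj < 0.05, |log2FC| > 0.58, trend p < 0.05; all strict) are combined as:
union over active inhibitors → minus anything touched by inactive inhibitors
or positive stress-model controls → intersected over every individual active
inhibitor → optionally refined by |log2FC| > 2 or a curated mitochondria
link.

**Module eigengene scores.** A treatment's per-gene z-scores (log2FC/SE) are
averaged per predefined co-expression module, weighted by the module
loadings: EGS_m = Σ w_g z_g / Σ w_g over the measured members, with coverage
reported per module.

## Worked example

Simulate one compound's MMP trajectories (7-point factor-5 concentration
series up to 10 µM, 4 replicates, hourly imaging over 24 h, 2% multiplicative
noise) and fit the shared-τ decay model:

```python
import mitoresponse as mr

cfg = mr.SynthConfig(seed=42, n_compounds=1, noise_sd=0.02)
truth = mr.default_ground_truth(cfg)
ts = mr.gen_mmp_timeseries(cfg, truth)
fit = mr.fit_decay(ts, n_starts=100, seed=0)
print(fit.summary().to_string(index=False))
```

```
          parameter   estimate
      a[0.00064 µM]   0.001143
       a[0.0032 µM]   0.022814
        a[0.016 µM]   0.280707
         a[0.08 µM]   0.735024
          a[0.4 µM]   0.799401
            a[2 µM]   0.803356
           a[10 µM]   0.803470
            tau [h]   4.987444
cost (weighted SSE) 732.160067
```

The maximal reduction rises sigmoidally with concentration and saturates at
`a ≈ 0.80` — the MMP drops to about 20% of control at high exposure — while
the shared decay constant `τ ≈ 4.99 h` matches the planted value (4.98 h;
planted top-concentration a = 0.803). The cost is the weighted SSE over all
7 × 25 × 4 observations.

The full pipeline (simulate → QC → normalize → trend test → differential
expression → signature → module projection → imaging endpoints) runs from the
shell:

```sh
mitoresponse run --out-dir demo_run --seed 7
```

and writes per-stage tables plus a `manifest.json` recording seeds and the
signature funnel (probes affected by any active inhibitor → specific to
actives → shared by all actives).

## Layout

- `src/mitoresponse/kinetics.py` — decay model, shared-τ fitting, clustering, logP regression
- `src/mitoresponse/dose_response.py` — Williams trend test, BMD/BMC
- `src/mitoresponse/expression.py` — count QC, normalization, DE stand-in, signature algebra
- `src/mitoresponse/modules_egs.py` — eigengene-score projection
- `src/mitoresponse/imaging.py` — per-object endpoint rules
- `src/mitoresponse/synth.py` — seeded generators with ground truth
- `src/mitoresponse/pipeline.py`, `cli.py` — orchestration and the `mitoresponse` command
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
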