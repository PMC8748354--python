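# Methods

## MMP decay model

Fraction-of-control MMP trajectories are modelled as a single-exponential
relaxation Ψ(t) = a·exp(−t/τ) + (1−a). The model is phenomenological: it
assumes the inhibitor acts immediately at full strength, that the MMP decays
toward a compound/concentration-specific plateau 1−a, and that the decay rate
τ is a property of the chemical alone (shared across its concentrations).
Ψ(0) = 1 holds structurally for every parameter pair, which is why
fraction-of-control normalization (dividing by matched vehicle wells) is the
expected input scale.

### Fitting

One compound's concentrations are fitted jointly by weighted least squares
over (τ, a-vector). Two decisions matter:

- **Weights.** Each (concentration, timepoint) cell is weighted by the
  inverse empirical variance across replicates, floored at the 10th
  percentile of the variances so near-zero-variance cells cannot dominate.
  An equal-weights mode is available (`weights="equal"`). The choice affects
  the cost surface but not noiseless recovery.
- **Profiling.** For fixed τ, the model is linear in each concentration's
  `a` (value = 1 + a·(e^{−t/τ}−1)), so the optimal a-vector has a closed
  form, clipped to the box [0, 1]. The multi-start search therefore runs
  over τ only: starting values are drawn log-uniformly from [0.1, 100] h,
  one at a time from a seeded stream (so the best cost is non-increasing in
  `n_starts` and any prefix of a longer run is reproducible), each followed
  by L-BFGS-B on log τ with box constraint τ ∈ (0, 1000] h. This is exactly
  equivalent to the joint multi-start over (τ, a) it replaces. Equal-cost
  ties break toward the smaller τ.

A flat trajectory at 1.0 is fitted as a = 0 at the boundary with zero cost
(τ is then unidentified; the reported value is whatever start converged
first, and the `a`-vector is the meaningful output). `n_starts` defaults to
1000 for protocol fidelity; because the profiled cost is a smooth 1-D
function of τ, a few dozen starts already locate the global optimum, and the
test suite uses 25–100.

### Clustering and logP regression

The compound × concentration a-matrix is clustered with Ward linkage
(scipy); missing cells are imputed as 0 with a warning, since an unfitted
concentration is indistinguishable from "no effect" for potency grouping.
Per inhibitor class, the summed maximal reduction Σ_c a(c) is regressed on
logP by OLS (statsmodels); at least 3 compounds per class are required, and
a constant response reports slope 0 with r² = 0.

## Williams trend test

The statistic is T = (amalgamated mean of the highest dose group − vehicle
mean)/SE, where the amalgamated means are the weighted isotonic regression
of the treated group means (weights = group sizes), the pooled within-group
variance uses n − K degrees of freedom, and SE = s·√(1/n_top + 1/n_vehicle).
Both monotone directions are evaluated and the larger |T| is reported with
its direction. Significance comes from permuting sample labels:
p = (1 + #{|T*| ≥ |T|})/(1 + B), which is exact-level by construction.

The isotonic value at the top group equals the extremal suffix-weighted-mean
(max over suffixes for a non-decreasing fit, min for non-increasing). The
batch implementation uses this identity to vectorise over probes and
permutations — all probes of one compound share the design, so group sums
for every permutation are computed as one matrix product. The identity is
cross-checked against the pool-adjacent-violators route in the tests.

Degenerate inputs: identical values give T = 0, p = 1; zero pooled variance
with unequal means gives an infinite statistic and the permutation floor
p = 1/(B+1).

## Benchmark dose and benchmark concentration

Eight parametric curves (power, linear, 2nd-order polynomial, Hill,
exponential 2–5 in the US-EPA-style parameterization) are fitted to the
per-sample responses by bounded least squares (`scipy.curve_fit`, trf, with
an evaluation budget derived from `max_iterations = 250`). Models with at
least as many parameters as concentration groups are skipped. Selection is
by AIC = n·ln(SSE/n) + 2k (additive constants cancel in comparison). The
benchmark response is `bmr_factor` (default 1) times the vehicle standard
deviation; the BMD is the lowest concentration where |f(c) − f(0)| reaches
the BMR, found on a log grid refined by Brent's method. BMDs below one tenth
of the lowest tested concentration or above the highest are flagged
extrapolated. A zero vehicle SD is an error (the benchmark response is
undefined), and data that never reach the BMR yield NaN.

Profile-likelihood lower bounds (BMDL) are not computed; the downstream
analyses only consume the point BMD.

The empirical benchmark concentration (`bmc_per_probe`) needs no model: it
is the lowest tested concentration whose group mean deviates from the
vehicle mean by more than one vehicle SD in either direction.

## Transcriptomics processing and the signature

- **QC.** Samples with library size strictly below 100,000 reads are
  removed (logged); removing everything is a hard error.
- **Normalization** is canonical median-of-ratios: per-sample size factor =
  median over universally expressed probes of count/probe-geometric-mean;
  normalized = count/size factor. Size factors are only defined up to a
  common scale: scaling one sample by k multiplies its factor *relative to
  the others* by k and preserves relative expression, which is what the
  tests assert.
- **Differential test.** A deliberate stand-in, not a negative-binomial GLM:
  log2FC = log2((mean normalized treated + 0.5)/(mean normalized vehicle +
  0.5)) and p from Welch's t on log2(normalized + 0.5), BH-adjusted per
  condition. The 0.5 pseudo-count bounds fold changes of near-zero probes.
  Any externally computed DE table in the same schema (probe, condition,
  log2fc, se, p_value, padj, trend_p) can be substituted; everything
  downstream is agnostic to the test's origin.
- **DEG filter.** padj < 0.05 AND |log2FC| > 0.58 AND trend p < 0.05, all
  strict; a missing trend p fails the filter.
- **Set algebra.** With per-treatment DEG sets and activity/class labels
  (labels are caller-supplied metadata, never inferred): any_active = union
  over actives; active_not_control removes every probe seen in an inactive
  or positive-control treatment; core intersects over each individual
  active treatment. `collapse="compound"` unions a compound's conditions
  first, so "every active inhibitor" means every compound rather than every
  compound×concentration cell. Refinement keeps core probes with max
  |log2FC| > 2 over actives or a curated mitochondria-link flag (the
  curation is an input).

## Module eigengene scores

EGS_m = Σ w_g z_g / Σ w_g over a module's measured members, with w the
module loadings (a plain-mean mode exists) and z = log2FC/SE per condition,
falling back to per-condition standardized log2FC when no SE is available.
The upstream module definitions do not publish their exact eigengene
weighting, so both modes are first-class and tested; the projection is
linear in z either way, and pure-noise z gives mean-0 scores with variance
Σw²/(Σw)². Unmeasured members are dropped (coverage records the measured
fraction); a module with no measured member scores NaN at coverage 0.
Heatmap selection keeps modules with max |EGS| ≥ 2 and orders them by
average-linkage clustering on Pearson correlation distance.

## Imaging endpoints

Per-object rules on already-segmented feature tables: PI-positive when
overlap/nucleus area > 0.10 (strict, per the rule's wording "larger than");
GFP-positive when integrated intensity ≥ 2× the vehicle mean (the boundary
is ambiguous in prose, so inclusivity is the documented default and
configurable); FRET ratio = emission 488/emission 408 by default
(acceptor/donor for a 408-excited probe; the orientation is configurable
because conventions differ); ATP luminescence is divided by the imaged
nuclear count; kinetic readouts are summarised as geometric means over
replicates divided by the matched vehicle geometric mean. Whether the GFP
vehicle reference is per-plate or per-experiment is the caller's choice —
it is passed in, not computed.

## Synthetic data

The generators emulate the study design: a 7-point factor-5 concentration
series ending at 10 µM, hourly sampling over 24 h, 4 biological replicates,
and a targeted panel of a few hundred probes.

- **MMP trajectories** are Ψ(t)·lognormal noise. Noise is multiplicative
  because intensities are positive and ratio-scaled; σ defaults to 0.05
  (replicate scatter of a few percent, typical of live-cell intensity
  ratios). The replicate-to-replicate variance of the emulated assay is not
  published anywhere, so these magnitudes are chosen for testability.
- **Counts** are gamma-Poisson (negative binomial, variance μ + φμ²) with
  lognormal size factors (σ = 0.2) and mean library size 300,000 reads.
  The dispersion default is φ = 0.02, the low biological variability of
  cell-line replicates on a high-count targeted panel. Planted probes carry
  a Hill-shaped log2FC in the compounds they respond to; the
  signature-scenario truth plants probes responding to all active
  compounds (the core), to strict subsets, and to the inactive/control
  compounds, so every branch of the set algebra is exercised.
- **Cell tables** plant positives as independent Bernoulli draws; positives
  satisfy both positivity rules with margin, negatives with margin on the
  other side, so threshold boundary behaviour is tested separately with
  constructed tables.
- **Module maps** draw disjoint member sets with loadings in (0.3, 1] and
  flag the largest loading as hub.

What passing these tests shows — and does not. The generators implement the
same structural assumptions the analysis makes (exponential decay, monotone
Hill dose–response, NB counts). Recovery results therefore validate the
estimation and set machinery, not the biological adequacy of those
assumptions; real data add probe-level dispersion heterogeneity, batch
structure, and non-monotone responses that are out of scope here.

## Problem sizes in the test suite

Simulation-based checks run at deliberately compact sizes: 50 seeds for
parameter-recovery and model-selection loops, 1000 null probes × 2000
permutations for trend-test calibration, 60-probe panels for the end-to-end
signature loop, and 25–100 τ starts per decay fit (sufficient for the
smooth 1-D profiled cost). These sizes give stable pass/fail behaviour at
the stated tolerances.

## Known limitations

- The differential test is a stand-in; effect sizes and error control on
  real overdispersed counts belong to a proper NB GLM, supplied externally.
- The Williams permutation test assumes exchangeability of samples across
  dose groups under the null (no plate/batch strata).
- The BMD suite reports point estimates only, without model averaging or
  confidence bounds.
- Eigengene weighting is a documented convention, not a reconstruction of
  the upstream module definitions' exact formula.
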