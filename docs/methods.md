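# Methods

## Generative model

The synthetic cohort is drawn from a linear stochastic (multivariate
Ornstein–Uhlenbeck) gene network

    dx = A(p) x dt + S dW,   Q = S Sᵀ,   A(p) = A₀ + p·B,

the canonical linearization of a dynamical system near a codimension-one
bifurcation. DNB theory is itself a statement about this linearized regime —
rising variance and correlation of a module are consequences of one drift
eigenvalue approaching zero — so an OU system is the weakest model that
exhibits exactly the phenomenon the detector targets, with no extra
mechanism that could smuggle in signal.

Construction (all defaults in parentheses):

- `A₀ = −I`: unit self-degradation for every gene.
- `B` is zero outside a planted module of `dnb_size` (10) genes. Within the
  module it has uniform symmetric couplings `intra_coupling / dnb_size` off
  the diagonal plus a uniform diagonal increment chosen so that the leading
  eigenvalue of `A(p)` equals `−(1 − p)` exactly. The control parameter is
  therefore directly interpretable: the distance to the stability boundary
  is `1 − p`.
- `Q = I` (unit diffusion). Stationary per-gene variances are then O(1)
  (baseline 0.5), so the default measurement noise contributes < 2% of the
  variance.
- Baseline expression `μ ~ N(8, 1)` per gene, log2-microarray-like
  intensities, drawn from the model seed.
- Stage schedule `p = (0.1, 0.3, 0.5, 0.7, 0.95)`; the maximal-`p` stage is
  the planted pre-disease stage.
- `intra_coupling = 1.0`. This value is pinned by a monotonicity
  requirement: the module's non-dominant drift directions have eigenvalue
  `−1 + p(1 − c)` for coupling `c`, so for `c` much above 1 their variance
  shrinks with `p` and the total fluctuation `trace Σ(p)` would dip before
  rising. At `c = 1` those directions stay exactly neutral and every
  direction's stationary variance is nondecreasing in `p` — total
  fluctuation rises monotonically toward the transition, the behavior the
  early-warning premise assumes. At the critical stage the module then shows
  within-module |r| ≈ 0.65 and a per-gene sd fold ≈ 1.7 over the first
  stage.
- A `destabilize="global"` variant spreads the same diagonal increment over
  all genes; with zero coupling this gives a fully exchangeable null model
  (no distinguished module) with the identical leading eigenvalue — used to
  check that the intervention ranking confers no advantage when there is
  nothing to find.

**Sampling.** Stages are i.i.d. draws from the exact stationary law
`N(μ, Σ(p))` — `Σ(p)` solves the continuous Lyapunov equation via
Bartels–Stewart, and draws use its eigendecomposition square root — plus
i.i.d. per-gene Gaussian measurement noise (sd 0.1). Exact stationary
sampling is used instead of trajectory integration for speed and exactness;
an Euler–Maruyama integrator is retained purely as an independent test
oracle (pooling independent chains so its Monte Carlo error is ~1%, inside
the 2% comparison bands). A master seed spawns per-stage child seeds by the
fixed rule `(seed · 1 000 003 + stage_index) mod 2³¹`, so a series is a pure
function of its seed.

The default cohort (500 genes × 8 samples × 5 stages) is deliberately
HDLSS. What the generator does **not** emulate: count-based (RNA-seq-like)
noise, normalization artifacts, batch effects, nonlinear saturation, or
dynamics beyond the stability boundary. Passing tests therefore demonstrate
correctness of the statistics and the recovery behavior attainable under a
clean Gaussian HDLSS cohort — not robustness to real microarray pathology.

## Detection

Per stage: per-gene sample sd (`ddof=1`) and absolute Pearson correlations
on values exactly as given (a `log2(x+1)` transform is opt-in, `--log2`).
Constant genes are masked, not dropped, keeping gene indexing stable across
stages; constancy is detected by zero range so float dust in the mean cannot
leak a constant gene into the correlation matrix.

Candidates are genes whose max-over-stages sd is ≥ `sd_fold_min` (1.5) times
their first-stage sd (kept if the reference sd is zero but the max is
positive). Candidates are clustered per stage by average-linkage
hierarchical clustering on distance `1 − |r|`, cut at `1 − corr_link_min`
(0.4); singletons are dropped; ties in cluster ordering and in all argmaxes
are broken deterministically (size, then smallest gene index; earlier stage
preferred — an earlier warning is the more useful one).

The composite index `I = sd_in · r_in / max(r_out, ε)` (ε = 1e−6 guards
modules with no measurable outside correlation) is evaluated for every
cluster; the best cluster per stage and the argmax stage give the result. A
peak is flagged significant when it is at least `peak_ratio_min` (2.0) times
the median of the other stages' best indices. This ratio rule is a
deliberate stand-in for a permutation test; on HDLSS data it is
conservative, because spurious clusters of high-|r| noise pairs keep the
off-peak indices high (null mean |r| ≈ 0.31 at n = 8). The i.i.d.-noise null
simulation in the test suite confirms the false-positive rate is low.

## Intervention ranking and validation

The sample covariance of the pre-disease stage (genes as variables, column
mean centering, `n − 1`) is eigenanalyzed — covariance, not correlation, by
design; a standardize-first flag exists but defaults off. In the HDLSS
regime the leading eigenpair comes from the thin SVD of the centered data
without forming the p × p matrix; the dense path and the SVD path agree to
solver precision and both are exercised in tests. Eigenvector sign is fixed
by making the largest-magnitude entry nonnegative (lowest index on ties);
ranking ties break lexicographically by gene id. A relative eigengap below
5% raises a warning rather than an error — HDLSS spectra are legitimately
near-degenerate in the tail.

Selection is fixed `k = 10` by default, with a largest-gap heuristic
(`--select gap`) as the documented alternative, since the choice of cutoff
on an index-vs-rank plot is inherently a judgment call. Biotype filtering
removes excluded classes (default `{lncRNA}`) order-preservingly; genes
missing from the annotation are retained with a warning by default.

Simulated intervention adds self-degradation `A_ii ← A_ii − c` to each
target — magnitude-only stabilization, because the eigenvector determines
which genes matter but not the direction of an effective perturbation — and
reports leading drift eigenvalue and stationary-variance traces before vs
after. A zero-strength intervention is an exact no-op by construction. The
top-k set is benchmarked against uniformly random k-sets by the fraction
whose post-intervention total variance is worse; ties (exact by symmetry in
exchangeable models) count one half, so an uninformative ranking scores 0.5
and the degenerate k = n case returns 0.5 by the same convention.

## Numerical choices and degenerate inputs

- Lyapunov solutions are symmetrized and verified to residual ≤ 1e−8
  (measured ~1e−16); stability is checked before solving and a
  non-stationary system raises a dedicated error.
- Correlation magnitudes are clipped to [0, 1] against round-off.
- Fewer than 3 samples per stage, fewer than 2 stages, one-sample
  covariances, asymmetric matrices, out-of-range `k`, negative rates and
  empty schedules all raise typed errors at the boundary where the quantity
  stops being defined; one-sample stages are legal for the generator itself.
- TSV round-trips are exact at 12 significant digits; parsers report the
  offending line.

## Replicate-level behavior and limitations

Under the default HDLSS conditions the workflow's single-run worked example
recovers the planted stage and module, but replicate averages are limited by
small-sample noise, and the test suite states those limits honestly rather
than hiding them:

- Stage recovery across seeds is ~40–60%, not near-certain. Two structural
  effects cap it: the best spurious cluster's index (selection bias over
  many noise clusters whose pairwise |r| can reach ~0.95 at n = 8) overlaps
  the planted cluster's index distribution, and the planted module's
  sd — driven by a single shared soft mode — fluctuates with one χ²₇ draw
  per stage (CV ≈ 53%).
- The sampled dominant eigenvector aligns only partially with the planted
  direction: with spike-to-bulk ratio ≈ 20 and aspect ratio γ = 500/8,
  spiked-covariance asymptotics give squared alignment ≈ 0.19, which
  translates to a mean top-10 overlap of ~60–70% (the analytic eigenvector,
  by contrast, puts essentially 100% of its mass on the module).

Larger per-stage sample sizes, larger effect amplitudes, or schedules
closer to the boundary would lift both numbers; the defaults keep the
HDLSS character of the intended application instead.
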