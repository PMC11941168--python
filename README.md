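# dnbkit

Dynamical network biomarker (DNB) analysis for stage-wise gene-expression
data: detect the **pre-disease state** — the unstable regime just before a
critical transition from a healthy to a disease attractor — and rank genes
for intervention by the dominant eigenvector of the pre-disease sample
covariance matrix.

The package is aimed at systems-biology researchers working with
high-dimensional low-sample-size (HDLSS) expression cohorts: thousands of
genes profiled at a handful of ordered stages (ages, time points) with few
samples per stage. Because such cohorts are rarely public, `dnbkit` ships a
first-class synthetic-data generator with planted ground truth, so the whole
workflow is testable end to end.

## The model and the statistics

**Generative model.** Expression deviations follow a multivariate
Ornstein–Uhlenbeck system

```
dx = A(p) x dt + S dW,     Q = S Sᵀ,     A(p) = A₀ + p·B
```

where the control parameter `p ∈ [0, 1)` pushes a small planted gene module
(the DNB) toward the stability boundary: the leading eigenvalue of `A(p)` is
exactly `−(1 − p)`. The stationary covariance `Σ(p)` solves the Lyapunov
equation `A(p)Σ + ΣA(p)ᵀ + Q = 0`; stages are i.i.d. draws from
`N(μ, Σ(p))` plus measurement noise.

**Detection.** For each stage the detector computes per-gene standard
deviations and absolute Pearson correlations, prefilters genes by sd fold
increase, clusters candidates by average linkage on `1 − |r|`, and scores
each cluster with the composite early-warning index

```
I = sd_in · r_in / max(r_out, ε)
```

(`sd_in` = members' mean sd, `r_in` = mean within-module |r|, `r_out` = mean
module-to-outside |r|). The stage whose best cluster maximizes `I` is the
pre-disease stage.

**Intervention ranking.** With `Σ̂` the sample covariance of the pre-disease
stage (genes × genes, computed via SVD of the centered data in the HDLSS
regime), the per-gene *intervention index* is `|v₁ᵢ|`, the absolute loading
on the dominant eigenvector `v₁` of `Σ̂`. The top-k genes (default k = 10)
are selected, optionally filtered by biotype (default: drop lncRNAs), and
validated in silico by adding self-degradation `A_ii ← A_ii − c` to the
targets and confirming reduced total stationary variance and a more negative
leading drift eigenvalue. Because the index cannot tell suppression from
promotion, only magnitude (stabilizing) interventions are simulated.

## Worked example

```sh
dnbctl run --config configs/demo.yaml --out demo_run
```

simulates 500 genes with a planted 10-gene module over stages
`p = 0.1, 0.3, 0.5, 0.7, 0.95` (8 samples each, seed 42), then detects,
ranks, filters and intervenes. It prints:

```
[simulate] 500 genes, 10-gene DNB, 5 stages, 8 samples/stage, seed 42
[detect] pre-disease stage stage4 (index 3.09, significant=False, 9 members)
[rank] top gene g0006 (index 0.225); 10 selected
[intervene] total variance 259.5 -> 248.9; beats 100% of random sets
detected stage stage4 (significant=False); selected: g0006, g0004, g0000, g0007, g0002, g0008, g0009, g0003, g0005, g0001
```

Reading the numbers: the composite index per stage is
`{stage0: 2.05, stage1: 2.44, stage2: 2.22, stage3: 2.99, stage4: 3.09}` —
it peaks at `stage4`, the planted pre-disease stage (`p = 0.95`). The
peak-to-median ratio falls short of the conservative significance rule
(hence `significant=False` and exit status 2), but the ranking step then
selects exactly the ten planted module genes `g0000 … g0009`: the dominant
eigenvector of the pre-disease sample covariance concentrates on the DNB.
Stabilizing those ten genes with strength 0.5 lowers the module's stationary
variance from 14.5 to 3.9 (total 259.5 → 248.9), moves the leading drift
eigenvalue from −0.05 to −0.55, and beats 100/100 random 10-gene target
sets. All artifacts (stage TSVs, `dnb_result.json`, `ranking.tsv`,
`intervention.json`, `report.json`) land in `demo_run/`.

The same steps are available as library calls (`build_network`,
`generate_stage_series`, `detect_predisease`, `ranking_from_expression`,
`simulate_intervention`, …) and as scikit-learn-style estimators:
`DNBDetector().fit(X, stage_labels)` and `InterventionRanker(k=10).fit(X)`,
the latter a feature selector usable inside sklearn pipelines.

A worked in-silico twin of the published candidate selection is included:
applying the lncRNA biotype filter to the published top-10 intervention
candidates (*Cst9, Cox8c, Ddx4, Tuba3b, Rbakdn, 4930449C09Rik, Pttg1ip2,
Capza3, Prr27, Piwil1*) removes the two lncRNAs (*Rbakdn*,
*4930449C09Rik*) and leaves the eight screened candidate genes.

## Layout

- `src/dnbkit/model.py` — OU network model, Lyapunov solver, trajectory oracle
- `src/dnbkit/synthetic.py` — stationary sampling, stage series, ground truth
- `src/dnbkit/detection.py` — stage statistics, clustering, composite index
- `src/dnbkit/intervention.py` — eigenanalysis, ranking, simulated intervention
- `src/dnbkit/io.py`, `pipeline.py`, `cli.py` — TSV/JSON I/O, workflow, `dnbctl`
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
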