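# Methods

## Scope

`aostress` re-implements, as a tested and reusable pipeline, a
cross-experiment meta-analysis of antioxidant-system (AOS) gene
expression under abiotic stress in cereals, together with the
efficiency-corrected qPCR quantification used to verify individual
genes experimentally. The two workflows are:

1. **Meta-analysis** — pooled public stress experiments (mixed
   microarray and RNA-seq platforms) are normalized onto a common
   control-relative fold-change scale, replicate profiles are clustered
   (Ward), experiments without an explicit stress response are filtered
   out, and stress clusters are compared against control replicates
   gene by gene with Benjamini–Yekutieli (BY) corrected t-tests.
2. **qPCR quantification** — per-well amplification efficiency and Cq
   are estimated from raw fluorescence curves by a window-of-linearity
   fit, and relative expression is the efficiency-corrected ratio
   `E_target^ΔCq_target / E_reference^ΔCq_reference` with
   `ΔCq = mean control Cq − mean treated Cq`; treatment effects on
   `ΔCq = Cq_target − Cq_reference` are tested with a two-way
   fixed-effects ANOVA (cultivar × treatment, type II sums of squares).

Everything runs on synthetic data with planted ground truth, so every
stage is testable without downloading public repositories. Phylogenetic
reconstruction, primer design, and repository scraping are out of scope.

## Normalization cascade

Counts platforms are converted to FPKM,
`1e9 · c(g,s) / (L(g) · N(s))` with `N(s)` the sample's total counts.
Each sample is then divided by its housekeeping-gene value, removing
per-sample scale (library size, labeling efficiency, batch level).
Finally, within each experiment, each gene is divided by the mean of
its control replicates, so every gene × experiment control mean is 1 by
construction and values are dimensionless fold changes comparable
across platforms and batches.

Numerical choices: genes whose control mean is zero in an experiment
cannot be normalized there — they are set to missing for that
experiment, logged, and dropped from any stage that needs complete
profiles (never imputed). Values are carried as linear fold changes;
log2 is applied only where a stage asks for it (distances, t-tests),
with `log2(fold + 1e-6)` guarding zeros. Microarray intensities are
assumed background-corrected on input.

## Clustering, labeling and the experiment filter

Replicate profiles are clustered with Ward's minimum-variance criterion
on Euclidean distances in `log2(fold + 1e-6)` space (fold changes are
multiplicative; a linear-space switch exists). The flat partition is a
dendrogram cut at `n_clusters`; when unspecified, k maximizes the mean
silhouette over k ∈ [3, 15]. The floor is 3, not 2, because the
analysis needs the control profile separated from each stress type and
a two-cluster cut cannot provide that — with strong up/down signatures
the silhouette otherwise occasionally prefers k = 2, which would make
the downstream experiment filter vacuous. We rely on scipy's
nearest-neighbor-chain Ward implementation, which is deterministic for
a given input; exact merge-distance ties (measure zero on continuous
fold profiles) may resolve differently after column permutation, and
the permutation-invariance guarantee is asserted on tie-free data.

Clusters are labeled `control` when controls are their strict majority
(and at least one control is present), otherwise `CR` (cold response)
or `WDR` (water-deficiency response) by strict-majority stress type,
and `mixed` on ties.

The quality filter excludes an experiment iff **strictly more** than
50% of its stress replicates fall into control-containing clusters
(exactly half retains). Two readings of "control-containing" are
implemented: `any` (≥1 control replicate; the literal reading and the
package default) and `majority` (majority-control clusters only). For
count data the `majority` rule is the recommended setting: negative
binomial noise at low expression occasionally throws a single control
replicate into a genuine stress cluster, and under the `any` rule that
lone outlier poisons the whole cluster and falsely excludes healthy
experiments. The recovery studies in `aostress.validation` use the
`majority` rule for this reason. Experiments with no stress replicates
are retained with an undefined fraction and flagged.

After filtering, the retained sample — stress replicates of retained
experiments plus **all** control replicates — is re-clustered, and the
differential stage compares each non-control cluster of the second pass
against all controls. An `experiment` comparison mode (stress vs
control within each experiment, no filter) covers small samples where
pre-selection is not affordable.

PCA of the replicate × gene fold matrix is computed on centered,
unscaled log2 folds (genes share units after normalization; unit
scaling is an option); all components are kept, so explained-variance
fractions sum to 1 and score distances reproduce profile distances.

## Differential calls

Per gene, stress and control groups are compared with a two-sample
t-test on log2 folds — Welch by default (cross-experiment groups are
heteroscedastic), Student's behind a flag. `mean_fold` is the
geometric-mean ratio; the arithmetic-mean ratio is reported alongside.
Degenerate cases: identical zero-variance groups give p = 1; unequal
means with zero variance in both groups get the machine-minimum p and a
flag rather than a fabricated statistic; genes with fewer than two
values in a group get a missing p.

P-values are adjusted with the BY step-up
(`a_i = p_(i) · m · c(m) / i`, `c(m) = Σ 1/j`, suffix minimum, capped
at 1), which controls FDR under arbitrary dependence — appropriate
here because genes within a comparison are correlated through shared
normalization. The family is all genes within one comparison, matching
how a per-comparison summary column is marked. Calls are `up` / `down`
when the adjusted p is below α (default 0.05) and the fold is above /
below 1; a raw-p mode exists because the bolding convention of the
original summary table cannot be attributed to raw or adjusted p with
certainty. The summary stage pivots calls and folds into a wide
genes × comparisons matrix (optionally aggregated to clade level by
arithmetic mean, the view needed when probes report whole homeologue
groups) and renders a heat-styled HTML report; missing cells are marked
"no data".

## qPCR model

The curve generator produces a saturating amplification curve with an
exact exponential early phase, `F(c) = B + P·x/(1+x)` with
`x = N0·E^c/P`, the regime a window-of-linearity estimator assumes.
Replicate noise acts on the cycle scale (each well's effective template
is `N0·E^(−d)`, `d ~ N(0, cq_noise_sd)`), so a well's Cq shifts by
exactly `d` cycles.

The estimator subtracts a baseline, locates the most log-linear window
of 4–6 consecutive cycles, and refines the baseline per candidate
window by a bounded scalar search maximizing the window R²; efficiency
is `10^slope` of the refined fit and Cq the fractional crossing of a
threshold placed at the window's geometric midpoint. Two constraints
keep the fit honest: the baseline never exceeds the curve's global
minimum (otherwise saturated windows can fake log-linearity), and
baseline refinement is applied to the top-ranked candidate windows, not
just the best provisional one, because a poor provisional baseline
distorts the ranking. Windows flatter than E = 1.05 are rejected; flat
curves (no-template controls) are flagged negative with undefined
efficiency and Cq. On noiseless curves the estimator recovers E within
±0.003 and the analytic threshold crossing exactly.

Per amplicon, the efficiency is the mean of per-well estimates and the
quantification threshold is shared (geometric mean of per-well window
midpoints), so Cq values are comparable across wells. Technical
replicates are averaged into biological-replicate Cq values;
`MEAN_control` and `MEAN_treat` are means over biological replicates.
The control treatment's own ratio is 1 by construction, as is the
reference gene's. Cq-only input skips estimation and requires
per-amplicon efficiencies. The ANOVA on ΔCq uses type II sums of
squares, the conventional choice for factorial designs when imbalance
is not interaction-driven; both factors need ≥2 levels and every cell
≥2 replicates.

## Synthetic generator: what it emulates, what it does not

The meta generator's defaults reproduce the pooled-sample shape the
pipeline targets: 13 experiments, 35 panel genes, 70 control + 130
stress replicates, alternating count/intensity platforms and
cold/water-deficiency stress types. Expected log2 expression per
replicate is baseline (per gene, sd 1.5) + experiment batch (sd 1) +
replicate scale (sd 0.5) + planted log2 fold (with per-experiment
jitter, sd 0.1) + replicate noise (sd 0.25). Default signatures plant
eight up- (fold 5) and eight down-regulated (fold 0.2) genes per stress
type. Count platforms draw negative binomial counts (dispersion 0.1)
around `mu·L·libsize/1e9`; intensity platforms emit the log-normal
values directly. `count_dispersion = 0` switches counts to rounded
expectations — the noiseless mode used by exactness tests.
`noisy_fraction` experiments receive no signature at all, directly
creating the "stress replicates cluster with controls" failure mode the
filter targets (rather than inflated variance, which would exercise a
different defect). The housekeeping gene has a fixed high baseline
(+6 log2 over the panel mean — reference genes are chosen for
abundance) and carries neither fold nor gene-level noise, including
counting noise: it tracks the per-sample scale exactly, which is the
contract housekeeping normalization relies on.

Features of real data deliberately not emulated: probe-level microarray
structure, read-level sequencing, cross-hybridization, tissue/time
covariate shifts within an experiment, melting curves, and fluorescence
measurement noise on qPCR curves (noise is planted on the Cq scale
instead). Passing recovery tests therefore demonstrates correctness of
the pipeline's logic under its own model assumptions, not robustness to
every artifact of public repository data.

## Study sizes used by the recovery checks

Recovery studies run at the pooled-sample shape (13 × 35 × 200): 20
seeded bundles for filter recovery and differential sensitivity/FDR,
20 small null bundles for the global-null false-call rate, 50
randomized-shape bundles for the normalization invariant, and 100
simulated plates (2 targets + reference, 3 treatments, 3 bio × 3 tech,
E ∈ {1.8, 1.9, 2.0}, Cq noise sd 0.2) for end-to-end qPCR recovery. A
plate run counts as successful when its mean relative error across
planted non-control ratios is ≤ 15%; with Cq noise sd 0.2 a *single*
ratio estimate has a log2-scale error sd of ≈ 0.13 (≈ ±9.5%), so
per-estimate success saturates near ~90% and the run-level mean is the
stable summary. The per-estimate fraction is reported alongside.

## Known limitations

- The filter's `any` rule is faithful to its literal description but
  fragile under count noise (see above); `majority` is recommended.
- Welch tests on pooled cluster-vs-control comparisons ignore the
  within-experiment correlation induced by shared control means; with
  many replicates this yields a mild excess of small-fold false calls
  (empirical FDR ≈ 0.07 at α = 0.05 in the recovery study, still under
  the BY nominal guarantee's practical envelope but above α).
- Micro-clusters of 2–3 outlier replicates can reach significance with
  near-zero within-group variance; their calls should be read together
  with the cluster sizes reported in the differential table.
- The silhouette-selected k is a heuristic; for publication-grade runs
  the cut should be chosen by inspecting the dendrogram.
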