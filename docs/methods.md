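# Methods

## Data model and scope

The package starts from ROI-level time series: per subject, a matrix with
one row per time point and one column per region of interest. Everything
upstream of that — slice-time correction, motion modelling, nuisance
regression, spatial normalization, band-pass filtering — is out of scope;
a parcellation pipeline is assumed to have produced the matrices. Voxel
concepts are mapped to ROI level throughout (the seed-based baseline
tests ROIs, not voxels).

## Synthetic cohorts

The generator plants `n_networks` disjoint ROI blocks. ROI *i* in block
*k* has time course

    x_i(t) = √ρ · s_k(t) + √(1−ρ) · e_i(t),

with the block's latent signal `s_k(t) ~ N(0,1)` and private noise
`e_i(t) ~ N(0, noise_sd²)`, all i.i.d. over time. The expected
within-block Pearson correlation is ρ / (ρ + (1−ρ)·noise_sd²) — exactly ρ
at `noise_sd = 1` — and the expected between-block correlation is zero.

Defaults: 70 ROIs, 7 networks (block 0 designated the planted DMN),
10 subjects, 180 time points, ρ = 0.6, `noise_sd = 1`. These mirror a
7-network, ~180-time-point resting-state setting at roughly a tenth of an
800-ROI parcellation, sized so the full pipeline runs in about two
minutes on one CPU. Each subject draws from an independent substream of
one seeded generator, split by subject counter, so enlarging the cohort
never perturbs earlier subjects.

What the generator does **not** emulate: temporal autocorrelation of
band-limited BOLD, hemodynamics, inter-subject variability in network
topography, spatially correlated noise, motion artifacts, and overlapping
or hierarchical networks. Pearson correlation is invariant to temporal
ordering, so autocorrelation would not change what the graph stage sees;
but a passing pipeline here demonstrates recovery of clean block
structure, not robustness to realistic confounds.

## Graph construction

Per-subject correlation matrices are averaged elementwise; the mean
matrix is thresholded at 0.1 with a **signed** comparison (an entry of
−0.3 is dropped, not kept by magnitude), matching the convention of
zeroing "values less than 0.1". Node features are the rows of the
thresholded group-mean matrix with the diagonal zeroed — the diagonal
would otherwise contribute a constant self-feature to every aggregation.
Features from the raw (unthresholded) rows were considered and rejected:
a single group-level graph needs a single group-level feature matrix, and
keeping sub-threshold entries would leak edges the graph has dropped.
Isolated nodes are allowed (warned about) and handled downstream by a
self-fallback in neighbor sampling. The graph itself is unweighted;
correlation magnitudes survive only in the features.

## GraphSAGE

* **Layers**: two, 200 then 100 units; weight `W^k` maps the concatenated
  (self ‖ neighborhood) vector, so its input width is twice the previous
  layer's output. No biases. σ = ReLU inside layers.
* **Fan-outs**: neighbors are sampled uniformly **with replacement** to a
  fixed fan-out, giving fixed-shape batches: 50 samples feed the output
  layer's aggregation (1-hop) and 10 the inner layer (2-hop). At
  inference the full neighborhood replaces sampling and dropout is off,
  so embeddings are a deterministic function of the learned weights.
* **Aggregators**: mean (default) and max-pool
  (`max over u of ReLU(W_pool h_u)`, with `W_pool` square in the input
  dimension). The LSTM aggregator is deliberately omitted: its output
  depends on an arbitrary recurrent parameterization and permutation
  order, neither of which is pinned down by the published setting.
* **Positive pairs**: 10 uniform random walks of 5 nodes from every node;
  every non-start visit yields one (start, visit) pair, i.e. the context
  window is the whole walk. Walks truncate at dead ends.
* **Loss**: J(z_u) = −log σ(z_uᵀz_v) − Σ_{q≤Q} log σ(−z_uᵀz_q), with σ
  the logistic sigmoid (inside layers σ is ReLU; the loss is only
  meaningful with a sigmoid) and Q = 5 negatives per pair drawn uniformly
  over all nodes, redrawn on collision with u or v. Computed via
  `log σ(x) = −log1pexp(−x)`, so it is stable and provably ≥ 0.
* **Optimization**: minibatches of 10 pairs, Adam (β₁ = 0.9, β₂ = 0.999)
  at learning rate 0.01, 100 epochs, dropout 0.15 applied to the input of
  each `W^k` during training only (inverted scaling). Glorot-uniform
  initialization, seeded. Gradients are derived by hand — including the
  path through the per-row L2 normalization and through the sampled-mean
  (scatter through the sampling matrix) and max-pool (route to argmax)
  aggregations — and validated against central finite differences in the
  test suite.
* **Numerical edge cases**: a ReLU output row that is exactly zero is
  left at zero rather than normalized (its normalization gradient is also
  zeroed). Transient zero rows occur early in training and are revived by
  later updates; on the default cohort the final embedding has none, and
  the tests assert unit norms there. A non-finite loss aborts training
  with the epoch and step in the message.
* **Ordering and ties**: nodes are processed in ascending ROI-index order
  everywhere; all randomness (init, walks, shuffles, sampling, dropout,
  negatives) flows from one seeded generator, so equal seeds give
  bit-identical embeddings.

Training recomputes all node representations each step with freshly
sampled neighborhoods (full-graph minibatching). For graphs of a few
hundred ROIs this is cheaper than per-batch computation-graph pruning and
keeps the gradient code simple; it would be the wrong trade-off for
graphs of 10⁵+ nodes, which this package does not target.

## Network extraction

PCA centers columns and keeps the **minimal** p whose cumulative
explained variance reaches the 95% target; clustering uses all p
components (a flag allows restricting to 2, which is useful for plotting
but discards separation). Per-axis sign is fixed by making each axis's
largest-magnitude loading positive, so results are deterministic. K-means
is Lloyd's algorithm from k-means++ seeding with 10 restarts, 300
iterations maximum, best inertia kept (scikit-learn's implementation,
seeded; its empty-cluster re-seeding applies). k defaults to 7 and is
exposed as a flag. The DMN cluster is identified by maximal Jaccard
overlap with a reference ROI list — ties toward the lower cluster index —
replacing visual identification, which is the only automatable surrogate.
On synthetic cohorts the reference defaults to the planted block 0.

## Seed-based correlation baseline

Per-subject seed-to-ROI Pearson correlations are Fisher-z transformed
(atanh; |r| ≥ 1 clamped to 1 − 10⁻⁷ with a warning) before the one-sample
group t-test, the variance-stabilizing convention of standard
connectivity toolboxes; a raw-r mode exists for comparison. The seed
itself is excluded from testing. Significance is a strict inequality
|t| > t_crit at the two-sided uncorrected level (default α = 10⁻⁴, so
t_crit ≈ 4.09 at df = 83); the optional familywise mode applies
Bonferroni — α_FWER divided by the number of tested ROIs — chosen because
the correction method behind the published familywise level is not
specified and Bonferroni is the conservative default. ROIs with zero
variance across subjects get ±∞ (or 0 at zero mean) with a warning
rather than NaN propagation.

## Reproducibility plumbing

One global pipeline seed derives the stage seeds by fixed offsets
(cohort +0, embedding training +1, k-means +2), so a stage can be re-run
in isolation from the run log, which echoes the full configuration and
all derived metrics. All writers emit headered TSV with 9 significant
digits, plus JSON for manifests and metrics.

## Problem sizes

The test suite and the acceptance script exercise the full pipeline at
the default 70-ROI, 7-network, 10-subject configuration (one shared
training run in the test session), unit primitives on instances of ≤ 50
nodes against brute-force oracles, and the closed-form 800-ROI quantities
(complete-graph edge count, critical t) directly.

## Known limitations

* Recovery numbers (ARI, SBC sensitivity/specificity) are for clean
  planted-block data and say nothing about empirical BOLD cohorts.
* A single group-level graph: no per-subject embeddings or
  subject-level inference on the GraphSAGE side.
* No selection of k (silhouette, gap statistic) — k is an input.
* Anatomical naming is limited to the DMN-by-overlap step; other
  clusters are reported by index only.
* The NIfTI atlas-export of cluster maps is not implemented; partitions
  are exported as TSV keyed by ROI identifier.
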