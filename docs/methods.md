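# Methods

`carcinomap` re-implements, as a tested library, the computational workflow
used to characterize chemically induced (4NQO) tongue carcinogenesis from
whole-slide histology images and Visium-style spatial transcriptomics:
unsupervised sub-region segmentation of slides, slide-grouped classification
of muscle tiles, spot-level clustering and marker detection, differential
expression with gene-set enrichment, spatial pseudotime trajectories with
switch-gene timing, and IHC H-score quantification.  All stages run end to
end on synthetic data with planted ground truth, so every claim the test
suite makes is about a recoverable target.

## Synthetic data model

The spot simulator places `K * n_spots_per_cluster` spots on a rectangular
grid.  Latent time `t` is the normalized coordinate along the gradient axis
(in [0, 1]); clusters are contiguous blocks along the gradient, so the
cluster sequence doubles as a planted lineage.  Counts are negative
binomial with mean `mu` and variance `mu + mu^2 / dispersion`
(`dispersion = inf` degenerates exactly to Poisson).  Per-gene baselines are
Gamma(2, 0.5) (mean 1 expected count); marker genes get their baseline
multiplied by `marker_fold` in their home cluster and are floored at 1
expected count, because they emulate canonical cell-type markers, which are
detectably expressed.  Switch genes flip between a low (0.1) and high (5.0)
expected count with `P(on | t) = logistic(slope * (t - t*))`, switch times
equally spaced in (0, 1), directions alternating on/off.  Per-spot library
sizes are log-normal.  Defaults (K=3, 200 spots/cluster, 2000 genes, 50
markers/cluster at fold 4, dispersion 2, 50 switch genes at slope 20,
libsize sigma 0.2) describe a small but realistic Visium section with a
strong developmental gradient.

The tile simulator draws standard-normal features per tile, adds
`effect_delta` to a planted feature subset in case-slide tiles, and a
shared Normal(0, `batch_sigma`) shift per slide.  Defaults (12 case + 14
control slides, 200 tiles each, 512 features, 20 planted at 1.5 sigma,
batch sigma 0.5) mirror the cohort geometry of the motivating study at
desk scale.  IHC tables are Dirichlet draws over the four staining
intensities, scaled to percentages.

What the generators do *not* emulate: real histology texture, spatial
autocorrelation of noise, gene–gene correlation beyond the planted
programmes, segmentation/deconvolution ambiguity, and batch effects more
complex than additive shifts.  Passing recovery tests therefore
demonstrates correctness of the algorithms under their stated assumptions,
not performance on real tissue.

## Histology segmentation

Tissue is masked by Otsu's threshold computed exhaustively on the 256-bin
histogram (ties resolve to the lowest threshold; dark pixels are tissue for
H&E).  Slides are tiled with a sliding window (512 px window, 128 px stride
at 20x by default); tiles below 50% tissue are dropped.  Features come from
a pluggable extractor: the default is a handcrafted 64-dimensional
descriptor (16-bin intensity histogram, per-channel mean/variance, 14-bin
gradient-magnitude histogram plus gradient moments, 26-bin uniform LBP with
P=24, R=3); features from any external model can be loaded from a table
keyed by tile coordinates.  The top 256 features by variance are kept, PCA
reduces them, a shared-nearest-neighbor kNN graph is built, and Leiden
communities at resolution 0.1 give the sub-regions.  Labels map back to
pixels by per-pixel majority vote over overlapping tiles (ties to the
smallest label id; uncovered pixels are -1).  Clustering is per slide;
labels are not comparable across slides.

## Spot preprocessing and clustering

QC removes spots below thresholds on detected genes and UMI total.
Normalization is `log1p(count / spot_total * 1e4)` — a deliberately simple
variance stabilization; downstream contracts do not depend on the specific
transform.  Batch correction is per-batch centroid alignment in PC space, a
pure translation sufficient for additive batch offsets (and exactly the
identity for a single batch).  HVG selection ranks genes by normalized-value
variance.  PCA is computed by SVD with a deterministic sign convention
(largest-magnitude loading positive).  The kNN graph uses union
symmetrization and Jaccard shared-neighbor weights; Leiden (RB
configuration modularity) clusters it, labels canonicalized by size then
smallest member.  Default resolution is 1.0 for expression and 0.1 for
image tiles; recovery tests use 0.1 because the planted targets are coarse
(K in 2–4).

Markers use a bimodal likelihood-ratio test: expression is a mixture of a
point mass at zero and a Normal on positive values; the LRT compares a
shared model against group-specific detection rate and positive mean
(shared SD re-estimated under each hypothesis), with 2 * delta-log-likelihood
referred to chi-square(2).  Null p-values are verified uniform by KS test.

## Differential expression and enrichment

Two-group DE uses a Wilcoxon rank-sum test by default (the bimod LRT is an
option).  Fold change is linear, computed from `expm1` of normalized means
with pseudocount 1e-9, and the filter is two-sided: up at FC > `fc_min`,
down at FC < 1/`fc_min`, combined with raw p < `p_max` (defaults 1.5 and
0.05; BH q-values are reported alongside but do not gate the filter).
Enrichment is the hypergeometric upper tail P(X >= k) of the overlap
between the filtered genes and each user-supplied GMT set within the tested
universe, BH-corrected across sets.

## Trajectory inference

The expression kNN graph (on PCA of the normalized layer) is turned into a
diffusion operator: Gaussian affinities on graph edges with locally scaled
bandwidths (each node's mean incident edge length), density-normalized
(alpha = 1), row-normalized to a stochastic matrix; eigenpairs come from
the symmetric conjugate.  Two numerical guards matter on strongly separated
clusters: (1) if the graph is disconnected, components are bridged before
diffusion by the k shortest cross-component point pairs — a single bridge
edge would be an artificial bottleneck whose near-unit eigenvalue dominates
the embedding; (2) per-edge bandwidth is floored at (d/2)^2 so no retained
edge has affinity below exp(-4): the sparse graph already encodes locality,
and vanishing kernel tails destabilize pseudotime.

Diffusion pseudotime of spot x is its Euclidean distance from the root spot
in the embedding `psi_i * lambda_i / (1 - lambda_i)` (i >= 2), rescaled to
[0, 1].  The root is always user-specified (cluster id, optionally a spot);
by default the root cluster's spot closest to its expression centroid.
Cluster connectivity is the observed inter-cluster edge count over its
degree-preserving expectation (a PAGA-style abstraction).

The pseudo-space-time distance between cluster nodes is
`alpha * d_expr + (1 - alpha) * d_spatial`, each term the Euclidean
centroid distance min-max normalized over off-diagonal pairs
(default alpha 0.5).  Direction is imposed by forbidding edges that run
backwards in mean pseudotime.  The lineage tree is the minimum-weight
spanning arborescence (Chu–Liu/Edmonds) over the finite entries, rooted at
the chosen cluster.

Known limitation: chain recovery needs boundary continuity in expression.
On a small fraction of generator seeds the kNN graph leaves a middle
cluster attached by a single edge; the expression manifold then genuinely
lacks the chain and the middle clusters can be misordered.  The seeded
default configuration recovers the planted chain exactly.

## Switch genes

Expression is binarized per gene with a 2-component Gaussian mixture on
normalized values; the threshold is the posterior crossover, with a
fallback to "value > 0" (flagged) when a component weight is below 0.05,
the means are within 0.1, or the gene is nearly constant.  The binary state
is regressed on pseudotime by a ridge-stabilized (epsilon = 1e-6) logistic
fit: switch time `t* = -b0/b1` clamped to [0, 1] (out-of-range fits
flagged), direction "on" iff the slope is positive, quality = McFadden
pseudo-R^2, significance = Wald test on the slope, BH across genes.  The
ridge keeps perfectly separated (ideal) switch genes finite; fits with
|slope| > 100 are flagged rather than dropped.  The timeline report filters
on q, pseudo-R^2 and flags, then sorts by switch time.

## Muscle subtyping

Tiles inherit their slide's class.  Evaluation is seeded repeated grouped
holdout: each iteration holds out 2 case + 2 control slides (tiles of a
slide never straddle train/test), avoiding re-use of test slides across
iterations while unused slides remain.  The classifier is L2-regularized
logistic regression over tile features (a least-squares-on-{0,1} scorer is
available); the probabilistic scores feed AUC (pairwise concordance, ties
0.5; 95% CI by stratified percentile bootstrap with 2000 replicates) and
majority voting per ROI and per slide (exact ties: mean score >= threshold
counts positive).  Feature importance is the intersection across iterations
of each model's top-50 absolute weights.

## IHC

H-score = sum of `P_i * i` over intensity categories 0–3 (percentages must
sum to 100 within 1e-6), range 0–300.  Groups are compared with the
classical pooled-variance unpaired two-tailed t-test (equal variances by
design, matching the named test), stars at 0.05 and 0.01.

## Determinism and problem sizes

All randomness flows from one root seed through keyed child generators
(CRC32-hashed stage names), so adding a consumer never perturbs existing
streams; reruns with the same config and seed are byte-identical, which the
CLI verifies via SHA-256 digests in its run manifests.  The test suite and
the acceptance script use the generator defaults (600 spots / 2000 genes
for the gradient simulation; 26 slides x 200 tiles x 512 features for the
classifier; 100 spots per group and 2000 genes for DE calibration) — sizes
chosen so each planted effect is recoverable with a comfortable margin
while a full run stays fast on one CPU.
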