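# carcinomap

Spatial-transcriptomic and histology analysis of carcinogen-induced tongue
tumor progression.

Chemically induced (4NQO) mouse tongue carcinogenesis progresses through
dysplasia, primary tumor and muscle invasion, leaving footprints both in
whole-slide histology and in spot-level spatial gene expression.
`carcinomap` is a reusable, tested implementation of the full analysis
workflow for such studies, aimed at computational biologists who want each
stage as a library function with explicit contracts:

* **Slide segmentation** (`histoseg`) — Otsu tissue masking, sliding-window
  tiling, pluggable tile features, top-variance feature selection, PCA +
  Leiden communities (resolution 0.1), per-pixel majority-vote label maps.
* **Muscle subtype classification** (`subtype`) — slide-grouped repeated
  holdout (2 case + 2 control test slides per iteration, no tile leakage),
  L2 logistic regression over tile features, ROI/slide majority voting,
  AUC with stratified bootstrap CI, and consensus features (intersection of
  per-iteration top-50 |weights|).
* **Spot analysis** (`st_core`) — QC, log1p CP10k normalization, HVG
  selection, PCA, batch-centroid alignment, SNN-weighted kNN graph, Leiden
  clustering, UMAP/t-SNE, and a bimodal (zero-inflation + Normal)
  likelihood-ratio marker test.
* **Differential expression** (`diffexpr`) — Wilcoxon or bimod tests with
  the two-sided linear fold-change filter (p < 0.05, FC > 1.5 by default)
  and hypergeometric gene-set enrichment over user GMT files with BH
  correction.
* **Trajectories** (`trajectory`) — diffusion pseudotime (DPT) from a
  user-chosen root, PAGA-style cluster connectivity, the pseudo-space-time
  distance `alpha * d_expr + (1 - alpha) * d_spatial` with
  pseudotime-directed edges, and the rooted minimum spanning arborescence
  (Chu–Liu/Edmonds) as the lineage tree.
* **Switch genes** (`switches`) — Gaussian-mixture binarization and
  ridge-stabilized logistic timing fits `P(on) = logistic(b0 + b1*tau)`,
  giving each gene a switch time `t* = -b0/b1`, a direction, McFadden
  pseudo-R², and BH-corrected significance.
* **IHC** (`ihc`) — H-score = Σ P_i·i over staining intensities 0–3 and the
  pooled-variance unpaired t comparison with significance stars.
* **Synthetic data** (`syndata`) — seeded generators for every input with
  planted ground truth (clusters, latent time, markers, switch genes,
  discriminative tile features, slide batch effects, bimodal images,
  staining tables), so each stage has a recoverable target.

See `docs/methods.md` for the models, defaults and numerical choices.

## Worked example

Simulate the default gradient dataset (3 clusters x 200 spots, 2000 genes,
50 switch genes), cluster it, infer the spatial trajectory and time the
switches:

```python
import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from carcinomap import STSimConfig, syndata, st_core
from carcinomap.trajectory import infer_trajectory
from carcinomap.switches import detect_switches, rank_switches

ds = syndata.generate_st_dataset(STSimConfig(seed=0))
ds, qc = st_core.qc_filter(ds, min_genes=1, min_umi=1)
ds = st_core.normalize_log(ds)

hvg = st_core.select_hvg(ds, 1000)
pca = st_core.run_pca(ds.subset_genes(hvg).layers["lognorm"].T, n_pcs=20)
graph = st_core.build_knn_graph(pca.scores, k=15)
clusters = st_core.cluster_graph(graph, resolution=0.1, seed=0)
print("clusters:", clusters.n_clusters,
      "ARI vs planted:", round(adjusted_rand_score(ds.truth["cluster"], clusters.labels), 3))

traj = infer_trajectory(ds, clusters.labels, root_cluster=0)
rho = stats.spearmanr(traj.pseudotime, ds.truth["latent_time"]).statistic
print("pseudotime Spearman vs planted time:", round(rho, 3))
print("lineage tree:", [(p, c) for p, c, _ in traj.edges])

table = detect_switches(ds.layers["lognorm"], traj.pseudotime, ds.gene_ids, seed=0)
timeline = rank_switches(table, top_n=5, q_max=0.05, min_r2=0.2)
print(timeline[["gene", "switch_time", "direction", "pseudo_r2"]].round(3).to_string(index=False))
```

Output:

```
clusters: 3 ARI vs planted: 1.0
pseudotime Spearman vs planted time: 0.914
lineage tree: [(0, 1), (1, 2)]
      gene  switch_time direction  pseudo_r2
gene_00161        0.087       off      0.201
gene_00162        0.093        on      0.207
gene_00164        0.126        on      0.288
gene_00163        0.142       off      0.224
gene_00166        0.180        on      0.340
```

The clustering recovers the three planted sub-populations exactly
(adjusted Rand index 1.0); diffusion pseudotime tracks the planted latent
time (Spearman 0.91); the lineage tree is the planted chain 0 → 1 → 2; and
the earliest significant switch genes appear at the start of the
trajectory with their directions called correctly (even-indexed planted
switches turn on, odd turn off).

The same stages are available as a CLI over YAML configs, each run
emitting a JSON manifest with input/output SHA-256 digests:

```sh
carcinomap --seed 0 --outdir out simulate
carcinomap --seed 0 --outdir out st-cluster
carcinomap --seed 0 --outdir out trajectory
carcinomap --seed 0 --outdir out switches
```

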