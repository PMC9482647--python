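# risyng

Multi-omics integrative clustering for cancer-subtype discovery, built
around RISynG (Recursive Integration of Synergised Graph-representations).
Given several sample-matched omics views — mRNA and miRNA expression, DNA
methylation beta values, protein abundance — the package finds the sample
partition that the views support jointly, for analysts who have a handful
of features × samples matrices and a target number of subtypes *k*.

## Method

Each view `X_m` (d_m × n) is encoded twice:

* **Gramian** `G_m = exp(-φ_m / φ̂_m)`, a heat kernel over pairwise
  correlation distances `φ = 1 - r` (maximum distance `φ̂` as bandwidth).
  Samples with proportional expression profiles are similar regardless of
  scale.
* **Shifted normalised Laplacian** `L_m = 𝓛_m + (2/n)·1·1ᵀ` with
  `𝓛_m = I − D^{-1/2} W_m D^{-1/2}`, where `W_m = exp(-ε_m / ε̂_m)` is the
  heat kernel over squared Euclidean distances. The rank-one shift moves
  the trivial constant eigenvector out of the bottom of the spectrum.

The two are fused per view into a **synergy matrix**
`H_m(β) = β·G_m + (1−β)·L_m`, `β ∈ [0,1]`, which stays symmetric PSD. `β`
is selected by a provisional validity scan: for each grid value
(step α = 0.1, eleven values), k-means on the k-dimensional eigenbasis of
`H_m(β)` is scored with the cluster-averaged silhouette, and the grid
maximiser wins. Views are ranked by that silhouette (most relevant first)
and merged recursively: each new view's eigenbasis is projected off the
accumulated **accretive basis** `b`, the residual is Gram–Schmidt
orthonormalised, attenuated by a sign-preserving elementwise power that
grows with the merge step, and added to `b`. k-means on the rows of the
final n × k basis yields the subtype labels.

The package also ships the full panel of validity indices (cluster-averaged
silhouette, Dunn, Davies–Bouldin, Xie–Beni; F-measure, ARI, NMI,
pair-counting Jaccard, purity), enrichment summaries (mean −log10 adjusted
p-value; annotation ratio), Fisher's exact overlap test, and a synthetic
multi-view generator so everything is testable without external data.

## Worked example

```python
from risyng import RISynG, SyntheticSpec, ViewSpec, make_multiview
from risyng.evaluation import adjusted_rand

spec = SyntheticSpec(
    n=120, k=3, cluster_proportions=[0.3, 0.3, 0.4],
    views=[ViewSpec(d=40, separation=5.0, noise_sd=1.0, relevant=True),
           ViewSpec(d=40, separation=5.0, noise_sd=1.0, relevant=True),
           ViewSpec(d=40, separation=0.0, noise_sd=1.0, relevant=False)],
    seed=11,
)
data, truth = make_multiview(spec)
model = RISynG(n_clusters=3, random_state=11).fit(data)
print("ARI vs planted labels:", round(adjusted_rand(model.labels_, truth), 3))
print("selected beta per view:", model.betas_)
print("relevance order:", model.ranks_)
```

prints

```
ARI vs planted labels: 1.0
selected beta per view: {'view0': 0.0, 'view1': 0.0, 'view2': 0.0}
relevance order: ['view1', 'view0', 'view2']
```

Two informative views and one pure-noise view: the planted three-way split
is recovered exactly (ARI 1.0). The scan selects β = 0 for every view
because these clusters live in Euclidean geometry, so the Laplacian
representation carries the signal; the noise view gets the lowest
provisional silhouette and is ranked last, which attenuates its
contribution to the accretive basis.

The same pipeline is scriptable from the shell:

```bash
risyng simulate --spec spec.yaml --out data/
risyng run --config run.yaml --out results/
risyng evaluate --labels results/labels.tsv --truth data/truth_labels.tsv
```

`run.yaml` lists the view files (TSV/CSV, features × samples), `k`, the
seed, and any estimator option; preprocessing (missing-value filter at 5%,
log10 for sequence expression with 0→1, top-2000 variance filter, sample
alignment) is applied before clustering.

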