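# isclone — clonal reconstruction from co-occurring viral integration sites

In gene therapy and experimental hematopoiesis, cells are marked by
integrating viral vectors, and the genomic integration sites (IS) of the
vector are used as heritable barcodes to track clones over time and across
blood compartments. Because transduction frequently inserts *several*
vector copies into one cell, counting each IS as a clone systematically
overestimates clonality and underestimates the size of expanding clones —
a direct problem for the safety monitoring of gene-therapy trials.

`isclone` reconstructs the true clonal structure from repeated IS abundance
measurements. All IS carried by one clone are amplified from the same
cells, so their relative abundances co-fluctuate across measurements. For
every pair of IS with abundance series *x*, *y* the package computes the
coefficient of determination R² of a linear regression with intercept
(equal to the squared Pearson correlation), collects these into a
similarity matrix *S*, clusters the IS with partition-around-medoids (PAM)
on the dissimilarity D = 1 − S, and selects the number of clones *k* by
maximizing the mean silhouette width. Clone abundances are then the mean of
the member-IS abundances, with IS that did not pass the initial filter
pooled into a background row divided by the mean number of IS per clone.

The package also contains the validation machinery: a stochastic
single-cell simulator of clonal hematopoiesis (logistic growth with
clone-specific differentiation rates drawn from 𝒩(d, δ²), Poisson(λ) IS
per clone, multiplicative measurement noise g ~ 𝒩(1, σ²) and per-clone
compartment variability f ~ 𝒩(1, ν²)), a generator for an in-vitro-style
clone-mix experiment, per-clone precision/recall, the adjusted Rand index
(ARI) against the simulated ground truth, and a parameter-sweep harness.

## Worked example

```python
from isclone import (SimulationConfig, simulate, FilterSpec,
                     reconstruct_pipeline, adjusted_rand_index)

cfg = SimulationConfig(lam=5.0, sigma=0.0, seed=7)    # 100 clones x 100 cells
result = simulate(cfg)
pipe = reconstruct_pipeline(result.observed, FilterSpec())  # top-50 filter

truth = result.is_map.labels_for(pipe.kept.is_ids)
print("IS kept:", len(pipe.kept.is_ids))
print("clones found:", pipe.clustering.k,
      "silhouette: %.3f" % pipe.clustering.silhouette)
print("true clones:", len(set(truth)))
print("ARI: %.3f" % adjusted_rand_index(truth, list(pipe.clustering.labels)))
```

prints

```
IS kept: 50
clones found: 10 silhouette: 1.000
true clones: 10
ARI: 1.000
```

i.e. the 50 most abundant IS at the final measurement stem from 10 clones,
and in this noiseless run the pipeline assigns every one of them to the
correct clone (ARI = 1); the reconstructed clone-level series is in
`pipe.clones`. With measurement noise (the same run at `sigma=0.04`) the
recovery is close but no longer exact (ARI 0.82 at 8 measurements).

The same workflows are available from the shell:

```sh
isclone simulate --lam 5 --sigma 0.04 --seed 1 -o out/
isclone reconstruct out/observed.tsv --filter top-n --n 50 -o rec/
isclone sweep --sigma 0.04 --vary n-measurements=3,5,8,12 --replicates 20 -o sweep/
isclone fixture --seed 0 -o mix/
```

`reconstruct` writes `clustering.json`, `clones.tsv` (clone × sample
abundances with a `background` row), `flags.txt` (IS whose within-cluster
similarity is separated from the rest by a gap — candidates for manual
review) and `graph.graphml` (the similarity network, for external viewers).

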