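# rwce — random-walk cluster ensembles for multi-omics consensus clustering

`rwce` turns many cheap, noisy clusterings of the same patients into one
robust consensus partition, and stacks that construction across data types
(mRNA expression, miRNA expression, DNA methylation, ...) to produce a
single integrated subtyping. It is aimed at computational biologists doing
cancer subtype discovery on matched multi-omics cohorts, and at anyone who
needs a cluster-ensemble method that models the relationships *between*
clusters instead of reducing the ensemble to co-occurrence counts.

## The method

An ensemble of M base k-means runs (each with a random cluster number K) is
pooled into the binary instance-cluster matrix F₀. Clusters form a network
with Jaccard-overlap edge weights J; diffusing the memberships over it with
a random walk with restart,

  F_{t+1} = α F_t Â + (1 − α) F₀,  Â = D⁻¹J,

gives each cluster a dense association profile, and a scaled exponential
kernel exp(−‖z_i − z_j‖²/2σ²) on those profiles gives a refined
cluster-cluster similarity. The refined instance-cluster (RIC) matrix keeps
each observed membership at 1 and fills every hidden association with that
similarity, normalised within its base clustering. RIC is then read as a
weighted bipartite graph W = [[0, RIC], [RICᵀ, 0]] and cut by normalized-cut
spectral clustering, with the number of consensus clusters chosen
automatically at the largest eigengap of the normalized Laplacian. For
multi-omics integration the per-view consensus clusterings are themselves
refined once more into the final partition.

## Worked example

```python
from rwce import (PipelineConfig, SyntheticSpec, ViewSpec, adjusted_rand,
                  generate_multiview, generate_survival, logrank_test,
                  run_integration, silhouette_mean)

spec = SyntheticSpec(n=150, c=3, seed=11,
                     views=[ViewSpec(m=40, separation=6.0, noise_fraction=0.2)] * 3)
views, truth = generate_multiview(spec)

result = run_integration(views, PipelineConfig(M=20, seed=11))
print("chosen k:", result.chosen_k)
print("ARI vs truth:", adjusted_rand(result.labels, truth))
print("silhouette on view0:", round(silhouette_mean(views[0], result.labels), 3))

times, events = generate_survival(truth, hazard_ratios=[1.0, 2.0, 4.0],
                                  censor_rate=0.2, seed=11)
stat, p = logrank_test(times, events, result.labels)
print(f"log-rank chi2 = {stat:.1f}, p = {p:.2e}")
```

prints

```
chosen k: 3
ARI vs truth: 1.0
silhouette on view0: 0.143
log-rank chi2 = 17.7, p = 1.41e-04
```

Three synthetic views share a planted 3-group structure; the eigengap
selects k = 3 without being told, the integrated labels match the planted
groups exactly (ARI 1.0), the modest silhouette reflects the 20% pure-noise
features in the raw view, and the groups separate survival decisively
because their hazards differ fourfold.

The same pipeline is available from the shell:

```
rwce simulate --spec cohort.yaml --out-dir fixtures/
rwce run --views fixtures/view0.csv --views fixtures/view1.csv \
         --views fixtures/view2.csv --out labels.tsv --seed 11
rwce evaluate --labels labels.tsv --view fixtures/view0.csv \
              --truth fixtures/true_labels.tsv --survival fixtures/survival.tsv
```

Views are CSV/TSV matrices (first column instance id, header row feature
names) with identical row order across views; `rwce refine` consumes a TSV
of precomputed base clusterings instead of raw data.

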