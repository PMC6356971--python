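# Methods

## The model

Given one instance-by-feature matrix per data type (rows matched across
types), the package produces a single consensus partition of the instances
in three steps.

**Step 1 — ensemble generation.** For each view, M base clusterings are
produced by k-means (k-means++ init, 10 restarts, 300 iterations) on
z-scored features, with the cluster number K of each run drawn uniformly
from [k_min, k_max]. Randomising K is the source of ensemble diversity.
The default upper bound is ⌈√n⌉: values of K approaching n produce
near-singleton partitions that carry no consensus signal (a `linear` mode
allowing K up to n − 1 is available).

**Step 2 — refinement of one ensemble into a consensus.** The ensemble is
pooled into the binary instance-cluster (IC) matrix F₀ (n × K_total, one 1
per instance per clustering). Clusters become nodes of a network whose edge
weights are Jaccard indices of their instance sets (disjoint clusters of
the same base run get weight 0; the diagonal is 1). The IC matrix is
diffused over this network by a random walk with restart,

    F_{t+1} = α F_t Â + (1 − α) F₀,

iterated until max |F_{t+1} − F_t| < tol (default 1e−6). Â is the
row-normalised transition matrix D⁻¹J; normalisation guarantees a unique
fixed point F = (1 − α) F₀ (I − αÂ)⁻¹ for any α < 1, whereas iterating on
the raw Jaccard matrix can diverge when its spectral radius exceeds 1/α
(a `normalize=False` mode retains the raw iteration for experiments).
The converged columns z_i are dense per-cluster association profiles;
cluster-cluster similarity is the scaled exponential kernel
sim(i, j) = exp(−‖z_i − z_j‖² / 2σ²), σ = 1.

The refined instance-cluster (RIC) matrix keeps a 1 for each observed
membership and fills the zeros of clustering block m by the similarity to
the instance's own cluster C\*, normalised over that block's other
clusters and scaled by dc:

    RIC(x, C) = dc · sim(C, C*) / Σ_{C′ ∈ π(m), C′ ≠ C*} sim(C′, C*).

RIC is finally read as a bipartite graph (instance vertices on one side,
cluster vertices on the other, edge weights RIC, no within-side edges) and
partitioned by normalized-cut spectral clustering: eigenvectors of the k
smallest eigenvalues of L_sym = I − D^{−1/2} W D^{−1/2}, row-normalised,
clustered by k-means (20 seeded restarts); only the instance vertices'
labels are kept. When k is `auto` it is chosen by the eigengap,
k = argmax_{i>1} (λ_{i+1} − λ_i), searched over i ∈ [2, min(15, n − 1)];
ties go to the smaller i (fewer clusters). The ceiling of 15 comfortably
covers realistic subtype counts while keeping the degenerate tail of the
spectrum out of the search.

**Step 3 — integration.** The per-view consensus clusterings (one per data
type) are themselves treated as a T-member ensemble and refined once more
with the same machinery and the same hyperparameters (each stage's
parameter is separately overridable).

## Parameters

| name | meaning | default | why |
|---|---|---|---|
| M | ensemble size per view | 50 | stable consensus at moderate cost; values 10–50 behave similarly on synthetic data |
| α | walk retention (1 − α = restart probability) | 0.9 | strong diffusion, the common choice for restart walks |
| σ | kernel bandwidth | 1 | unit bandwidth on walked profiles |
| dc | non-member association mass per block | 1 | results are robust to it over a wide range; see degeneracy below |
| tol | walk convergence (max abs change) | 1e−6 | tight enough that the kernel distances are stable |
| k | consensus cluster count | auto (eigengap) | subtype counts are rarely known a priori |
| k_min, k_max | base-clustering K range | 2, ⌈√n⌉ | see Step 1 |

Seeding: a master seed is split into per-view sub-seeds by hashing the view
name into a `numpy.random.SeedSequence` (splitmix-style), so per-view
results do not depend on the order views are supplied, and the whole
pipeline is byte-reproducible given the config.

## Numerical choices

- Convergence is measured in the max-absolute-entry norm; with the
  row-stochastic transition matrix the iteration is a contraction with
  factor α, so the distance to the fixed point at stop is below
  tol·α/(1−α).
- Eigenvalues of L_sym are clipped into their theoretical [0, 2] band to
  absorb round-off; eigendecomposition is a dense symmetric solve restricted
  to the lowest min(16, n) eigenpairs.
- Zero rows of the spectral embedding are left unnormalised (with a
  warning) rather than divided by zero.
- Isolated instance vertices (all-zero RIC rows) are an error — their
  normalized-cut degree is undefined; isolated cluster vertices are dropped
  with a warning since they carry no instance information.
- An all-zero similarity denominator in the RIC ratio (impossible with the
  exponential kernel, possible with injected raw similarities) leaves the
  block's non-members at 0.
- If the bipartite graph has more connected components than a requested k,
  the labels follow the components and a warning is raised; components are
  the exact normalized-cut optimum in that case.
- Empty k-means clusters in base runs are removed by relabelling to a
  contiguous 1..K′, keeping every partition crisp and exhaustive.

## Known degeneracies and limitations

- **Binary blocks are uninformative.** In a two-cluster block the RIC ratio
  for the single non-member cluster is sim/sim = 1, so with dc = 1 the
  non-member entry equals the member entry. An ensemble consisting only of
  identical two-cluster partitions therefore yields an all-ones RIC matrix
  (a complete bipartite graph) from which the original partition cannot be
  recovered; more generally, two-cluster base runs contribute
  near-uniform "hub" weight that dilutes the eigengap when M is small.
  With the default K range and moderate M the effect is diluted and planted
  partitions are still recovered exactly.
- **Ratio normalisation is per block, not absolute.** Each block's
  non-member mass always sums to dc regardless of how small the absolute
  similarities are. When all foreign clusters are nearly equidistant the
  mass spreads harmlessly; when group sizes are very unbalanced and
  similarities nearly underflow, the ratio concentrates the whole mass on
  the single nearest foreign cluster, which can chain otherwise unrelated
  groups together.
- The walk, kernel and spectral steps are dense matrix computations:
  memory is O((n + K_total)²). Cohorts in the low thousands are fine on a
  laptop; much larger n would need sparse variants.

## What the synthetic generator does and does not emulate

Each synthetic view is a Gaussian mixture over one shared latent partition:
cluster centers sit on a scaled random orthonormal frame so every pairwise
center distance equals `separation` (in within-cluster SD units, SD = 1),
a `noise_fraction` of features carries no class signal, and views draw
independent centers and noise. This captures the premise that data types
reflect the same latent grouping through independent lenses, which is the
property the integration step exploits. It does not emulate omics
marginals (count overdispersion, bounded methylation fractions), feature
correlation, batch structure, or partially overlapping cohorts — so
passing recovery tests demonstrates correctness of the machinery under the
shared-partition model, not performance on real cohorts.

Survival times are exponential with cluster-specific hazards
(`baseline_hazard` × per-cluster hazard ratio). Censoring marks each
instance independently with probability `censor_rate` and truncates its
time at a uniform fraction of the event time — a deliberately simple
mechanism that is independent of the event process, sufficient for
calibrating the log-rank test.

## Evaluation

Mean silhouette (Euclidean; singleton clusters scored 0 by convention),
adjusted Rand index against a reference partition, and the log-rank test
for survival separation (classical chi-squared; the k-group generalisation
with k − 1 degrees of freedom when more than two groups are compared) are
exposed behind one `evaluate` surface. Silhouette and ARI are computed by
scikit-learn, the log-rank test by lifelines; the test suite checks each
against an independent brute-force or textbook hand computation. A Cox
concordance index is intentionally out of scope: it scores a fitted Cox
model rather than a clustering.

## Problem sizes used in tests

The end-to-end recovery checks run at n = 300 instances, 3 views of 50
features, M = 30, over 10 seeds; statistical calibration uses 2000 null
survival simulations at n = 200. These sizes give sub-minute runtimes per
check while keeping Monte-Carlo error well inside the asserted bands.
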