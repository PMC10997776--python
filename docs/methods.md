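# Methods

## Model

We assume the rows of a numeric table sample a compact, possibly
non-convex and non-linear space `M` embedded in an ambient space `ℝᵈ`
equipped with a metric `d_A`. The datascape approximates `M` with two
coupled structures built from the sample `X = {x_i}`:

**Neighbor graph.** For each point, its k nearest points under `d_A` form
the *natural* neighbors `N_k(x_i)`. Because nearest-neighborhood is not a
symmetric relation (an isolated point may elect a neighbor in a dense
region that does not reciprocate), the *enforced* neighbors
`N⁺(x_i) = {x_j : x_i ∈ N_k(x_j), x_j ∉ N_k(x_i)}` are added, giving a
symmetric neighborhood `N(x_i) = N_k ∪ N⁺` and an undirected graph whose
edge weights are ambient distances. If the graph has m > 1 components,
the closest cross-component point pair is found for each component pair,
and a minimum spanning tree over this component meta-graph selects the
subset of bridges with minimal total weight (Kruskal; equivalent to
iteratively merging the two closest components). These *connecting* edges
make all geodesics finite but are tagged and excluded from everything
that describes similarity or shape: hull construction, risk-score
neighborhoods, and any query run with `use_connecting=False`.

**Geodesic metric.** `d_G(x_i, x_j)` is the minimum cumulative edge
weight over graph paths (Dijkstra on the sparse adjacency). It agrees
with `d_A` on neighbor pairs, never undercuts it (for metrics satisfying
the triangle inequality), and degrades gracefully to `d_A` everywhere as
k → n−1 when the graph becomes complete.

**Shape.** Each point's neighborhood `{x} ∪ N(x)` is summarized by its
convex hull; `shape(D)` is the union of these local hulls. This is a
convex cover of the support estimate: an ambient point is *inside* the
datascape iff at least one local hull contains it, so holes and cavities
— regions inside the global convex hull but outside every local piece —
are preserved. A dataset point is *extreme* (on the boundary) iff it is a
vertex of every local hull that contains it; the search is restricted to
dataset points rather than the continuum surface, which makes the test
finite at the cost of not enumerating non-sample boundary points.

### Center inclusion

The hull of a point is built over `{x} ∪ N(x)`, including the center
itself. This guarantees `X ⊆ shape(D)` (every dataset point is inside at
least its own hull) and makes the extreme-point test well defined: a
point strictly interior to its own neighborhood hull cannot be a boundary
point. Excluding the center would let isolated points fall outside the
shape entirely.

## Out-of-sample operations

A query point `x*` is inserted by wiring it to its k nearest dataset
points with ambient weights; the base graph and hulls are never rebuilt
(insertion is a query, not a model update, and the stored extreme set is
kept). Boundary distance `d_G(x*, E) = min_{e∈E} d_G(x*, e)` is a single
multi-source Dijkstra sweep from the extreme set. The *extremeness score*
of each dataset point is the same quantity without insertion; it is zero
exactly on extreme points and largest along the interior backbone of the
shape.

For trajectories (time-ordered states of one entity), each state is
scored independently, and the geodesic between the first and last state
is computed after inserting both — the second insertion may select the
first inserted state as a neighbor, so a stationary trajectory has
geodesic length exactly 0. This two-point augmentation is the minimal
extension of single-point insertion that keeps coincident endpoints at
distance zero.

## Risk score

With binary labels, `score(x) = |{y ∈ N(x) : label(y) = 1}| / |N(x)|`,
excluding the point itself and its connecting neighbors. Out-of-sample
scores use the k inserted neighbors. This is an unsupervised classifier:
the datascape is built without looking at labels, which are only read off
the neighborhoods afterwards. The benchmark harness evaluates it with a
label-stratified 4-fold split, rebuilding the datascape on each training
fold and scoring held-out points by insertion; AUC is computed with
midrank tie handling. On well-separated Gaussian classes the score is
essentially a k-NN vote, and the benchmark asserts it stays within 0.1
AUC of one.

## In-shape sampling

Samples are convex combinations of a hull's vertices with flat Dirichlet
weights: uniform on the vertex-weight simplex, rejection-free, and valid
in any dimension, but *not* volume-uniform — mass concentrates toward
vertex-dense regions of each hull. Sampling a fixed count per hull also
weights dense graph regions more heavily. Both biases are acceptable for
the intended use (visual densification and shape-preservation checks:
every sample is inside the shape by construction).

## Parameters

| parameter | default | meaning and guidance |
| --- | --- | --- |
| `k` | 10 | neighborhood size; controls which topological features survive. Small k fragments the graph; large k shortcuts across cavities. The circle experiment and `k_scan` (components + circuit rank per k) support choosing it; 10 is a reasonable desk-scale trade-off, but the right value is study-dependent. |
| `metric` | Euclidean | ambient distance; Manhattan and Chebyshev are registered, and any symmetric non-negative callable is accepted. All coordinates should be on comparable scales. |
| `eps` | 1e-9 × hull diameter | boundary tolerance per hull (absolute floor 1e-12). Points within `eps` of a facet count as inside — required so a vertex is "in" its own hull. |
| `per_hull` | 3 | in-shape samples per neighborhood. |

## Numerical choices

- **k ≥ n** is clamped to n−1 with a warning rather than an error, so
  tiny fixtures work.
- **k-NN ties** are broken by ascending row index; **equal-length
  geodesics** resolve to the lexicographically smallest vertex sequence
  (greedy walk on the shortest-path DAG). Both make builds and tests
  deterministic; neither affects any distance value.
- **Duplicate points** are allowed and become mutual zero-weight
  neighbors; droppable via `drop_duplicates` at ingestion.
- **Degenerate neighborhoods** (affinely dependent, e.g. k ≤ d or data on
  a hyper-surface): the affine rank is estimated by SVD with a relative
  1e-9 cutoff, the points are projected onto their affine span, and
  membership means lying on that lower-dimensional hull within `eps`
  (rank 0 → point, rank 1 → segment, rank ≥ 2 → sub-dimensional
  quickhull).
- **High dimension** (d > 8 full-rank): facet enumeration is abandoned
  for per-point LP vertex identification and LP-feasibility membership on
  the convex-combination system.
- **Dense-matrix threshold**: the full pairwise distance matrix is
  materialized up to n = 8192; beyond that, Euclidean neighbor search
  uses a k-d tree and cross-component minima are computed blockwise.
- **Disconnected geodesics** return an infinite-length sentinel, never an
  exception; the circle error experiment relies on this.

## Synthetic data

The generators encode the study conditions used throughout the tests:

- **sinusoid** (n=1000, d=3): `x ~ U(0, 2π)`, `y = cos x`,
  `z = cos(x − 0.5)`, plus uniform noise `ε_x ~ U(−1, 1)`,
  `ε_y, ε_z ~ U(−0.3, 0.3)`; latent pre-noise values are returned for
  testing.
- **torus** (d=3): parametric surface with `u, v ~ U(0, 2π)`, defaults
  R=2, r=1; uniform in parameter space, not in surface area.
- **circle** (n=100, d=2): unit circle with latent angles, giving exact
  arc-length ground truth.
- **annulus** (n=200): radii U(1, 1.5) — the minimal cavity example.
- **cohort** (n=2000, d=5): two unit-variance Gaussian clouds with class
  means `separation` apart on the first axis, optional label flips. The
  benchmark uses separations 0 (null), 2 (intermediate) and 6 (wide).

These emulate the geometry the method targets (non-convexity, holes,
noise, class overlap) but none of the messiness of real tables: missing
values, mixed scales, heavy tails, label imbalance. Passing tests
demonstrate the geometric and algorithmic contracts, not robustness to
such artifacts; ingestion deliberately rejects missing values rather than
imputing.

## Circle distance-error experiment

For each k, the symmetrized graph is built *without* connecting edges
and all-pairs geodesics are compared with true arc lengths. The per-pair
standardized error is `min(1, |d_G − d_arc| / π)`, with disconnected
pairs assigned the maximal error 1 (π is the largest possible arc
distance, so 1 bounds the connected-pair error too). The curve's shape is
the meaningful output: high error while the graph is fragmented, a sharp
drop once it becomes one component, the minimum near the k where the
cycle of the circle appears (median best k = 6 over seeds), and a slow
rise toward the complete graph, whose geodesics are chords
(`2 sin(a/2)` vs arc `a`). Exact y-values depend on the sample and on
the standardization and are not asserted.

## Known limitations

- Membership scans are O(n) hulls per query (with bounding-box and
  nearest-center short-circuits); no spatial index over hulls.
- Extreme-point detection needs every hull, O(n) quickhull runs; in high
  ambient dimension with sparse data, most points become extreme and the
  inside/outside distinction loses value (dimension reduction upstream is
  the practical remedy).
- The hull union is a support estimate, not a density estimate: sparse
  regions and outliers are indistinguishable.
- Serialization stores points, edges and extreme ids; custom (unnamed)
  metrics cannot be restored from a container.
- `k_scan`'s circuit rank counts independent cycles, a cheap proxy for
  first-homology features; it does not distinguish persistent from
  spurious ones the way a full persistent-homology analysis would.
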