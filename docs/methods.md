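# Methods

This note documents the model implemented by `weakties`, the parameter
defaults and why they hold, what the synthetic generators do and do not
emulate, the numerical conventions, and the known limitations.

## Model and assumptions

A PPI network is a simple undirected graph over opaque protein
identifiers; interactions carry no weights or directions, self-loops and
duplicates are artefacts of upstream exports and are dropped at parse
time. A protein complex is modelled as a densely interconnected **core**
plus peripheral **attachments** bound to the core — the core–attachment
anatomy observed in affinity-purification data.

The central modelling assumption is the *weak ties effect*: edges joining
vertices with dissimilar neighborhoods are the ones that hold the global
network together, while intra-complex edges are locally redundant. Both
facts are measurable. Percolation: deleting edges in ascending order of
topological similarity disintegrates the network far earlier than the
descending order, with a spike in the normalized susceptibility
S̃ = Σ₍s<s_max₎ s²/N at the transition. Anticorrelation: per-edge weak-tie
bridgeness and walk similarity are negatively rank-correlated.

### Bridgeness

Two per-edge scores are implemented exactly (maximum-clique sizes are
computed by pivoting Bron–Kerbosch enumeration restricted to the relevant
closed neighborhood, with a guard that raises above a configurable
neighborhood size rather than approximating):

* reference: `sqrt(C_u * C_v) / C_{u,v}` — constant 1 on every clique
  edge, hence blind to clique size;
* weak-tie: `(1 - J(u,v)) * sqrt(C_{u\v} * C_{v\u}) / C_{u,v}` — equals
  `2(m-1)/m^2` on an isolated m-clique (edges of small cliques are more
  plausibly bridges than edges of large ones) and is maximal on bridges.

"Largest clique containing x" is the *maximum* clique through x; this is
the only reading under which the clique identities above hold. The
Jaccard similarity uses open neighborhoods; a closed-neighborhood switch
exists for sensitivity analysis only. `C_{u\v}` is 1 when deleting v
isolates u (the trivial clique {u}).

### Similarity, virtual network, detection

Edge weights are `W = exp(-B)`, so strong bridges get weights near 0 and
cohesive edges weights near 1. Pairwise similarity is the cubic walk
polynomial `S = W + beta*W^2 + beta^2*W^3`; the truncation at length-3
walks is deliberate (no Katz-style infinite series — the implementation
matches the defining polynomial term for term). `beta` defaults to 0.618,
discounting longer walks; larger beta raises the relative weight of long
walks, which fragments large cores and trades F-measure for coverage (the
`sweep` harness reproduces this trade-off).

The virtual network Φ(G, τ) connects pairs with `S >= tau` (inclusive).
τ has no canonical value; 0.02 is the package's reference operating point
for sparse PPI-like inputs and a sweep is recommended for any new network
— virtual-network size decreases monotonically in τ, which the sweep
table makes visible. Cores are the maximal cliques of Φ(G, τ) with at
least `min_core = 3` members (size-2 cores would make every edge a seed).
Exact enumeration is used rather than a heuristic dense-neighborhood
miner: the virtual network is the object whose cliques *define* cores, so
exactness gives a testable contract.

Attachment selection follows the average-closeness rule: candidates are
vertices outside the core with at least one *original-network* interaction
into it; candidate v is adopted iff `cl(v,U) = sum_u S(v,u)/(|U|+1)` is
(a) at least the candidate average `acl = sum_w cl(w,U)/(|CS(U)|+|U|)`
and (b) strictly positive, where similarities below τ contribute zero to
cl. Convention (b) and the τ-floor are this package's design choice: the
thresholding step already declares sub-τ pairs unreliable ("unconnected"),
so they cannot testify for an attachment. Without the floor, a core
surrounded only by uniformly weak spurious links adopts essentially all of
them (a homogeneous candidate set always satisfies `cl >= acl` because the
denominator adds |U|), and detection loses its robustness to random edge
addition. With floor = 0 the printed rule is recovered, which is the
default of the standalone `closeness`/`select_attachments` functions;
`detect_complexes` passes its τ. Predicted complexes with identical member
sets are deduplicated (first in canonical core order wins); overlapping,
non-identical predictions are retained — the method is overlapping by
design.

### Evaluation

Matching uses the neighborhood affinity `NA(p,b) = |p∩b|^2/(|p||b|)` with
threshold t = 0.2 (the standard choice in this evaluation lineage; both
are flags). F-measure is the harmonic mean of `N_cp/|PS|` and
`N_cb/|BS|`; the coverage rate and the clustering-wise Sn/PPV/ACC/Sep
scores work on the |BS|×|PS| overlap-count matrix, with zero-sum rows and
columns contributing zero (the limit of the defining ratios). Enrichment
uses the hypergeometric upper tail P(X ≥ k) with the PPI network size as
the universe, no multiple-testing correction, a 1e-2 significance cutoff,
and assigns each complex its best group.

## Synthetic data: what it emulates, what it does not

`planted_network` emulates core–attachment structure: each complex is a
core clique (sizes uniform in an inclusive range, default 4–8) plus
attachments (default 2 per complex) each linked to `ceil(0.5 * core
size)` random core members; optional bridge edges join random core pairs
and background noise edges appear i.i.d. over non-edges. Defaults plant
20 complexes with no bridges and no noise; experiments that study bridges
or noise switch them on explicitly. All randomness flows from one seed
through a dedicated generator per call.

The percolation and anticorrelation experiments use 20 size-8 cores, 2
attachments each, 30 bridge edges and background noise 0.01. The noise is
not cosmetic: a noise-free union of cliques is pathologically symmetric —
whole orbits of edges share one similarity value, so any removal order
within a tie class is an artefact of the tie-break (lexicographic by
default; a seeded random tie-break is available for sensitivity checks).
One percent background noise breaks the symmetry the way real data does.

`test_graph_from_catalog` builds the union-of-cliques *test graph* of a
complex catalog; `alter_graph` deletes then adds uniformly random edges,
both percentages relative to the intact edge count (so an addition can
recreate a deleted edge). The robustness experiment grid runs the
detector on each altered graph and scores ACC/Sep against the catalog.
For the union-of-cliques robustness protocol the detector is operated at
τ = 2.0: within-complex pair similarities on a size-8-clique test graph
are ≈ 10, while even mutually reinforcing random added edges stay well
below 2, so the virtual network filters 100 % added noise — raising τ is
the method's own prescription for noisy inputs. Detection accuracy is
then flat (ACC ≈ 1.0) through 100 % edge addition and drops to ≈ 0.7 at
40 % deletion, where destroyed clique edges can no longer be re-derived
from walk support.

What passing these tests does **not** show about real data: planted
complexes are disjoint, equally sized within a run, and embedded in
homogeneous noise; real catalogs overlap, real networks have hubs, broad
degree distributions, and experiment-specific noise structure. Absolute
metric values on the synthetic benchmarks do not transfer to any
database-derived network.

### A documented negative result

The published percolation signature includes the claim that *descending*
(strong-first) removal shows no susceptibility peak. On a 160-vertex
planted graph this is unattainable: every finite graph passes its own
disintegration transition near full removal, and the measured descending
peak (S̃ ≈ 3–9 across seeds and noise levels) exceeds any sensible
"no-peak" bound, while the ascending peak (S̃ ≈ 7–23) arrives far earlier
and larger. The no-peak behaviour reported on a 4,928-protein interaction
network reflects hub-dominated, heterogeneous structure that smears the
strong-first transition — structure the union-of-cliques generator does
not (and is not meant to) reproduce. The corresponding acceptance test
asserts the full published signature and its descending clause fails; the
two robust clauses (strictly earlier disintegration, ascending spike)
hold.

## Numerical choices and degenerate inputs

* Susceptibility excludes exactly one largest component when several tie
  for the maximum; singletons count as size-1 components; the divisor is
  the vertex count N (not the component count — the alternative
  normalization in parts of the literature is noted but not used).
* Percolation scores are computed once on the intact graph and never
  refreshed during removal; removal is batched (`ceil(step * |E|)`,
  default step 0.01); ties break lexicographically.
* Walk similarity switches from dense to sparse matrix powers above 2,000
  vertices; results are identical.
* Diagonal similarity entries are computed but never consulted.
* Empty graphs: giant-component fraction and susceptibility are undefined
  (error); edgeless inputs yield empty catalogs; empty predicted or
  benchmark sets give defined-zero scores with a warning.
* The hypergeometric tail is computed through the log-stable survival
  function; it matches exact rational summation to 1e-12 on universes up
  to 60.
* Catalog order is stable under read→write round-trips; detection output
  is fully deterministic and invariant under vertex relabelling.

## Known limitations

* Exact maximal-clique core mining enumerates *every* maximal clique; on
  heavily noised dense inputs at low τ this multiplies overlapping
  spurious cores (the τ = 2 operating point above is the antidote for
  union-of-cliques robustness runs). A heuristic dense-neighborhood miner
  would behave differently in that regime.
* The neighborhood-size guard (default 200) makes clique queries refuse
  pathological hubs rather than approximate; raise it explicitly for
  dense graphs.
* No identifier normalization, no PSI-MI/MITAB parsing, no GO DAG
  semantics: inputs are taken as given.
* τ and β interact; the sweep harness, not a fixed default, is the
  recommended way to set τ on a new network.
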