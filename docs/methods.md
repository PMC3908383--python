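# Methods

## The walk model

Let *G(V, E)* be an undirected PPI network with positive edge weights
(binary networks are the weight-1 case). Move probabilities are
*P(v,u) = w(v,u)/d(v)*, where *d(v)* is the weighted degree (strength);
rows of isolated nodes are zero. The resistance walk started at *v* holds an
occupancy vector *q* with *q(0) = e_v* and updates, for each ordered edge
*(i, j)*:

- candidate flow *c = qᵢ(k) · Pᵢⱼ*;
- if *j* has been visited (held positive mass at any step ≤ *k*), the flow
  is *max(0, c − ε)*: every traversal pays the toll ε;
- if *j* is unvisited, the same flow applies only when
  *maxᵢ(qᵢ(k)Pᵢⱼ) ≥ β*; otherwise all flows into *j* are blocked this step;
- *qⱼ(k+1) = Σᵢ fᵢⱼ(k+1)*, and *j* counts as visited once *qⱼ(k+1) > 0*.

The source is visited at *k = 0*. The update is deterministic flow
bookkeeping — no sampling, hence no random seed in this stage.

Two consequences shape everything downstream. First, with ε > 0 total mass
strictly decreases by at least ε per live edge and the walk provably dies in
at most ⌈1/ε⌉ steps, so the *instantaneous* final state is the zero vector
and carries no information; the **topological profile** is therefore the
cumulative visitation vector Σₖ q(k) (a `profile="final"` mode returning the
last positive occupancy is kept for experimentation). Second, the β gate
binds only at *first entry*: it stops the walk from leaking into the
periphery through hubs, whose many outgoing flows are individually weak,
without taxing flow inside already-reached dense regions. At ε = β = 0 the
dynamics reduce exactly to the ordinary random walk and the cumulative
profile equals Σ_{k≤K} e_v Pᵏ, which the tests use as a matrix-power oracle.

The PP-TS matrix is the Pearson correlation of profile rows over all node
columns (no column exclusion — the simplest defensible convention, and
configurable territory if ever needed). Constant rows get correlation 0
with everything and are logged; other diagonal entries are set to 1.

### Walk parameters

| parameter | default | meaning |
|---|---|---|
| ε (`epsilon`) | 0.01 | per-traversal toll (units of probability mass) |
| β (`beta`) | 0.05 | first-entry threshold on the strongest incoming flow |
| `max_steps` | 100 | hard cap; rarely reached since ε kills the walk first |
| `tol` | 1e-6 | stop once remaining total mass ≤ tol |

ε = 0.01 lets a unit walk survive roughly two to three hops on a
degree-5 network (first-hop flows ≈ 0.2, second-hop ≈ 0.03), so profiles
capture the 2-hop neighbourhood — the scale at which co-complex proteins
share structure. β = 0.05 blocks first entries weaker than 5% of the
initial mass, which on a degree-5 network admits direct neighbours and
strong second-hop paths but not hub fan-out. These are package defaults, are
echoed in every output manifest, and are deliberately not tuned per network.

## Clustering

Modularity is the weighted Newman–Girvan form
*Q = Σ_c [w_in(c)/W − (s(c)/2W)²]*.

**Qcut** alternates two phases until neither improves *Q*:

1. *Spectral partitioning*: each community is recursively bisected by the
   leading eigenvector of its generalized modularity matrix
   *B⁽ᵍ⁾ᵢⱼ = Bᵢⱼ − δᵢⱼ Σ_{l∈g} Bᵢₗ* with *Bᵢⱼ = Aᵢⱼ − sᵢsⱼ/2W*, followed by
   a Kernighan–Lin sweep on the sign vector; a split is accepted iff its
   exact global ΔQ = sᵀB⁽ᵍ⁾s/4W is positive.
2. *Refinement*: the best strictly-Q-increasing single change among vertex
   moves (ΔQ = (K_vb − K_va)/W − s_v(s_b − s_a + s_v)/2W²) and community
   merges (ΔQ = E_ab/W − s_a s_b/2W²) is applied repeatedly to a local
   optimum.

Connected components are clustered independently; isolated nodes are
singleton communities. The public `refine()` operator additionally offers
community *splits* implemented as Qcut on the induced subcommunity; inside
Qcut itself the split role is played by the spectral phase, which the outer
loop re-runs after every refinement pass — the result is still a local
optimum under all three operator families, without recursive self-calls.
Everything is deterministic: eigenvector sign is fixed by making the
largest-magnitude entry positive, and the "best change" scan order (node
order, then community order) breaks exact ties.

**HQcut** re-runs Qcut inside each community (of ≥ 4 nodes) and accepts the
subdivision when the sub-partition's own modularity exceeds `q_threshold`
(default 0.3) **and** its empirical p-value is below `alpha` (default 0.05),
recursing on accepted subdivisions. The p-value is
(1 + #{Q_null ≥ Q_obs}) / (1 + n_random) over Qcut modularities of
degree-preserving rewirings of the subnetwork, so at the default
n_random = 30 the smallest attainable p is 1/31 ≈ 0.032. The threshold is
applied to the trial subdivision's Q — the only reading under which it can
gate subdivision at all. With `q_threshold = inf`, HQcut equals Qcut
exactly.

**Null model.** Degree-preserving Maslov–Sneppen double-edge swaps
(10·|E| attempted successes, attempts capped at 20× that), with the weight
multiset shuffled onto the rewired edge set. Degree preservation matters
because modularity is strongly degree-driven and PPI networks are
degree-skewed; a density-matched Erdős–Rényi null would systematically
overstate significance. Graphs admitting no legal swap (a triangle) return
unchanged, which makes the modularity difference of such graphs exactly 0 —
a useful fixed point for tests.

## Cutoff selection

`auto_hqcut` thresholds the PP-TS matrix at each grid cutoff (edge kept iff
similarity ≥ cutoff, inclusive; all nodes retained so partitions cover every
protein), discards unusable rows (no edges, or largest component < 4 nodes),
and scores the rest by *Q_diff = Q_obs − mean(Q_null)* where both terms are
HQcut modularities and the nulls are rewired copies of the thresholded
network (n_random of them; the null spread is also reported). The argmax row
wins; ties go to the smaller cutoff because the denser network discards less
evidence. The default grid is 0.30–0.95 in steps of 0.05. On synthetic
benchmarks Q_diff and the (held-out) Fowlkes–Mallows accuracy are strongly
rank-correlated across the grid (Spearman ≈ 0.95 in the acceptance tests),
which is precisely the property that makes the label-free selection work.

## Evaluation

Predictions (disjoint partitions) and references (possibly overlapping
complex sets) are compared on co-membership pairs restricted to the shared
protein universe; overlapping reference complexes contribute each pair once.
The accuracy is the Fowlkes–Mallows index |A∩B|/√(|A|·|B|) — the geometric
mean of pairwise precision and recall — with the convention 0 (plus a
warning) when either pair set is empty. Per-complex accuracy restricts the
prediction to one complex's proteins, which reduces to √(|A|/|B|) because
every restricted co-clustered pair is a reference pair; how to attribute a
complex split across several predicted communities is genuinely
underdetermined, and this restriction-based definition is our
operationalization. Pairs missing from an external score table are excluded
from curve means (not scored 0) with the effective count reported.

GO semantic similarity is *not* computed internally; it enters as a
precomputed pair-score table. Co-expression is plain Pearson correlation
over conditions, with zero-variance genes dropped.

## Synthetic benchmark

Defaults: 12 disjoint planted complexes with sizes uniform on 4–8,
p_in = 0.8, p_out = 0.01 — a sparse network (mean degree ≈ 5) of small
complexes, emulating a curated-catalogue setting where most complexes have
a handful of members. Degradation follows the PPI noise model: delete
round(fn_rate·|E|) true edges uniformly, add round(fp_rate·|E|) random
non-edges, optionally attach hub nodes to a random 20% of proteins.
The degradation study conditions used throughout are fn = 0.3, fp = 0.1.
Planted complexes are disjoint even though real references overlap
(evaluation handles overlap; generation keeps the ground truth
unambiguous), and no attempt is made to match a specific real degree
distribution.

What passing synthetic tests does *not* show: robustness to systematic
(non-uniform) measurement bias, to overlap between true complexes, or to
identifier-mapping noise — all of which real PPI/complex data contain.

## Problem sizes and statistics in the test bench

The acceptance-style tests run at desk scale by choice: networks of
~50–130 nodes, cutoff grids of 7–9 points, n_random = 6 rewired nulls per
scan row and 24 inside HQcut's significance test (enough for p < 0.05 to be
attainable). The end-to-end comparison uses 16 replicate seeds: a one-sided
sign test at the observed ~0.8 per-seed win rate is underpowered at 10–12
replicates, and 16 gives ~80% power at α = 0.05. The acceptance script
reports means over 6 replicates seeded from its `--seed`.

## Known limitations

- Dense n×n profile propagation: fine to a few thousand proteins, not for
  proteome-scale interactomes without blocking.
- The greedy best-first refinement applies one change per pass and can be
  slow on networks far above the tested scale.
- Auto-HQcut tends to select the densest valid cutoff when the grid starts
  above the noise floor; a grid reaching below the informative range wastes
  scan time but does not change the selection rule.
- `community_pvalue` needs n_random ≥ 20 for p < 0.05 to be reachable;
  smaller values silently make subdivision impossible.
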