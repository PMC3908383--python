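# rwscomplex

Protein complex prediction from protein–protein interaction (PPI) networks.

High-throughput PPI networks are binary, sparse, and noisy: they carry a high
false-positive rate, an even higher false-negative rate, and a hub-heavy
degree distribution — all of which hurt clustering algorithms that look only
at direct neighbours. `rwscomplex` addresses this for computational
biologists who want complex predictions from an edge list, in three stages:

1. **Random Walk with Resistance (RWS).** From every protein *v*, a unit of
   probability mass is propagated through the network with transition
   probabilities *P(v,u) = w(v,u)/d(v)*. Each edge traversal pays a toll ε
   (the flow along *(i, j)* at step *k+1* is max(0, *qᵢ(k)Pᵢⱼ* − ε)), and a
   never-visited node is entered only if its strongest incoming candidate
   flow reaches β — damping hub smearing and bounding walk depth. The
   cumulative visitation vector of the dying walk is *v*'s topological
   profile, and the Pearson correlation between profiles gives the dense
   **protein–protein topological similarity (PP-TS) matrix**: two proteins
   are similar when they see the rest of the network the same way, whether
   or not they are directly connected.

2. **Auto-HQcut.** A cutoff converts the PP-TS matrix back into a sparse
   weighted network. For each candidate cutoff, the network is clustered by
   HQcut — recursive Newman–Girvan modularity (*Q*) maximization that
   subdivides a community when its internal structure is strong
   (sub-*Q* > 0.3) and significant (empirical *p* < 0.05 against
   degree-preserving rewired nulls), correcting modularity's resolution
   limit — and the cutoff is scored by the modularity difference
   *Q_diff = Q_obs − mean(Q_null)*. The cutoff with the largest *Q_diff*
   wins; its communities are the predicted complexes.

3. **Evaluation.** Predictions are scored against a reference catalogue
   (e.g. curated complexes) with the Fowlkes–Mallows index
   |A∩B|/√(|A|·|B|) over co-membership pairs, and PP-TS rankings can be
   checked against external per-pair functional scores (GO similarity
   tables, or gene co-expression computed from an expression matrix).

A planted-complex synthetic generator with PPI-style degradation (uniform
false-negative deletion, random false-positive insertion, optional hubs)
makes the whole pipeline testable without any external download.

## Worked example

Predict complexes on a degraded planted benchmark (51 proteins in 8 planted
complexes, 30% of true edges deleted, 10% spurious edges added):

```sh
cat > demo.yaml <<EOF
synthetic:
  n_complexes: 8
  size_range: [4, 8]
  fn_rate: 0.3
  fp_rate: 0.1
  seed: 5
grid: [0.3, 0.5, 0.7]
n_random: 6
pvalue_n_random: 24
seed: 42
EOF
rwscomplex run --config demo.yaml --outdir demo_out
```

prints

```
n_nodes: 51
n_edges: 109
selected_cutoff: 0.3
selected_q: 0.8105399194146286
n_communities: 8
fowlkes_mallows: 0.7750911453015731
```

and `demo_out/cutoff_scan.tsv` holds the full audit trail:

```
cutoff  n_edges  valid  Q_obs     Q_null_mean  Q_null_sd  Q_diff    n_communities
0.3     101      True   0.81054   0.483042     0.0131714  0.327498  8
0.5     46       True   0.819625  0.60174      0.0197973  0.217885  21
0.7     14       True   0.66122   0.546727     0.0457651  0.114493  41
```

Cutoff 0.3 maximizes the modularity difference (0.327) and yields 8
communities — the planted complex count — with a Fowlkes–Mallows accuracy of
0.775 against the ground truth; higher cutoffs shred the network into many
small fragments and score a lower *Q_diff*, exactly the behaviour the
selection rule exploits. The run also writes the PP-TS matrix, the selected
partition, a per-complex evaluation table, a GraphML export (openable in
Cytoscape), and a `manifest.json` echoing every effective parameter so the
run is exactly reproducible.

The same stages are available individually (`rwscomplex synth / rws /
cluster / auto / evaluate / export`) and as library functions
(`build_ppts`, `auto_hqcut`, `hqcut`, `fowlkes_mallows`, ...). To run on
real data, pass a TSV edge list (`node1<TAB>node2[<TAB>weight]`) or SIF file
instead of the `synthetic` block, and a `complex_id<TAB>protein` reference
file for evaluation.

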