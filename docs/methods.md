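# Methods

## Model

`specfam` treats protein homology inference as graph partitioning.
Vertices are sequences; an edge between sequences *i* and *j* carries a
weight `s_ij ∈ (0, 1)` interpreted as the probability that the pair is
evolutionarily related, derived from the better of the two BLAST
E-values reported for the pair. The clustering objective is implicit in
the spectral relaxation: groups of vertices connected mostly by
heavy-weight edges should end up in the same cluster.

The spectral step follows the standard normalized-affinity recipe:
`L = D^(−1/2) S′ D^(−1/2)` where `S′` is the symmetric affinity matrix
after small-component removal (unit diagonal) and `D` the diagonal
matrix of its row sums. Eigenvalues of `L` lie in `[−1, 1]`; the
eigenvalue 1 has multiplicity equal to the number of connected
components. The rows of the matrix of the top-K eigenvectors, scaled to
unit length, place vertices of well-separated clusters near K mutually
orthogonal points, which a k-means pass then separates.

### Assumptions

- Similarity is meaningfully monotone in the E-value, and one logistic
  curve on `−log10 E` captures the intra/inter discrimination. Domain
  architecture, alignment coverage and compositional bias are not
  modelled.
- Pairs with no reported hit have similarity exactly 0 (structural
  sparsity). BLAST's reporting cutoff therefore shapes the graph.
- Clusters are "flat": each sequence belongs to exactly one family.
  Multi-domain proteins that genuinely belong to several families are
  forced into one.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 1.02 | eigengap ratio threshold; K = smallest k with λ_k/λ_{k+1} > ε. Larger values make the gap harder to cross, selecting more clusters (finer granularity). |
| `min_component_size` | 5 | components smaller than this bypass the spectral stage and re-enter as final clusters. |
| `bridge_weight` | 0.005 | weight of the random chain edges connecting residual components; must stay below 0.01 so the perturbation of the spectrum is negligible. |
| `evalue_floor` | 1e-180 | clamp before the log transform; BLAST reports E = 0.0 for very strong hits. |
| CCA `evalue_threshold` | 1e-6 | edge-retention cutoff of the connected-component baseline. |
| hierarchical `cut_evalue` / `missing_evalue` | 1e-6 / 10 | dendrogram cut level and the distance assigned to unreported pairs (the default BLAST reporting ceiling), both on the raw E-value scale. |
| enrichment `alpha` / `min_cluster_size` | 0.05 / 3 | BH-corrected significance level; clusters below the size floor are excluded from testing and from the summary ratios. |
| `seed` | 0 | single seed feeding every random draw (bridging, centroid init, generators). |

## Numerical choices

- **Degrees.** For `L`, vertex degrees include the unit diagonal of
  `S′`, guaranteeing strictly positive degrees. For the quality metrics
  (mass fraction, modularity) self-similarities are excluded from
  `d_i` and `m`; this makes the all-singleton mass fraction exactly 0
  and keeps the all-in-one-cluster modularity exactly 0. Under this
  convention the all-singleton modularity is `−Σ_i d_i²/(2m)²`, which
  is slightly negative rather than zero — the standard weighted Newman
  form is used deliberately.
- **Eigensolver.** Dense symmetric decomposition (`numpy.linalg.eigh`)
  for n ≤ 64 or when nearly the full spectrum is requested; otherwise
  implicitly restarted Lanczos (ARPACK via `scipy.sparse.linalg.eigsh`)
  with a seeded start vector for determinism. Every returned pair must
  satisfy `‖L·u − λ·u‖ ≤ 1e-6` or the solver errors out. In automatic
  mode at most `min(n − 1, 200)` eigenvalues are computed before the
  gap scan; 200 comfortably covers realistic cluster counts and the
  bounded mode exists precisely for problems where a cheaper upper
  bound is known.
- **Eigengap edge cases.** A ratio across a non-positive `λ_{k+1}` is
  meaningless (the spectrum of `L` can be negative) and is treated as
  an immediate gap. A perfectly flat scanned spectrum selects the full
  scan length with a warning.
- **Logistic fit.** Unpenalized maximum likelihood via IRLS
  (statsmodels GLM/Binomial, 200 iterations). When the two training
  classes are perfectly separated on the feature — detectable exactly
  in one dimension as disjoint ranges — the ML optimum does not exist;
  the fit warns and returns the iteration-capped coefficients, whose
  decision boundary approaches the margin midpoint. The similarity
  output is clipped to `[1e-300, 1 − 1e-16]` because the sigmoid
  saturates in float64.
- **k-means.** Lloyd iterations with Euclidean distance on the
  unit-norm rows (equivalent to cosine ordering), `max_iter` 300,
  centroid-shift tolerance 1e-6. Initial centroids are data points
  chosen greedily to minimize the maximum absolute cosine to those
  already picked, after a seeded random first pick. Empty clusters are
  re-seeded with the farthest point so the selected K survives.
- **Degenerate embedding rows.** Rows of the eigenvector matrix with
  norm below 1e-12 (possible under numerical cancellation) are excluded
  from k-means and afterwards adopt the label of their
  strongest-similarity non-degenerate neighbour, falling back to the
  nearest cluster mean.
- **Bridging.** With c residual components, c − 1 edges of fixed weight
  0.005 connect them in a seeded random chain — the minimal perturbation
  that guarantees connectivity. Quality metrics are computed on the
  original, un-bridged graph.
- **Hierarchical tie-breaks.** scipy's average-linkage merge order is
  used as-is; it is deterministic, which is all the tests require.

## Synthetic data

The planted-partition generator emulates the statistical signature of
all-against-all BLAST over a set of families: log10 E-values are drawn
from an intra-cluster Gaussian (mean −50, sd 10) and an inter-cluster
Gaussian (mean 0, sd 1), pairs are reported with probability 0.9
(intra) and 0.05 (inter), and E-values are clipped to
`[1e-180, 10]` — the similarity-model floor and the default BLAST
reporting ceiling. The means and densities mirror the clear separation
of intra- vs inter-superfamily E-value populations in curated data; the
standard deviations are the package's own choice of a realistic spread
(intra-family E-values range over many orders of magnitude; spurious
inter-family hits cluster near E = 1). An asymmetric mode emits both
query directions with independently jittered E-values to exercise the
min-E symmetrization.

What the generator does *not* emulate: heavy-tailed per-sequence hit
counts, multi-domain chaining (one protein bridging two families
through different domains), compositional-bias artifacts, and
transitive similarity decay within large diverse families. Passing the
recovery tests therefore demonstrates correctness of the pipeline on
cleanly separated family structure, not performance on hard remote
homology — where real benchmarks show all methods degrade.

Default study conditions used in the tests: 3 planted blocks of 20
sequences, the distribution parameters above, fixed seeds. The
enrichment null calibration uses 1,000 replicates of random annotations
(4 terms, carrier probability 0.3) over a fixed 10-cluster partition of
60 ids; the brute-force quality-metric checks enumerate all partitions
of random graphs up to 8 vertices (4,140 partitions).

### Toy worked example

`specfam.synthetic.toy_worked_example()` returns a fixed 12-sequence,
3-family instance used in examples: families `gl1–gl4`, `ef1–ef4` and
`tx1–tx4` with intra-family E-values

| pair | E | pair | E | pair | E |
|---|---|---|---|---|---|
| gl1–gl2 | 1e-42 | ef1–ef2 | 2e-28 | tx1–tx2 | 1e-30 |
| gl1–gl3 | 3e-38 | ef1–ef3 | 8e-25 | tx1–tx3 | 2e-29 |
| gl1–gl4 | 2e-35 | ef1–ef4 | 1e-22 | tx1–tx4 | 7e-28 |
| gl2–gl3 | 5e-40 | ef2–ef3 | 6e-27 | tx2–tx3 | 4e-31 |
| gl2–gl4 | 1e-33 | ef2–ef4 | 3e-24 | tx2–tx4 | 5e-29 |
| gl3–gl4 | 4e-37 | ef3–ef4 | 9e-26 | tx3–tx4 | 1e-27 |

and three weak cross-family hits gl1–ef1 (0.7), ef2–tx1 (1.5),
gl3–tx2 (2.0). Thresholded component analysis at 1e-6 and spectral
clustering with K = 3 both recover the three families exactly.

## Known limitations

- The combined F-score is asymmetric (gold families pick their best
  cluster); swapping the roles of gold and predicted changes the value.
- Eigengap selection assumes a spectral gap exists; on graphs with
  smoothly decaying spectra (e.g. one homogeneous random graph) the
  automatic mode warns and returns a large K.
- The hierarchical baseline materializes a dense n×n distance matrix,
  so it is quadratic in memory and only suitable up to tens of
  thousands of sequences.
- GO term enrichment tests each term independently against the flat
  annotation sets supplied; no DAG ancestry propagation is performed.
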