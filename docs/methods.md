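# Methods

## Similarity model

The unit of evidence is a pairwise alignment statistic pair
(E-value, bit-score). The two are fused into the EB-score
`EB = −ln(E) · bits`, clamped to zero by a Heaviside step with
`H(0) = 1`. Conventions:

* **Log base.** Natural log, the convention of E-value statistics
  (`eb_score(log_base=...)` overrides it). The choice only rescales
  every edge weight by a constant, and the threshold ladder is built
  from the weight range, so classification is invariant to it.
* **Underflow.** Tools report `E = 0` below their printable range; the
  E-value is clamped to `1e-180` before the log so the EB-score stays
  finite and ordering-correct.
* **Symmetrization.** The family graph is undirected but search tools
  report directed hits, possibly several HSPs per pair. One unordered
  pair gets the **maximum** EB over both directions and all HSPs — the
  strongest evidence for homology wins. A missing pair means "no
  detectable similarity" and is exactly weight 0, which is "no edge" at
  every pyramid level including t = 0.
* **Built-in aligner.** For FASTA-only runs, `align_pair` computes a
  Smith–Waterman local alignment with affine gaps (BLOSUM62, gap open
  11 / extend 1 — a gap of length k costs 11 + k) through Biopython's
  `PairwiseAligner`, and converts the raw score with standard gapped
  Karlin–Altschul parameters (λ = 0.267, κ = 0.041), search space
  defaulting to the product of the sequence lengths. This gives
  bit-scores and E-values on familiar scales; it performs the exact DP,
  not a heuristic seeded search, so it is meant for moderate problem
  sizes.

## Thresholds and the pyramid

The global ladder quantizes the *edge-weight* range: n uniformly spaced
cutoffs over (0, w_max], w_max the largest training edge weight. An
edge whose weight equals a cutoff survives it (the `H(0) = 1` boundary
again). Nested views follow: every edge set at a higher threshold is a
subset of every lower one.

Each feature works on a contiguous slice of the ladder (defaults for
n = 10; all configurable):

| feature | levels | default parameters |
|---|---|---|
| AC, RC | 6–10 | T_AC = T_RC = 0; r = 3 below the ladder midpoint, 5 above |
| SM, TR | 3–7 | star power p = 2; k-max fan-in k = 3 |
| GE | 1–2 | evaluated at the lowest level only |

Rationale: clustering and rich-club deltas are precise exactly where
edges are scarce and only strong matches remain; triangle and star
counts need a moderately dense band; the spectrum is informative only
where the graph is dense, so energy works at the bottom with the
smallest candidate pool. r grows with the level because "rich" means
more as hubs shed weak edges. k = 3 (never stated by the sources the
parameters otherwise follow) is small enough to prune and large enough
for the five-set mode to be meaningful.

## Qualification rule

A family qualifies for a candidate set at level t when

1. the query *interacts* there — at least one attachment weight
   survives t, and
2. the feature delta clears the secondary threshold,
   `Δ − T ≥ 0` (for AC/RC), or is strictly positive (SM/TR/GE k-max).

The interaction gate matters: with the default T = 0, an isolated query
leaves an empty or unchanged view unchanged (Δ = 0), and a bare `Δ ≥ 0`
rule would flood the top level with spurious candidates. t\* is the
highest qualifying level; the search stops there.

## Tie resolution, in order

1. mode of AC ⊎ RC ⊎ SM ⊎ TR ⊎ GE is unique → done;
2. re-vote SM and TR with k = 1 at their t\*, mode of
   SM₁ ⊎ TR₁ ⊎ GE unique → done;
3. single largest strictly positive ΔGE over SM ∪ TR (label order
   breaks exact numerical ties) → done;
4. otherwise **nd** — surfaced, never guessed, and counted separately
   from wrong decisions.

If the AC shortlist is empty (the query interacts at no AC level), the
classifier consults only the energy arbiter over all families, the
low-threshold analogue of step 3; if no family gains energy, the result
is nd.

## Graph energy: binary vs weighted adjacency

`graph_energy(view)` defaults to the binary adjacency of the view,
consistent with the binary matrix used for triangle counting. The
*classifier*, however, defaults to the weighted variant
(`PyramidConfig.weighted_ge = True`), and this is a deliberate,
measured choice: on a dense view the binary spectrum saturates — on a
90%-dense 27-vertex graph, a query with 2 edges gains ≈2.05 energy
while a query with 26 edges gains ≈2.49 — so two weak cross-family
edges can outvote full-family membership. The weighted gain keeps
tracking interaction strength (edge weights enter the spectrum), which
matches the geometric "graph spread" intuition the feature encodes.
Both variants are exposed; `weighted_ge=False` restores the binary
arbiter.

Other degenerate-case conventions: a vertex with < 2 neighbours has
clustering 0; φ(r) is 0 when fewer than two vertices exceed degree r;
star motifs count degree **≥ p** rather than = p, which makes ΔSM
monotone under attachment (a query can only strengthen hubs).
Eigenvalues come from the symmetric solver (`eigvalsh`); no small-value
cutoff is applied since near-zero eigenvalues contribute nothing to the
sum of absolute values.

## Determinism

Identical model + query + configuration always produce the identical
result, including the tie path: candidate sets are computed over
label-sorted classes, all argmax ties break by ascending label, and the
evaluation counter is part of the result. Incremental updates replace
exactly one family graph and are rebuild-equivalent: attaching a query
gives the same matrix as rebuilding the family from the enlarged member
list.

## Synthetic benchmark

`simulate_score_network` emulates the two load-bearing properties of
real family similarity networks:

* **Separation** — intra-family EB-scores are drawn
  LogNormal(μ_in = 6.0, σ = 0.25), sporadic inter-family scores
  LogNormal(μ_out = 5.0, σ) on a random 5% of cross pairs. The 4σ gap
  between the log-means is the documented separable-benchmark
  condition; log-normal weights reflect the heavy-tailed spread of
  real EB-scores.
* **Hubs** — intra-family pairs are thinned to 90%, retained with
  probability ∝ ((deg_i+1)(deg_j+1))^γ (γ = 1 by default): the
  rich-gets-richer mechanism that concentrates edges on a few
  sequences, as gene duplication does in practice.

10% of each family is withheld as queries (80% for the
scarce-training experiment); the score table covers query rows too, so
incremental learning can link later queries to earlier ones. Every
generator is a pure function of its spec, seed included.

What the generator does **not** emulate: realistic evolutionary
divergence (indels, rate heterogeneity, domain shuffling), BLAST's
E-value statistics, or families of very unequal size. Passing the
recovery benchmark therefore demonstrates that the machinery exploits
separation and hub structure correctly — not that it reaches any
particular accuracy on real family databases, where separation is far
messier.

The default experiment sizes (20 families × 30 members; five seeds for
the learning comparison) keep the whole suite and the acceptance script
comfortably fast on a single CPU while leaving enough queries (60, and
480 per seed in the scarce-training run) for stable rates.

## Evaluation

cd / wd / nd are correct / wrong / no decisions;
precision = cd/(cd+wd) with nd reported separately (never folded into
wd), and left as "not applicable" when nothing was decided.
`compare_efficiency` counts (feature, class, level) delta evaluations —
a deterministic, hardware-independent proxy for testing time.
`roc_sweep` varies the secondary thresholds (T_AC, T_RC) and
micro-averages one-vs-rest: a correct decision is one true positive
among n positives, a wrong decision one false positive among n·(M−1)
negatives. What is swept to obtain an ROC is a design choice here; the
secondary thresholds are the natural acceptance knobs of the voter.
Per-feature ROC curves (classifying with a single GSF) are not built
into `roc_sweep`; single-feature behaviour is visible instead through
the `sweep` report of feature values per level.

## Known limitations

* The exact-DP aligner is quadratic per pair; all-vs-all FASTA scoring
  is for benchmarks and small databases, not proteome-scale search.
* Dense weight matrices per family: memory is O(N²) in family size.
* The ladder-slice defaults are tuned for 10 levels; other level counts
  get proportional slices that always cover the ladder but have not
  been optimized.
* Secondary thresholds default to 0 and rely on the interaction gate;
  `tune` grid-searches them on a validation split when families are
  less separable.
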