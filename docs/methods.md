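# Methods

## Problem and model

`slranker` ranks candidate synthetic-lethal (SL) gene pairs in a tumor cohort.
The premise: if two genes are synthetic lethal, tumors carrying a mutation in
both should be selected against, so across a cohort their somatic mutations
appear mutually exclusive; and because jointly losing the pair is catastrophic
for the cell, the pair tends to occupy structurally important positions in the
cancer interaction network. Known SL pairs are scarce, so the ranker is
semi-supervised: it orders a large unlabeled candidate set by feature
similarity to a small positive set instead of fitting a classifier.

The pipeline has four stages.

### 1. Candidate screening

From a binary gene×sample mutation matrix, genes with mutation rate ≥ 1%
(boundary inclusive) are paired with every gene of the cancer network.  For
each pair A,B the 2×2 table over samples is

|            | B mutant | B wild type |
|------------|----------|-------------|
| A mutant   | M        | N           |
| A wild type| X        | Y           |

Pairs are kept when the Yates-corrected Pearson chi-square test rejects
independence (p ≤ 0.05) **and** mutation exclusivity (X+N)/(M+N+X) ≥ 0.8.
Both thresholds are inclusive. Pairs with a zero marginal (test undefined) or
with no mutated sample (exclusivity undefined) are dropped, not imputed.  No
multiple-testing correction is applied at this stage — the screen is a recall
filter, not an inference.

### 2. Three features per pair

- **Mutation coverage** — fraction of samples mutated in at least one member.
- **Driver score** — −log10 of the smaller of the two genes' driver p-values
  (floored at 1e−16, so the score caps at 16). Driver p-values come either
  from an external per-gene TSV (so the output of a dedicated driver-discovery
  tool can be plugged in) or from the built-in scorer: expression-outlier
  events (|z| ≥ 2, per-gene mean/SD across samples; zero-SD genes yield no
  events) are greedily explained by mutated genes — an event (g, s) is
  coverable by gene m mutated in sample s iff g = m or g neighbors m in the
  cancer network. The gene covering the most uncovered events is selected
  repeatedly (ties: lexicographic). Significance: the mutation matrix's gene
  labels are permuted (default 100 permutations, seeded) and the greedy run
  repeated; a selected gene's p-value is the add-one fraction of permutations
  whose selection at the same greedy rank covers at least as many events.
  Unselected genes get p = 1. The rank-matched null keeps the comparison
  between like quantities (best-vs-best, second-vs-second), since greedy
  coverage decays with rank by construction.
- **Network information centrality** — relative efficiency drop
  C = |E(G) − E(G′)|/E(G) when the pair's nodes are deleted from the
  biomarker-filtered network. Efficiency is the average reciprocal
  shortest-path length over ordered node pairs; unreachable pairs contribute
  1/(D(G)+1) with D(G) the diameter of the **original** network. Deleting a
  node absent from the network is a no-op; a pair entirely outside the network
  scores 0; a deletion that leaves fewer than two nodes gives E(G′) = 0 and
  hence C = 1.

Each feature is min–max normalized to [0,1] jointly over positives ∪
candidates (a constant feature maps to all zeros). Joint normalization is
forced by the ranker: both sets must live on one scale.

### 3. Manifold ranking

Normalized triples are points x_i; the first q points are positives (y_i = 1),
the rest candidates (y_i = 0). With W_ij = cos(x_i, x_j), W_ii = 0,
L = D^{−1/2} W D^{−1/2}, the scores are

    f* = (1 − α) (I − αL)^{−1} y,   α ∈ [0, 1)

equivalently the fixed point of f ← αLf + (1−α)y. Candidates are ranked by
f* descending; ties (after rounding scores to 12 decimals to absorb solver
round-off) break lexicographically by pair name. α controls how far label
mass diffuses: α = 0 returns y itself, α → 1 weights the manifold structure
maximally.

The affinity text "1 − cosine distance" is read as cosine **similarity**
(high for similar pairs), since the quantity weights relevance between
neighboring points; the literal cosine-distance reading is available via
`RunConfig.affinity = "distance"`.

### 4. Evaluation and α selection

α is chosen by 10×5-fold cross-validation over a grid (default 0.00–0.99,
step 0.01): positives are shuffled (seeded per shuffle) and split into five
folds; held-out positives join the unlabeled set with y = 0 and are ranked
like candidates. Each fold records NDCG@p and the hypergeometric enrichment
of held-out positives in the top p, with p = the held-out count (configurable
via `top_k`). The α maximizing mean NDCG wins; ties go to the smallest α.
The final model then trains on **all** positives at the chosen α.

NDCG@p uses binary gains (2^rel − 1)/log2(i+1) with the ideal ranking
truncated at min(#relevant, p). The enrichment tail is implemented as printed
in the screening literature, P(K > k); the conventional P(K ≥ k) sits behind
`enrichment_tail="ge"`. Validation utilities for cell-line work are included:
a one-sided Welch t-test comparing drug sensitivity between mutant and
wild-type cell-line groups (direction set by whether the readout increases or
decreases with sensitivity), and the relative-growth ratio
treated/placebo.

## Numerical choices

- Iterative solver: tolerance 1e−9 on the max-abs update, cap 10,000
  iterations; the closed form is the default (problem sizes here are ≲10⁴).
  (I − αL) is always invertible for α < 1 because ρ(L) ≤ 1.
- One LU factorization per α is shared across all shuffle×fold label vectors,
  which makes the full 100-point grid cheap (seconds at n ≈ 500).
- Zero-degree points receive f* = (1−α)y_i, forced by the update rule.
- D(G) is computed once on the reference network and reused as the
  unreachable penalty when evaluating E(G′); recomputing it per deleted graph
  (`recompute_diameter=True`) is exposed but non-default, because deletion
  can disconnect the graph and destabilize the penalty base.
- Diameter of a disconnected graph is the max over components, keeping the
  penalty finite.
- A known worked example in the literature for the NDCG formula above prints
  Z = 0.4331 and NDCG@5 = 0.4907 for positives at ranks 2, 3, 8; direct
  evaluation of the formula gives Z ≈ 0.4693 and NDCG@5 ≈ 0.5307. This
  implementation follows the formula, not the printed example.

## The synthetic cohort generator

No real cohort ships with the package; `slranker.synthdata` emulates the
input structure end to end so every stage is testable.

- **Background mutations**: per-gene rates are a two-tier mixture — most
  genes U(0.005, 0.05), a `frequent_gene_fraction` (default 15%) at
  U(0.05, 0.30) — mimicking the long-tailed rate spectrum of real cohorts.
  (A flat rare rate would leave the chi-square screen with nothing: at 4/200
  mutated samples the Yates-corrected test never reaches p ≤ 0.05.)
- **Planted SL pairs** mutate through a shared per-sample event: with
  probability ε (default 0.9) exactly one member (uniform choice), otherwise
  both. Empirical exclusivity then concentrates at ε with analytic control of
  M/N/X, and the co-mutation count falls well below the independence
  expectation. The per-gene marginal rate defaults to 0.40 — the territory
  of highly recurrent drivers (TP53-like) — because mutual exclusivity at
  ε = 0.9 is only detectable by a cohort-scale chi-square test when both
  genes are frequently mutated; at rates ≤ 0.05 the test has essentially no
  power regardless of ε.
- **Driver signal**: planted genes shift each network neighbor's expression
  by `driver_effect_size` SD (default 4) in a mutated sample with probability
  `driver_penetrance` (default 0.25). Partial penetrance is essential, not
  cosmetic: a shift applied in *all* mutated samples of a gene with rate r
  inflates the neighbor's SD until shifted samples max out at
  z = √((1−r)/r) < 2 for r > 0.2, i.e. a frequent driver's effect would be
  invisible to a z-score outlier rule. It is also the more realistic model —
  not every mutated tumor dysregulates every interaction partner.
- **Network**: preferential-attachment graph over half the gene universe
  (connected by construction), with biomarkers covering 80% of its nodes so
  the biomarker filter genuinely prunes edges.

What the generator does **not** emulate: mutational signatures, copy-number
events, subclonality, expression covariance between genes, batch effects, and
biological pathway structure in the network. Passing tests therefore
demonstrate that the pipeline recovers the statistical structure it screens
for — exclusive mutation, mutation-linked expression outliers, network
centrality — not that it recovers true SL pairs in real tumors.

## Problem sizes

Defaults were chosen so a full run stays interactive on one core: 200
samples × 300 genes, 10 planted pairs, ~25k raw pairs, ~300–400 screened
candidates, 100-point α grid with 50 CV evaluations each. A full pipeline run
takes ~20 s.

## Known limitations

- The built-in driver scorer is a deliberately simple stand-in for dedicated
  driver-discovery tools; use `driver_pvalue_file` to substitute real output.
- The screening chi-square is two-sided: a strongly *co-occurring* pair also
  passes the p-threshold, and is excluded only by the exclusivity filter.
- With few positives (e.g. 10), per-fold NDCG@2 is coarse (0, ~0.39, ~0.63,
  or 1), so mean NDCG across folds has high variance between cohorts even
  when top-10% recovery is stable.
- Gene symbols are matched case-sensitively with no alias resolution;
  binarize mutation calls and resolve identifiers upstream.
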