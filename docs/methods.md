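# Methods

This note defines every quantity the package computes, the default
parameters, and the modeling choices behind them.

## 1. Objects

A **protein** carries a binary annotation vector *P* ∈ {0,1}^D (D
functional terms), an amino-acid sequence over the 20 standard
residues, a secondary-structure string over {H, E, C}, and a
solvent-accessibility string over {H (buried), E (exposed)} of the same
length as the sequence.

A **pathway candidate** is a directed graph G = (V, E): vertices are
protein ids, arcs are ordered pairs (duplicates collapsed; self-loops
are representable, though the generators never produce them). Datasets
require |V| ≥ 3. Every arc (i, j) is weighted by the **annotation
likelihood**

  w(i, j) = Pi · Pj / (‖Pi‖ ‖Pj‖) ∈ [0, 1],

with w = 0 when either vector is all-zero. Weighting is symmetric, but
arcs remain directed.

## 2. Graph features (88, groups 1–9)

All statistics over empty sets are 0; "variance" is always the
population variance.

1. **Size & density (2):** |V| and |E| / |V|².
2. **Degree statistics (8):** mean, variance, median, max of the in-
   and out-degree distributions. The median of an even-length list is
   the mean of the two middle order statistics.
3. **Edge-weight statistics (4):** mean and variance over all arc
   weights, and over the strictly positive arc weights.
4. **Topological change (7):** with E_i = {arcs with w > i/10}
   (strict), T_i = (|E_i| − |E_{i+1}|) / |E_i| for i = 1..7, and 0 when
   E_i is empty.
5. **Degree correlation (6):** per vertex, D′ = |E′| / k where the k
   in- (resp. out-) neighbors induce E′ arcs of G; mean, variance, max
   per side. Vertices with k = 0 contribute 0.
6. **Clustering (6):** as group 5 with C′ = |E′| / k².
7. **Shared-neighbor topology (12):** for each ordered vertex pair
   (i, j), i ≠ j, the overlap |N_a(i) ∩ N_b(j)| / |N_a(i)| for the four
   (a, b) ∈ {in, out}² combinations (0 when |N_a(i)| = 0); averaged
   over j for each i, then mean/variance/max over i. Defined only for
   |V| ≥ 2 (all-zero otherwise).
8. **Singular values (3):** the three largest singular values of the
   0/1 adjacency matrix, zero-padded below rank 3.
9. **Local density change (40):** per vertex, its k in- (or out-)
   neighbors form a complete similarity graph; for cutoffs
   w = 0.0, 0.1, …, 0.9, L′(w) = 2 · |{pairs with similarity > w}| /
   (k(k−1)), 0 when k ≤ 1. Mean and max over vertices, per side and
   cutoff.

## 3. Biological features (264, groups 10–13)

Each protein gets **132 raw descriptors**:

- **Physicochemical CTD (4 × 21):** the sequence is rewritten over a
  three-class alphabet {P, N, H} for hydrophobicity, normalized van
  der Waals volume, polarity, and polarizability (default residue
  groupings shipped with the package; overridable via YAML,
  `load_alphabets`). For a class string of length L:
  - *Composition:* 100 · count(c) / L per class.
  - *Transition:* per unordered class pair, 100 · (adjacent positions
    forming the pair, either order) / (L − 1); 0 when L = 1.
  - *Distribution:* for a class with m > 0 occurrences, the 1-based
    position of the ⌈q·m⌉-th occurrence × 100 / L, for the first
    occurrence and q = 0.25, 0.5, 0.75, 1.0 (five values; all 0 when
    m = 0).
  Worked example: "PNHPN" gives composition (40, 40, 20), transitions
  (PN, PH, NH) = (50, 25, 25), distribution for P =
  (20, 20, 20, 80, 80).
- **Solvent accessibility CTD (7):** two-class strings report only the
  first class's composition and distribution plus the single
  transition (1 + 1 + 5).
- **Secondary structure CTD (21):** three classes H/E/C, as above.
- **Amino-acid composition (20):** 100 · count(aa) / L.

Descriptors are **z-score standardized** per column over all proteins
appearing anywhere in the dataset being featurized (population σ;
constant columns map to 0). Graph features are used raw. Each pathway
then takes, per descriptor, the **mean and max** over its member
proteins — 264 values, interleaved (mean, max). Total: 88 + 264 =
**352 features**; the registry (`build_registry`) fixes names and
group ids.

## 4. Feature selection

Features are discretized into three bins at μ ± σ (per column, over
all samples): below μ − σ → −1, above μ + σ → +1, else 0. Mutual
information is the plug-in estimate in nats. **MaxRel** sorts by
relevance I(f, h) with h the class label; the reported top slice is the
first ⌊0.10 · N⌋ = 35 features. **mRMR** selects greedily: round 1
takes the max-relevance feature; round t maximizes
I(f, h) − (1/|S|) Σ_{s∈S} I(f, s) over the remaining features
(quotient form available via `criterion="quotient"`). Ties break to
the lower feature index; all N rounds run, yielding a full ordering.

## 5. Classification and evaluation

The classifier is 1-nearest-neighbor with cosine distance
1 − x·y/(‖x‖‖y‖) (distance 1 to an all-zero vector; Euclidean metric
available). Ties break to the lowest sample index. Evaluation is the
**jackknife** (leave-one-out): each sample is predicted from all the
others; we report positive-class, negative-class, and total accuracy.
**Incremental feature selection (IFS)** jackknifes every prefix of the
mRMR ordering up to `max_prefix`; the **optimal** feature set is the
smallest prefix maximizing positive-class accuracy.

Datasets are assembled **negatives first**. With cosine distance on
low-dimensional nonnegative prefixes, large blocks of samples can tie
at distance 0; under the lowest-index tie rule such degenerate prefixes
then predict the majority (negative) class rather than spuriously
achieving perfect positive accuracy, so a degenerate 1-feature prefix
cannot masquerade as the optimum.

## 6. Synthetic benchmark

The generator is a study condition: its defaults are frozen and are
not tuned to any particular outcome.

**Universe** (`UniverseConfig`, seeded via `SeedSequence([seed, k])`):
`n_proteins=300` proteins with i.i.d. Bernoulli(`annotation_density=0.01`)
annotations over `annotation_dim=500` terms (≈ 5 hits per protein),
uniform random sequences of length 50–150, and uniform ss/acc strings.

*Why sparse annotations:* with dense i.i.d. annotations the pairwise
cosine similarities concentrate around their mean with spread
O(1/√D), so no plausible exponential tilt can distinguish "related"
from "unrelated" proteins. With ~5 hits per protein the similarity of
a random pair is usually 0 and occasionally large, giving the bias
something to act on.

**Positive pathways** (`n_positive=169`, sizes uniform in
`pathway_size_range=(5, 25)`): membership is grown greedily — a uniform
seed protein, then each subsequent member drawn with probability ∝
exp(β · a_i), where a_i is the **maximum** similarity of candidate i to
the current members and β = `similarity_bias` (default 2.0). The max
(not mean) keeps the clustering pressure from diluting as the pathway
grows. Arcs: m = round(`arcs_per_vertex=2.0` · n), clipped to
[n − 1, n(n−1)], sampled without replacement over ordered pairs with
probability ∝ exp(β · similarity); no self-loops.

**Negatives** (`generate_negatives`, default ratio 100:1, split evenly;
odd remainder to route 1):

- *Route 1 (random):* draw a (|V|, |E|) template jointly from the
  positives' empirical size distribution, pick vertices uniformly
  without replacement, arcs uniformly over ordered pairs.
- *Route 2 (half-substitution):* pick a positive, replace ⌈n/2⌉ of its
  vertex positions with distinct outside proteins, keep every arc as a
  position-indexed pair (`source_id` records the template).

Candidates colliding with a positive or an earlier negative under the
canonical form (sorted vertex set + sorted arc set) are regenerated,
up to 100 attempts.

**Signal recovery.** The package's end-to-end validity check compares
β = 5 against β = 0 (all else equal) over paired seeds: the IFS-optimal
positive-class accuracy under bias must exceed the null
(one-sided paired t-test; `scripts/acceptance.py` reports the means
and p-value). Representative run (10 seeds, 50 positives, ratio 10):
biased ≈ 0.41 vs null ≈ 0.17, p ≈ 5 × 10⁻⁵.

## 7. Numerical conventions

- All randomness flows from `numpy.random.Generator` seeded by
  explicit `SeedSequence` spawns; equal configs reproduce byte-identical
  artifacts.
- Population (not sample) variance/σ everywhere.
- Empty-set statistics are 0; 0/0-style ratios are defined as 0
  (topological change, degree correlation, clustering, overlaps,
  local density).
- Mutual information uses natural logarithms and the plug-in estimator
  with 0 · log 0 = 0.
- Feature matrices must be finite; `ConfigurationError` is raised on
  NaN/inf, dimension mismatches, and invalid configurations.

## 8. What the generator does not model

The synthetic universe is a controlled testbed, not a biological
simulation: annotations are independent Bernoulli draws (no ontology
structure or term correlations), sequences/structures are uniform
noise uncorrelated with the annotations (so the biological feature
groups carry no planted signal — any selection of them under the null
reflects chance), and pathway topology beyond the similarity tilt is
unstructured (no motifs, hubs, or modularity). Consequently absolute
accuracies on synthetic data are not comparable to accuracies on real
pathway collections; only contrasts between generator conditions are
meaningful.
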