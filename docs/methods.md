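# Methods

## The exclusivity screen

The screen treats each sample×gene mutation status as binary (1 = mutated;
calls of any variant class count, and fusions are recorded under the 5'
partner symbol, so e.g. CBFB-MYH11 pools into the CBFB column). A gene
enters the candidate set when its cohort mutation rate is strictly greater
than `min_rate` (default 0.04). The strictness follows the "higher than"
reading of the threshold; a gene mutated in exactly 4% of samples is
dropped. Anchor-panel genes (IDH1, IDH2, TET1, TET2, TET3, DNMT1, DNMT3A,
DNMT3B, DNMT3L) are exempt from the rate filter, since the screen is only
meaningful when the anchors are present. The rate filter is applied on the
full cohort, including samples with no mutation call (which is why
`binarize` accepts a cohort list and emits all-zero rows: wild-type samples
carry the `d` cell of every table).

The pair universe is candidate×anchor plus all anchor×anchor pairs, not
all-vs-all: the question is which genes track the de/methylation pathway,
and the anchor families' internal exclusivity (IDH1–IDH2, IDH2–TET2) is a
positive control worth reporting.

### Fisher exact test

Conditional on the table margins, the both-mutated count follows a
hypergeometric distribution. The two-sided p-value is the sum of the
probabilities of all support points whose probability does not exceed the
observed one — the conventional two-sided definition, chosen because the
same screen reports both exclusivity and co-occurrence and reads the
direction off the odds ratio. Probabilities are evaluated in log-space via
`gammaln` and summed after subtracting the maximum, so tables as large as
whole-cohort AML sizes are exact to floating-point precision. Two
numerical choices matter:

* ties: a support point is included when its log-probability is within
  `log1p(1e-7)` of the observed one, so exactly tied tables (which arise
  whenever the margins are symmetric) are never lost to rounding;
* margin order is canonicalized (the smaller margin indexes the support),
  which makes the computation exactly invariant under table transposition
  rather than invariant only to ~1e-16.

Degenerate margins (a gene mutated in no or in all samples) give p = 1 by
convention, with a log note: no table with those margins can show
association.

### Odds ratio

OR = ad/bc. With any zero cell the Haldane–Anscombe correction adds 0.5 to
all four cells (default), keeping the OR finite so the OR < 0.5 exclusivity
cutoff stays well-defined for rare genes; `correction="none"` returns the
raw ratio with ±inf/0 at zero denominators for meta-analysis reporting.

### Calls and multiplicity

A pair is called exclusive when OR < 0.5 *and* p ≤ `p_max` (default 0.05),
co-occurring when OR > 2 and p ≤ `p_max`. The significance gate is a
deliberate addition: with a rare candidate, OR < 0.5 happens by sparsity
alone, and gating on p removes those. Setting `p_max: 1` recovers a pure
OR screen. Benjamini–Hochberg q-values are computed once over all tested
pairs per run (`statsmodels.multipletests`); with `fdr_method: none`,
q = p. Output is sorted by p, ties broken lexicographically, so runs are
byte-reproducible.

## Methylation signatures

β-values are methylated-fractions in [0,1]. Probe selection keeps CpGs
whose across-sample SD (n−1 denominator) strictly exceeds `sd_min`
(default 0.27), or the top-n by SD with ties broken by probe id; probes
with any missing value are dropped before ranking rather than imputed —
determinism beats a marginal gain in probe count at desk scale. Both
cutoff styles are exposed because an SD threshold tuned on one cohort has
no guarantee of yielding a comparable probe count on another.

Samples are clustered agglomeratively (scipy linkage) on the selected
probes; default Euclidean distance with complete linkage, with
1−Pearson and average/Ward as options (Ward restricted to Euclidean,
where it is defined). The dendrogram is serialized as Newick and cut with
`fcluster` into k clusters.

Group comparison takes the per-sample mean β over selected probes, runs
one-way ANOVA across all groups with ≥2 samples, then tests each group
against the stated control with a pooled-variance two-sample t-test
multiplied by the number of pairwise tests (Dunn–Bonferroni). A group is
called hypo-(hyper-)methylated when its mean is below (above) the control
mean with adjusted p ≤ 0.05. Zero within-group variance is degenerate for
both F and t: p is set to 1 when the means are equal and 0 otherwise, and
logged. The control group is explicit user input, never inferred.

## DE thresholding and overlaps

`threshold_de` splits a DE table at |log2FC| ≥ 0.585 — log2(1.5) to the
printed precision — with the boundary inclusive, matching the "at least
1.5-fold" reading; the cutoff and an optional q ≤ 0.05 gate are
configurable. The DE model itself is consumed, not computed; only the
simulator runs a per-gene test, to fabricate realistic tables.

Overlap significance is the upper-tail hypergeometric probability
P[X ≥ k] for an overlap of k between sets of sizes |A| and |B| drawn from
a universe, computed with the same log-space machinery as the Fisher test
(set-size order canonicalized for exact symmetry). The universe is
user-supplied, defaulting to the union of contributing tables, and every
output restates it: the percentages (overlap as % of each set) are
universe-free, the p-value is not, so the p should only be compared across
analyses with the same universe. Venn region counts are computed by direct
set algebra for 2–3 sets.

## Synthetic data

The simulators define the test conditions; they emulate structure, not
biology.

* **Mutations.** Background genes mutate independently with per-gene rates
  drawn uniformly from a configured range (default 5–20%, cohort default
  n = 1000 — the mid-range of the per-cancer-type cohorts such screens run
  on). A planted pair with margins (p_A, p_B) and target odds ratio ψ is
  sampled from the unique joint Bernoulli law with those margins: the
  (1,1)-cell probability solves
  (1−ψ)p₁₁² + [1+(ψ−1)(p_A+p_B)]p₁₁ − ψ p_A p_B = 0,
  taking the root inside the Fréchet bounds. For interior margins every
  ψ > 0 is feasible (the OR sweeps 0→∞ as p₁₁ crosses the bounds); the
  infeasibility guard only trips on numerically degenerate input. Planted
  and background truth labels are returned for harnesses.
* **β matrices.** Per-CpG baseline β comes from a two-component Beta
  mixture (defaults Beta(2,8) / Beta(8,2), half weight each) reproducing
  the bimodal marginal of array data. Group shifts δ are applied on the
  logit scale to a signature block (defaults: 10% of CpGs, δ = −1.0 for
  the mutant group — a shift of the size a DNMT3A-like lesion produces on
  its signature probes), plus logit-normal noise (σ = 0.3) and back through
  the logistic, so values stay in (0,1). Logit-normal rather than
  Beta-distributed noise keeps shifts additive and invertible (the
  M-value/β-value duality). What this does **not** model: probe-type
  chemistry effects, batch structure, cell-composition mixtures, spatial
  correlation along the genome — so passing tests show the statistics
  behave, not that array preprocessing is unnecessary.
* **DE tables.** Per-gene two-condition normal expression on the log2
  scale (null SD 0.5, 5 vs 5 replicates, planted effects ±2), Welch-tested
  with BH q. Real RNA-seq mean–variance structure is not modeled; the
  tables exist to exercise thresholding and overlap, not the DE model.

Every generator is deterministic given its seed (numpy `default_rng`).

## Problem sizes

Simulation-based checks use 100–200 replicates at n = 500–1000 samples,
3,000-CpG β matrices, and 1,000-gene DE tables — sizes at which the
planted effects are comfortably identifiable and the whole suite runs in
seconds, chosen as the package's own desk-scale test conditions.

## Known limitations

* The screen is marginal and pairwise: no permutation or coverage-weighted
  model (DISCOVER/MEGSA-style), no pathway-level grouping.
* The published pan-cancer pair list, the 8,030-probe TCGA set and the
  445/598/673/58 DE counts depend on cBioPortal/TCGA/GEO downloads and are
  out of scope; the simulators replace them with planted ground truth.
* Hypergeometric overlap p-values inherit the arbitrariness of the
  universe; report the percentages alongside.
* The mutation-matrix polarity is 1 = mutated throughout.
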