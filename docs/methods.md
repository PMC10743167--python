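# Methods

## Problem and pipeline

Extracellular vesicles (EVs) transfer miRNAs between cells; a miRNA whose
abundance shifts in a phenotype-altering EV population is a candidate
upstream regulator of that phenotype. Because a single miRNA represses
hundreds of genes, the analytic problem is one of *focusing*: from the union
of all predicted targets of the shifted miRNAs, find the few genes most
likely to matter. `evhub` does this with two complementary branches — an
interaction-network hub ranking over all targets (GD, "global data") and a
curated-keyword bipartite network that privileges immune/inflammation
biology (SK, "specific keyword") — and merges their nominations into one
report per comparison.

## Differential miRNA statistics

Input is a miRNA × sample count matrix with a two-group labelling (A =
reference, B = test). Counts are normalized to counts-per-million (CPM) per
sample; the per-miRNA statistic is

    log2FC = log2((mean CPM_B + c) / (mean CPM_A + c)),   c = 0.5 (pseudocount)

with a two-tailed Welch t test on log2(CPM + c) for the p-value. The
upstream sequencing vendors that usually produce such tables keep their
pipelines proprietary, so the module both computes its own defensible
statistic and accepts externally computed (log2fc, p) tables unchanged.
Choices that matter:

- **Pseudocount c = 0.5** stabilizes the log at low counts; it biases
  |log2FC| toward 0 by at most ~1% at CPM ≥ 50.
- **Welch rather than pooled t** because group variances on the log scale
  are not assumed equal; the pooled variant exists in the assay module where
  a classical Student test is wanted.
- **No multiple-testing correction by default**: the volcano filter operates
  on raw p < 0.05 (the convention in the screens this pipeline serves);
  Benjamini–Hochberg is available via `classify(..., adjust=True)`.
- **CPM cancels uniform between-group scaling.** Data already depth-
  normalized upstream can use `compute_stats(..., normalize=False)`, where a
  uniform 8× shift yields log2FC = 3 exactly.
- Groups with a single sample get log2FC but a missing p (classified `ns`).

The volcano rule is strict (`>`): log2FC must exceed log2(2) = 1 exactly to
call `up`. Top-k selection is per direction (descending |log2FC|, k = 4, "up
to" semantics when fewer qualify), with lexicographic miRNA-id tie-breaks so
the output is order-deterministic. Ranking by |FC| within each direction —
rather than signed FC across both — matches the symmetric 4-up/4-down design
of the bundled reference screen.

## Target mapping

TargetScan-style tables are reduced to (miRNA, gene, CWCS) records; CWCS is
the cumulative weighted context++ score, a log2 repression estimate, so
CWCS ≤ −0.4 corresponds to 1 − 2^(−0.4) ≈ 24% predicted knockdown.
Duplicate (miRNA, gene) rows collapse to the most negative score. The
threshold is **inclusive** (≤ −0.4) by default — the operative convention in
the reference screen's bookkeeping — with `inclusive=False` for the strict
variant. Gene identity is a case-sensitive symbol match after whitespace
trimming; alias resolution is out of scope.

Per comparison, the selected miRNAs' target sets are unioned within each
direction group. The *comparison total* is deliberately
|up union| + |down union|, not the union across directions: the two
direction groups are biologically distinct (they predict opposite gene
regulation), and this is also how group subtotals are tallied in the screens
the package reproduces (301 + 104 = 405, 275 + 394 = 669, grand total 1074
on the bundled sizes with disjoint sets).

## GD branch: Maximal Clique Centrality

The interaction graph is a simple undirected graph from a STRING-style edge
list; edges below a combined score of 400 (medium confidence, 0–1000 scale)
are dropped by default — the cutoff is exposed because published analyses
rarely state it. Hub score:

    MCC(v) = Σ over maximal cliques C containing v of (|C| − 1)!

computed from Bron–Kerbosch-with-pivoting clique enumeration
(`networkx.find_cliques`); only cliques of size ≥ 2 contribute, so isolated
nodes score 0. On triangle-free graphs MCC equals degree; the factorial
weighting otherwise makes large-clique membership dominate. The test suite
verifies MCC against an independent brute-force subset-enumeration oracle on
hundreds of random graphs of ≤ 12 nodes.

Ranking is MCC-descending with degree then gene id as tie-breaks; a top-k
window (default 30) and a short candidate list (default 5) are cut by the
same ordering. Degree as tie-break encodes "prefer the better-connected
gene" where MCC cannot discriminate.

## SK branch: keyword–gene bipartite network

The default lexicon holds 18 canonical keywords in three categories (immune
responses, immune cells, inflammation signaling). Matching is:

- case-insensitive; hyphens, en/em dashes and slashes normalize to spaces,
  so "T-cell" ≡ "T cell" and "JAK/Stat" ≡ "JAK-STAT";
- token-boundary: a keyword's tokens must appear as a contiguous token
  sequence, so "CD3" never fires inside "CD34";
- variant-aware: each canonical keyword carries synonym spellings
  (e.g. NF-kappaB ⇢ NF-kB, NF-κB, "nuclear factor kappa B"), user-overridable
  via a YAML lexicon; a keyword counts at most once per gene.

Plain substring matching was rejected because it corrupts degrees (the
CD3/CD34 collision). Every (matched keyword, gene) pair is an edge of a
bipartite network; a gene's bipartite degree is its selection statistic, and
the default threshold is degree ≥ 4 (≥ rather than =, so richer annotations
can only strengthen a call).

## Integration

Branch outputs are merged per comparison with per-gene deduplication (both
provenance tags kept). Each candidate gets a regulating miRNA: among the
selected miRNAs that target it, the most negative CWCS wins, then
lexicographic miRNA id — repression strength is the only principled
discriminator the data offers. The inferred gene regulation is the opposite
of the miRNA's direction (miRNAs repress); a gene targeted by no selected
miRNA is reported with an explicit unassigned state, never dropped
silently. Reports serialize losslessly to JSON and human-readable TSV.

## Assay formulas and statistics

- **LDH cytotoxicity (%)** = 100·(OD_test − OD_low)/(OD_high − OD_low) at
  490 nm; requires OD_high > OD_low; values outside [0, 100] are returned
  with a warning (biological over/undershoot is information). The formula is
  affine-invariant in the three ODs.
- **Phagocytic activity (%)** = 100·(bead-positive cells)/(total cells).
- **Invasion estimate** = (Σ sampled-area counts)/fraction_sampled, rounded;
  the sampled membrane fraction is a required user parameter because it is a
  property of the imaging setup.
- **Smirnoff–Grubbs outlier test**: G = (x_max − x̄)/s (side="max", the
  default one-tailed form), compared to
  ((n−1)/√n)·√(t²/(n−2+t²)) with t the Student quantile at tail probability
  α/n, df = n−2. `side="min"` mirrors it; `side="both"` tests max|x−x̄|/s at
  α/(2n). Each variant rejects a true null with probability α — the
  directional default at α/n, the two-sided search at α/(2n); pairing the
  two-direction search statistic with the one-sided critical value would
  double the realized size, which is why the directional statistic is the
  default rather than |·|. At most one point is flagged per pass; iterative
  removal (for masked multiple outliers) is off by default.
- **Two-tailed t test**: classical pooled-variance Student test by default
  (`equal_variance=False` for Welch); two zero-variance groups yield p = 1
  (equal means) or 0 by convention.

## Synthetic data: what it emulates and what it does not

- **Counts**: negative binomial with variance m + φm² (dispersion φ > 0),
  per-miRNA baseline means log-normal (sdlog 1.0) around `baseline_mean`,
  group B means scaled by 2^(planted log2FC). Defaults — 500 miRNAs, 3
  samples per group, φ = 0.1, baseline mean 200 — mirror a typical EV
  small-RNA library: a few hundred detected miRNAs, triplicate designs,
  moderate overdispersion. The generator does not simulate reads, mapping
  artefacts, compositional effects of a few dominant miRNAs, or
  sample-quality covariates; calibration results on it bound, but do not
  guarantee, behaviour on real libraries.
- **Target tables**: exact per-miRNA set sizes; `disjoint` mode (unions
  exactly additive — the regime in which published per-group sums hold) or
  `random` mode with collision probability p per link. CWCS uniform in a
  configurable interval, default (−1.2, −0.4].
- **Interaction graphs**: Erdős–Rényi background plus complete cliques on
  fresh nodes with a reserved `PC` label prefix, so tests can identify
  planted hubs without the labels leaking into any score. Planted cliques
  are not wired into the background; recovery statements therefore compare
  clique members against pure background nodes.
- **Annotations**: planned keywords (random variant spellings) embedded in
  filler prose drawn from a fixed vocabulary that shares no token with any
  lexicon variant, so filler can never create a match; the generator
  self-checks each planned text against the matcher and fails loudly on any
  discrepancy. Decoy genes get at most a stated number of keywords
  (default 0).

Every generator is a pure function of (spec, seed): same seed, byte-identical
output.

## Numerical and degenerate-input conventions

- Missing p-values (single-sample groups) never classify as significant.
- Zero library size, non-positive dispersion/means, probability parameters
  outside [0, 1], planted effects for unknown miRNAs, clique sizes < 2 and
  synonym entries for unknown keywords all raise validation errors.
- Constant series: Grubbs flags nothing (zero SD); the t test returns the
  degenerate conventions above.
- Clique enumeration is guarded by a configurable 5000-node ceiling because
  Bron–Kerbosch is exponential in the worst case.
- All orderings (top-k, hub ranking, degree selection) carry deterministic
  lexicographic tie-breaks, so outputs are permutation-invariant to input
  order.

## Problem sizes used in the test and acceptance runs

The suite checks MCC against brute force on 200 random graphs of ≤ 12 nodes
(subset enumeration is exact and fast at that size); differential-filter
calibration on 10 × 500 null miRNAs and recovery on 200 replicates at 10
samples per group, dispersion 0.1; and Grubbs null calibration on 10,000
replicates at n = 7. These sizes give Monte-Carlo error comfortably inside
the asserted tolerances while keeping the whole suite in seconds.

## Known limitations

- The DE statistic is a deliberately simple, documented stand-in for
  whatever pipeline produced a user's table; for real count data a
  dedicated RNA-seq model (negative-binomial GLM with shrinkage) is
  preferable, and precomputed tables can be slotted in directly.
- Gene symbols are matched literally; no alias/ortholog resolution.
- The keyword matcher is token matching, not NLP: negations ("no immune
  involvement") still match.
- The comparison total counts each direction group separately; the
  deduplicated cross-direction union is available from the per-group sets
  when wanted.
- Live STRING/TargetScan/annotation services are never queried; only their
  file dialects are supported.
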