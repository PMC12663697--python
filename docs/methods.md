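# Methods

This note documents the models and procedures panfam implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Iterative pan-family construction

The builder partitions a multi-accession set of family CDSs into
orthologous gene groups (OGGs) by iterative assignment against a growing
reference set:

1. Every gene of the seed accession opens one OGG with itself as reference.
2. Each remaining gene is scored against all references; it joins the best
   reference meeting **both** thresholds (identity ≥ 90 %, coverage ≥ 90 %),
   with ties broken by higher identity, then higher coverage, then the
   lexicographically smallest OGG id.
3. If genes remain unassigned, the next accession (iteration order: seed
   first, then sorted accession ids — configurable) that still holds
   unassigned genes contributes a new reference: its unassigned gene with
   the most above-threshold neighbours among *all* unassigned genes (a
   greedy centroid; ties go to the longest CDS, then the smallest gene id).
4. Steps 2–3 repeat until every gene is assigned. Each round either assigns
   or promotes at least one gene, so termination is guaranteed, and the
   result is a partition: members are disjoint and exhaustive.

Because references only accumulate, the implementation caches each
candidate's best passing hit and scores only newly elected references per
round; this is observationally identical to re-scanning everything each
round (checked against a brute-force re-scan in the tests).

**Alignment scoring.** An external BLAST-style search is replaced by an
in-process pairwise global alignment with free end gaps (match +1, mismatch
−1, gap open −2, gap extend −0.5). Identity is the fraction of identical
A/C/G/T columns over all columns between the first and last aligned pair
(terminal overhangs excluded, internal gaps counted); coverage is the
number of aligned residue pairs over each sequence's length, and both
sequences must reach the coverage threshold — requiring only one side would
let short fragments seed oversized groups. Any column involving an N
counts as a mismatch. At the simulated divergences (within-group ≈ 97 %
identity, between-group ≤ 80 %) the 90/90 decision is far from the
sensitivity of the scoring scheme, so the exact parameter choice is not
load-bearing.

## Pan-category bands

With N accessions and occupancy o (number of accessions carrying ≥ 1
member): core o = N; softcore ⌈0.9 N⌉ ≤ o ≤ N−1; shell ⌊0.1 N⌋+1 ≤ o <
⌈0.9 N⌉; cloud 2 ≤ o ≤ ⌊0.1 N⌋. The ceil/floor convention is the one that
yields the familiar 100–110 / 12–99 / 2–11 cutpoints at N = 111.
Bands are implemented with integer arithmetic (⌈0.9 N⌉ = (9N+9)//10) so no
floating-point edge cases exist, and they are disjoint and exhaustive for
every N ≥ 2 (property-tested to N = 500). Occupancy-1 groups get an
explicit **private** label rather than being silently forced into cloud
(whose band starts at 2); roll-ups count private with the dispensable
categories. A single-accession dataset degenerates to "everything core"
(o = N = 1), which the classifier honours by checking the core rule first.

## Codon-usage metrics

All metrics operate on sense-codon counts of in-frame CDSs: the terminal
stop codon is excluded, an internal stop is an error, and codons containing
N are skipped (and tallied) rather than guessed.

* **RSCU**: for an amino acid with k synonyms used t times in total,
  RSCU(c) = k·count(c)/t; within each amino acid the defined values average
  to exactly 1. Unused amino acids yield missing values, not zeros.
* **CAI** (Sharp & Li): weights w(c) = pooled reference count(c) / max
  count among its synonyms, so every amino acid's optimal codon has w = 1;
  reference codons with zero counts are floored at 0.5/max to avoid
  log-zero (the floor is logged). CAI is the geometric mean of w over the
  gene's codons, excluding Met, Trp and stops, which carry no usage signal.
  The reference set is a user input; the pipeline defaults to pooling all
  input genes, standing in for a highly-expressed genome-wide reference
  when no expression data accompanies the sequences.
* **ENC** (Wright): per amino acid with n ≥ 2 counted codons,
  F̂ = (n·Σp̂²−1)/(n−1); class averages F̄ₖ over the 2-, 3-, 4- and 6-fold
  classes of the standard code (Ile the sole 3-fold; Leu/Ser/Arg 6-fold)
  give ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clipped at 61. A missing
  3-fold class is substituted by (F̄₂+F̄₄)/2 and a missing 6-fold class by
  F̄₄ (Wright's fallbacks). If the 2- or 4-fold class itself is absent, or
  any class average is non-positive, ENC is reported missing rather than
  extrapolated — genes using only 2-fold amino acids therefore have no ENC.
* **GC/GC1/GC2/GC3**: G+C percentages per codon position over the counted
  codons; total GC is the mean of the three positions, so the identity
  gc = (gc1+gc2+gc3)/3 holds exactly on N-free sequences.

**Group comparisons.** A single Wilcoxon rank-sum implementation serves
both the codon and the selection module. When both groups have ≤ 12
observations the null distribution of the midrank sum is enumerated over
all C(n₁+n₂, n₁) splits and p = min(1, 2·min(P(W≤w), P(W≥w))) — exact even
under heavy ties; larger groups use the tie-corrected normal approximation.
Raw p-values (with the conventional `*` ≤ 0.05 / `**` ≤ 0.01 stars) and
Benjamini–Hochberg-adjusted values are both reported.

## NG86 Ka/Ks

Codon alignments are built ParaAT-style: translate, globally align the
proteins (BLOSUM62, gap open −10, extend −1), back-translate so gaps fall
on codon boundaries. NG86 counting then proceeds over gap-free codon
columns (columns with N-containing codons are excluded):

* Sites: per codon position, the synonymous fraction among non-stop
  single-nucleotide changes; s summed over positions, n = 3 − s, averaged
  over the two sequences. S + N = 3 × compared columns always holds.
* Substitutions: codons differing at one position contribute directly; two-
  and three-fold differences average the synonymous/nonsynonymous step
  counts over all orderings of the changes, excluding pathways that pass
  through a stop codon and re-weighting the remainder equally. Columns
  whose every pathway is blocked are dropped entirely (from sites too).
* Rates: Jukes–Cantor, K = −¾·ln(1 − 4p/3). p ≥ ¾ (saturation) or an empty
  site class yields a missing rate; ω = Ka/Ks is defined only when both
  rates are and Ks > 0. Missing estimates are excluded from means and
  counted, never imputed — silently imputing zeros or caps would bias the
  category and population contrasts the pipeline reports.
* Significance: a two-sided Fisher exact test on [[Sd, S−Sd], [Nd, N−Nd]]
  with fractional counts rounded half away from zero. NG86 was chosen as
  the estimator because it is the canonical approximate counting method,
  fully specifiable, and verifiable against a brute-force pathway-
  enumeration oracle (the tests hold both to 1e-9 agreement); maximum-
  likelihood estimators (GY94-style) are out of scope.

Within an OGG all unordered member pairs are estimated, subsampled
uniformly with a seed when they exceed `max_pairs` (default 200 — an OGG
spanning 111 accessions yields > 6,000 pairs). Following the convention of
selection scans that report only significant estimates, per-OGG means are
taken after discarding pairs with Fisher p ≥ 0.01; the filter is
configurable (`p_filter=None` keeps everything) because at shallow
divergence it can discard most pairs, and parameter-recovery checks of the
estimator itself are run unfiltered.

## Family assignment

Domain counts (from an upstream HMM/CDD scan, supplied as a table) map to
families as: ≥ 2 AP2 domains → AP2; 1 AP2 + ≥ 1 B3 → RAV; 1 AP2 alone →
ERF-like; 0 AP2 → unclassified (excluded from downstream group tables).
ERF, DREB and Soloist cannot be separated by domain counts; they stay
"ERF-like" unless a labelled reference panel is supplied, in which case a
gene takes the group of its best-identity panel sequence passing the
builder's 90/90 thresholds. This nearest-labelled-reference rule replaces
tree-based subfamily classification, which requires external phylogenetic
tooling and is not deterministic at the level this package tests.

## Synthetic-data generator

The generator's defaults are the study conditions the package is designed
around: 111 accessions in three populations (36 cultivars / 40 landraces /
35 wild), 225 OGGs with the 18/107/51/49 core/softcore/shell/cloud mix,
gene bodies of 100–300 codons (typical transcription-factor CDS lengths),
within-group pairwise identity ≈ 97 % and between-group identity ≤ 80 %.

* **Ancestral CDSs** are ATG + biased sense codons + TAA. Codon bias is a
  per-amino-acid Dirichlet draw with concentration 1/strength: strength 0
  gives uniform synonym usage, larger values increasingly skewed usage —
  one knob spans the range the CAI/ENC tests need. Amino acids are drawn
  uniformly; real amino-acid composition is not modelled.
* **Between-group dissimilarity** is enforced by rejection sampling against
  the builder's own identity computation, guaranteeing the separability the
  builder assumes (up to 200 attempts per group before a configuration
  error).
* **Mutation** is a per-codon Gillespie process over unit time with channel
  rates syn_rate·s(codon) and nonsyn_rate·n(codon), s/n being the NG86 site
  counts of the current codon (recomputed after every jump). Stop-creating
  changes are never proposed. This makes the rate parameters "expected
  substitutions per site of that class" in exactly the currency NG86
  measures, so equal rates calibrate to ω ≈ 1 (held to [0.9, 1.1] over 200
  replicate pairs in the tests) and the default 0.03/0.01 gives ≈ 1.5 %
  per-copy divergence (≈ 3 % between two members) under mild purifying
  pressure (ω = ⅓).
* **Occupancy** is drawn uniformly inside the requested category band and
  carriers are sampled without replacement; each carrying accession gets
  exactly one member, so copy-number variation within an accession is not
  emulated. Requesting a category whose band is empty at the configured N
  (e.g. cloud below N = 20, softcore below N = 10) is a configuration
  error naming the band.
* **Domain and expression tables**: each group draws a family architecture
  (12 % AP2, 4 % RAV, 79 % single-AP2, 5 % no-AP2); per-gene up/down/ns
  flags are Bernoulli with per-category enrichment multipliers (core-like
  categories enriched), exercising the cross-tabulation stage without an
  expression model.

Everything is driven by one NumPy generator seeded from the config, so a
given config is byte-reproducible. Passing tests on this generator show
that the pipeline recovers structure *under the generator's assumptions* —
point substitutions only (no indels, recombination, or assembly artefacts
beyond optional truncation), independent loci, homogeneous rates across
groups — not that it is robust to every property of real assemblies.

## Problem sizes and numerical choices

Tests and the acceptance script run on a scaled design — 12 accessions /
30 OGGs for builder recovery (the same 97 %/80 % identity separation as the
full design), 200 neutral pairs of 300 codons for ω calibration, 500
random ≤ 30-codon alignments for the NG86 oracle — sizes chosen so the
whole suite completes in about a minute while each check retains its
discriminating power. Determinism conventions: all stochastic components
take explicit seeds; alignment ties are resolved by Biopython's
deterministic enumeration order; exact-test comparisons use a 1e-9 rank
tolerance; ENC is clipped at 61; Fisher tables round half away from zero.

## Known limitations

* The aligner is quadratic per pair; the full 111-accession, 16k-gene
  design is hours of CPU rather than minutes. The architecture (incremental
  best-hit caching, per-stage checkpoints) supports it, but routine use at
  that scale would want the optional external-aligner hook.
* Subfamily resolution depends entirely on the supplied panel; no tree
  inference is attempted.
* The Fisher exact test for Ka/Ks significance treats rounded fractional
  counts as independent observations, the standard approximation for
  counting-method estimates.
* DEG flags are consumed, not computed; differential-expression calling
  belongs to an upstream RNA-seq pipeline.
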