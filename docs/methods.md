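# Methods

## The question the package addresses

Somatic mitochondrial DNA (mtDNA) point mutations clonally expand in ageing
mitotic tissues. Whether their occurrence and expansion is shaped by
purifying selection — as germline mtDNA variation clearly is — can be asked
with three observational comparisons: (i) are the mutations placed randomly
along the genome, or depleted from functionally constrained regions;
(ii) is the ratio of synonymous to amino-acid-changing (non-synonymous,
premature-stop, frameshift) changes in protein genes shifted relative to
other cohorts; (iii) are predicted pathogenicity scores of the observed
amino-acid changes lower than those of all possible changes. `mitospectra`
implements exactly these comparisons for cohorts of mitochondrial point
mutations given in rCRS coordinates (somatic/ageing, rare population
variants, disease-causing mutations), plus a seeded synthetic-cohort
generator so that every stage is testable without external data.

## Reference and annotation

Coordinates are 1-based inclusive on the rCRS heavy strand (m.-notation).
The genome is circular; the control region (16024–576) wraps the origin, so
the "coding region" is 577–16023 (15,447 bases). The 37-gene annotation
(13 protein, 22 tRNA, 2 rRNA genes, with strands and incomplete stop-codon
lengths) is bundled as a TSV transcription of the NC_012920.1 feature table.

The full 16,569-base rCRS sequence is not redistributable here, so the
default reference is a **synthetic stand-in sequence** built
deterministically over the real coordinates: every CDS has an ATG initiator
(in CDS orientation), complete TAA terminators where the feature table has
them, trailing T/TA for polyadenylation-completed stops, no internal stop
codon in any reading frame — including the ATP8/ATP6 (46 bp), ND4L/ND4
(7 bp) and ATP6/CO3 (1 bp) overlaps and the light-strand ND6 — and the
historical N placeholder at position 3107. The generator fixes the
constrained bases first and then repairs internal stops to a fixpoint,
restarting from a new deterministic seed if a locked codon cannot be
repaired. Users with the real NC_012920.1 FASTA can pass it to
`load_reference`, and everything downstream is unchanged. Consequently the
package's tests and the acceptance outputs exercise the full machinery on a
structurally faithful genome, but sequence-specific values (e.g. the residue
identity of a particular variant, or the exact count of possible missense
changes) are properties of the synthetic sequence, not of the real rCRS.

Overlap rule: where genes overlap, a position is tabulated once under the
priority protein > tRNA > rRNA > noncoding, ties to the gene starting
earliest in genome order; per-type base counts therefore partition the
genome exactly. Per-gene annotation (`annotate_all`) still reports one call
per overlapping gene; the single-call API (`annotate`) keeps the most severe
class (frameshift/premature stop > stop loss > non-synonymous > in-frame
indel > synonymous).

## Consequence classification

Substitutions in protein genes are classified by rebuilding the containing
codon with the alternate base (reverse-complemented for light-strand genes;
ref/alt are always stated in heavy-strand orientation) and translating under
the vertebrate mitochondrial code (translation table 2: TGA=Trp, ATA=Met,
AGA/AGG/TAA/TAG=stop). Any initiator codon at codon 1 is read as Met, so a
substitution turning ATG into ATT at codon 1 is synonymous. Indels are
frameshifts unless their length is a multiple of three (in-frame indels get
their own class; they are not pooled with frameshifts by default). Changes
in a complete terminator codon are stop-loss unless the codon remains a stop
(then synonymous); changes in the 1–2 trailing bases of an incomplete stop
codon (8 genome positions) are classed stop-loss with no amino-acid fields,
since no complete codon exists there. tRNA/rRNA-gene mutations are classed
by gene type only; no RNA structural scoring is attempted. For cohort
tables, premature stops and frameshifts are pooled into one "truncating"
reporting category alongside synonymous and non-synonymous.

The exhaustive enumeration generates all 3 substitutions at every
residue-encoding CDS base of the 13 protein genes (terminator codons and
incomplete-stop bases excluded, because residue-substitution predictors
score amino-acid changes only), once per gene in overlap regions. Two
counting conventions are reported: nucleotide substitution events, and
distinct (gene, aa_pos, aa_ref, aa_alt) tuples (different third-base changes
can produce the same residue change). The distinct-tuple count is the
default meaning of "all possible amino-acid variations", since it counts
variations at the residue level; both are always computed.

## Pathogenicity scores

Scores are consumed from a table keyed by amino-acid change, one value in
[0,1] per variant; the package never computes a predictor. Conventions:
non-synonymous substitutions are scored by lookup; synonymous changes score
0 when `synonymous_as_zero` is on (they change no residue) and are excluded
otherwise; truncating changes are always excluded (unscoreable by
residue-substitution predictors); lookup misses are flagged and excluded
from summaries, so reported n can be smaller than the non-synonymous count.
A `collapse_duplicates` flag scores each distinct variant once rather than
per observation; both behaviours exist because published summaries are
ambiguous between them. Summaries are mean ± sample sd (n−1; sd = 0 when
n = 1), printed to 3 decimals. With the convention on, the mean is exactly
the convention-off mean shrunk by n_off/n_on, which is asserted in tests.

The bundled synthetic score table draws one Beta(5.58, 3.11) score per
enumerated distinct missense variant (mean ≈ 0.64, sd ≈ 0.15, matching the
marginal shape of published all-possible-variant score tables). Scores are
independent of the variant's identity, so synthetic cohort-vs-cohort score
differences arise only through composition (e.g. the synonymous-as-zero
convention or selection thinning), not through any built-in severity signal
— which is precisely the null the comparison machinery should not reject.

## Statistics

* **Random placement.** Positions are binned per 2,000 bases from position 1
  (nine bins over the genome; the last is 569 bp); expected counts are
  proportional to each bin's overlap with the analyzed region (default the
  coding region), with an equal-expectation mode for sensitivity. Gene-type
  placement is tested against expectations proportional to the bases each
  type occupies. Both use Pearson X² = Σ(O−E)²/E with df = k−1 and the
  chi-squared upper tail. The gene-type test conditions on the three gene
  classes by default: the ~89 intergenic bases of the coding region would
  contribute an expected count below one at realistic cohort sizes.
* **Cohort comparison.** r×c Pearson chi-squared tests of independence,
  overall and for every pair of cohorts, with no Yates continuity
  correction (a flag enables it); Bonferroni correction is reported as
  fixed significance thresholds 0.05/k, 0.01/k, 0.001/k for k pairwise
  tests (k = 3 → 0.017, 0.003, 0.0003; k = 6 → 0.008), alongside the raw
  p-values.
* **Score distributions.** Two-sided Wilcoxon rank-sum (Mann–Whitney U);
  exact null when both n ≤ 12 and the pooled sample is tie-free, otherwise
  the normal approximation with tie and continuity corrections. The exact
  path is validated against a brute-force enumeration over all rank
  assignments for every tie-free case with n₁+n₂ ≤ 10.

`null_calibration` vectorises the two goodness-of-fit tests across
replicates of uniformly placed cohorts, so type-I error at 10,000 replicates
computes in seconds; a slower property test drives the full cohort generator
through the same check at a few hundred replicates.

## Synthetic cohorts

`CohortSpec` defaults emulate an ageing-colon-like cohort: 156 cells with a
per-cell mutation count distribution of 0/1/2/3/4 at 67/61/20/5/3 in 156
(≈129 mutations in ≈89 mutated cells); type mix 90% transitions, 5%
transversions, 3% deletions, 2% insertions; 65% of transitions C:G→T:A with
C:G→A:T rare (~1% of all substitutions); 39% of mutations homoplasmic, the
rest uniform on 10–95%; COX deficiency probability 0.88 / 0.45 / 0.25 for
cells with a homoplasmic mutation / any mutation / none. Positions are
uniform over the coding region by default (uniform-genome and per-gene-weight
models available); position 3107 (the N) is never drawn. To honour the pair
mix exactly while keeping placement uniform, the pair label is drawn first
and the position uniformly among candidate sites whose reference base
matches the label's ref pair; with the synthetic reference's uniform base
composition this leaves placement indistinguishable from uniform at the
tested resolutions. Ref bases are read from the reference so every record
validates. All generation flows through one explicit seed.

What the generator does **not** emulate: mutational hotspots and sequence
context effects, phylogenetic structure among population variants, linkage
between mutations in a cell, electropherogram-derived heteroplasmy noise,
and any true pathogenicity signal in scores. Passing tests therefore show
the machinery is correct and calibrated under its stated null, not that real
cohorts behave this way.

`spike_selection` models purifying selection as independent binomial
thinning of amino-acid-changing classes (non-synonymous, premature stop,
frameshift) at a given retention probability.
`selection_detection_power` computes the power of the 2×3 spectrum
contingency test by multinomial simulation from the enumeration's class
distribution and its retention-tilted counterpart; at retention 0.5 and
cohort sizes 81 vs 155 the power is ≈50–55% at α = 0.05, stable across
seeds.

## Pipeline and reporting

`run_full_analysis` chains load/simulate → coding-region filter (577–16023,
bounds configurable) → annotation → spectra → randomness tests → pairwise
contingency comparisons → scoring and Wilcoxon comparisons (all cohort
pairs and each cohort against the all-possible score pool, both score
conventions, plus inherited-vs-sporadic score and truncating-fraction
comparisons within a disease cohort), logging before/after counts at every
filter so the sample-size funnel is auditable. When no cohort tables are
supplied it simulates three cohorts: the ageing default; a population cohort
(94% transitions, ~0.6% indels, homoplasmic by definition) thinned at
retention 0.2 to emulate germline purifying selection; and a disease cohort
weighted 3:1 toward tRNA genes with sporadic/inherited labels. Percentages
are reported to 1 decimal and score summaries to 3 decimals. Without a
user-supplied score table the synthetic Beta table is generated and the
report says so; spectrum stages never depend on scores.

## Problem sizes and numerical choices

Default test and acceptance runs use: 1,000 random substitutions for the
annotation-vs-whole-protein oracle; 10,000 replicates for null calibration
(vectorised); cohorts of n = 10,000 single-mutation cells for parameter
recovery (3-binomial-sd bands); 1,000–2,000 replicates for power estimates.
Expected-count vectors are validated to be strictly positive and to match
observed totals within 1e-9. Ties in severity resolve to the gene earliest
in genome order; duplicate (cell, position, alt) records are rejected at
parse time.

## Known limitations

* The default reference sequence is synthetic: structurally faithful, but
  analyses of real cohort tables should load the real NC_012920.1 FASTA
  (ref-base validation will otherwise reject real mutation lists).
* Gene boundaries follow one annotation build; 1–2 bp boundary differences
  in other curations could shift single mutations between classes.
* Heteroplasmy is taken at face value from the input table; homoplasmy
  means exactly 100%.
* RNA-gene mutations are located, not functionally scored.
* The contingency machinery offers no Fisher-exact fallback by default
  (flagged option deliberately omitted from the default path because
  multi-category tables dominate and the tests are calibrated as-is).
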