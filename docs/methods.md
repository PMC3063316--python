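# Methods

## Statistical model

The unit of inference is one (site, tissue) pair. Each expressed sequence
overlapping a known A-to-I site is classified on the transcript strand:
G → edited, A → unedited, anything else (a SNP or sequencing error at the
position) → excluded from both counts. For tissue *T* the 2×2 table
(a, b; c, d) holds edited/unedited counts in *T* and in the pool of all other
tissues. Under the null hypothesis that a sequence's edited status is
independent of tissue, a is hypergeometric given the margins; Fisher's exact
test gives the p-value. Two-sided by default (summing the masses of all
tables as or more extreme in probability), with a one-sided `greater` option
summing the tail a′ ≥ a.

Multiple testing is corrected **within each tissue**: m is the number of
sites testable in *T*, and Benjamini–Hochberg step-up control at q = 0.05
rejects the hypotheses of ranks 1..k where k is the largest rank with
p(k) ≤ (k/m)·q. Reported "FDR corrected" values are BH adjusted p-values
(min-over-suffix form); rejection ⇔ adjusted p ≤ q. Ties in the p-value
ranking are broken by input order; the adjusted values are invariant to
that choice, and the rejection set at a smaller q is always a subset of
the set at a larger q.

### Direction of calls

A rejected pair is emitted as a *call* only when the editing fraction in
*T* exceeds the pool's, a/(a+b) > c/(c+d). The exact test is symmetric:
when one tissue is strongly edited at a site, its counts inflate the pool
that every other tissue is compared against, so well-covered unedited
tissues at that site are rejected as significantly *depleted*. Depletion
against an inflated pool is a side effect of the pooling construction, not
tissue-specific editing, so directionality is part of the call definition
(the underlying two-sided p-values and BH decisions are still computed and
logged undirected).

### Testability filters

A site is tested in *T* only if it has at least one retained observation
there (a+b ≥ 1) and at least `min_edited_in_tissue` edited sequences
(default 1). The latter prevents calling a tissue on pool-side signal
alone; raise it for stricter evidence requirements. With a single tissue in
the catalog the pool is empty, no tests run, and a warning is logged.

## Library curation

Libraries whose annotation is empty/whitespace are excluded (no tissue
source); annotations containing any configurable substring pattern
(defaults: `mix`, `pool`, case-insensitive) are excluded as mixed samples.
Remaining annotations are trimmed and case-folded; an optional two-column
merge map then collapses synonyms — in particular normal and cancerous
variants of one tissue — onto a single category. An annotation mapped to
two categories is a configuration error. Exclusions carry their reason and
can be written as a summary table.

## Classification conventions

Observation rows carry the base as read on the genome **plus strand**; the
site catalog is authoritative for strand, and the single plus-to-transcript
conversion (complementing at minus-strand sites) happens in the classifier.
Coordinates are 1-based and fully closed everywhere in the public formats;
6-column BED input (0-based half-open) is converted at the I/O boundary.
One sequence contributes at most one observation per site (duplicates by
sequence id collapse to the first), guarding against chimeric alignment
records. Observation rows at unknown sites, from unknown libraries, or with
a strand contradicting the catalog are dropped and counted in the log.

## Editing-level estimator

`editing_level_percent(g, total)` returns 100·g/total rounded half-up to
one decimal, matching how editing levels are read off sequencing
chromatograms as the G peak over the G+A peak sum.

## Effect annotation

Scanning operates on transcript-strand sequence supplied by the caller;
locating a genomic site within transcript features (CDS/5'UTR/3'UTR/intron,
per isoform, strand-aware) is a separate step, and a site outside every
feature is labeled intergenic. ESE matrices score every window of matrix
width as the sum of per-position per-base weights; a window is functional
when its score is **≥ threshold** (equality counts — "over the threshold"
leaves equality ambiguous, and the closed reading is adopted). An edit
loses a hit when a functional window overlapping the position drops below
threshold, and gains one in the converse case; gained motifs are reported
even though destruction is usually the interesting direction, since the
symmetric diff costs nothing. ESS hexamers are exact 6-mer matches diffed
the same way. Codon recoding uses the standard genetic code ('*' for stop)
and flags synonymous changes and stop gain/loss.

The bundled matrix files carry the published widths and thresholds of the
SF2/ASF (7, 1.956), SC35 (8, 2.383), SRp40 (7, 2.67) and SRp55 (6, 2.676)
motifs but **synthetic placeholder weights** (marked in filename and
header): the real nucleotide-frequency matrices are distributed with
ESEfinder. The bundled hexamer file is likewise a synthetic four-member
subset of a FAS-hex-3 style list. All correctness tests use toy matrices
and sets, so algorithm behavior never depends on the bundled values;
replace the data files for production annotation. Analyses that require
external trained predictors (phosphorylation, signal peptides,
glycosylation, propeptide cleavage, splice-site models, miRNA/piRNA
targets) are deliberately unsupported and raise a clear error.

## Synthetic data generator

The generator emulates the pipeline's three inputs with known ground
truth: sites alternate strands across chromosomes; each tissue gets a fixed
number of libraries; each (site, library) cell draws its edited count from
Binomial(n, rate), where rate is the tissue's effect level for that site if
one is configured and the background level otherwise. Observations are
emitted as plus-strand base letters honoring site strand, so the classifier
path is always exercised. Decoy libraries annotated `mixed` and `` (empty)
are generated at background rate and exercise both exclusion rules. All
draws come from one `numpy.random.default_rng(seed)` stream: identical
configurations produce byte-identical datasets. Coverage is uniform by
default — real EST coverage is highly uneven across tissues — with an
optional per-tissue multiplier to emulate unevenness.

The generator does **not** simulate alignment artifacts, sequencing error,
SNP contamination, or overlapping transcripts; passing tests therefore
demonstrate correctness of the statistical machinery under the binomial
idealization, not robustness to those real-data complications.

## Numerical choices

- Hypergeometric masses are compared with a relative tolerance of 1e-7
  when deciding whether a table is "as extreme" as the observed one, so
  exact mass ties are included despite floating-point noise.
- The p-value is clamped to the smallest positive float when the tail sum
  underflows, and snapped to exactly 1.0 when it is within 1e-12 of 1
  (every table included).
- Adjusted p-values are computed with a reversed cumulative minimum and
  capped at 1.
- Percent rounding is decimal half-up (not banker's).

## Problem sizes used by the test and acceptance suites

Null error control runs 1000 replicates of 20 sites × 5 tissues × 1
library × 100 observations per site per library at editing probability
0.1; the acceptance script reports the fraction of replicates with zero
calls on this design. Effect recovery runs 100 replicates of 8 sites × 5
tissues × 200 observations per cell with two planted effects at level 0.6
over background 0.05. The Fisher implementation is verified against exact
integer enumeration on every 2×2 table with total ≤ 30, and against
`scipy.stats.fisher_exact` on random tables; BH is verified against the
direct step-up definition and `statsmodels`.

## Known limitations

- BH control is per tissue, as the method prescribes. Error guarantees are
  therefore *per tissue*: across many tissues, the per-tissue q-budgets
  accumulate, so a dataset-wide "no false call anywhere" guarantee does not
  follow, and simulations show replicate-level false calls at roughly the
  per-tissue budget times the number of tissues. Use a smaller q (or a
  dataset-wide correction outside this package) if family-wise control
  across all tissues is required.
- The pool construction makes tests at the same site across tissues
  dependent; BH's FDR guarantee within a tissue still applies (independent
  sites), but no attempt is made to model cross-tissue dependence.
- The 2×2 test treats sequences as independent Bernoulli draws; clustering
  within libraries (one heavily-sequenced clone) is not modeled.
- Genomic-to-transcript sequence extraction (splicing, strand) is the
  caller's responsibility for motif scanning; the package does not lift
  over coordinates between genome assemblies.
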