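# Methods

## Data model and conventions

The package works on a *sites-only* model: every variant carries aggregate
counts (AC, AN, Hom, overall and per population) but no per-individual
genotypes. Internal coordinates are 0-based half-open; VCF and GTF
coordinates (1-based inclusive) are converted at the I/O boundary. The
variant position kept on the record itself stays 1-based because the
identity key `chrom-pos-ref-alt` follows the VCF convention. Chromosome
names are unified by stripping a leading `chr`.

Population codes default to the seven continental groups of large exome
aggregates — AFR, AMR, EAS, FIN, NFE, SAS, OTH — and are configurable
(`StoreConfig.populations`); nothing in the pipeline assumes this
particular set.

## Variant normalization

Multi-allelic sites are split into one record per alternate allele. Each
allele keeps its own AC and Hom, shares the site's AN, and — when the
annotation format declares an `Allele` sub-field — receives only the
consequence entries matching it. Spanning-deletion `*` alleles are dropped
with a warning; AN is shared, so totals are unaffected. Every allele of a
site with more than one ALT is flagged `multiallelic`.

Minimal representation trims the shared suffix, then the shared prefix,
each while both alleles keep length > 1, advancing the position one base
per trimmed prefix base. The procedure is idempotent and position-monotone.
One caveat is inherent to any trimming scheme: for homopolymer-ambiguous
indels whose long allele ends in the same base as the short allele (e.g.
ref `AA` → alt `A`), left-shifted and right-shifted descriptions are both
fixed points, because the "correct" anchor depends on sequence context that
a context-free normalizer cannot see. The padding-invariance property is
therefore stated — and tested — for alleles whose trailing bases differ
(SNVs and unambiguously anchored indels), for which the fixed point is
provably unique; idempotence holds for all alleles.

## Consequence severity

The severity table ships as a plain-text data file
(`data/severity_order.txt`, one Sequence Ontology term per line, most
severe first) following the VEP ordering, so it is inspectable and
replaceable. The "worst consequence" of a variant is the minimal-index term
over all terms of all its per-transcript annotations; it is invariant under
input order by construction. Unknown terms raise an error naming the term
rather than ranking silently.

The consequence sub-field order is always read from the VCF header's
`Format:` declaration — VEP versions reorder and extend the field, so
hard-coding it would corrupt parses silently. Entries with fewer sub-fields
than declared are rejected with a log message and parsing continues.

## Codon arithmetic and MNV candidates

For a transcript with CDS features, the CDS offset of a genomic position is
the number of coding bases strictly 5′ of it in transcript orientation; on
the minus strand the walk starts from the highest genomic coordinate. The
codon number is `offset // 3`. Two SNVs with equal codon number in one
transcript are reported as a multi-nucleotide-variant (MNV) candidate pair
and flagged, since their joint effect on the codon can differ from either
annotation alone.

Because the sites-only model lacks genotypes, candidacy is positional; an
optional co-occurrence table (pairs of variant keys observed in one
individual) restricts pairs to those actually carried together. Pairs are
reported once, members ordered by ascending (pos, ref, alt), and the pair
list itself is sorted the same way — codon order would invert the listing
on minus-strand transcripts, so positional order keeps output deterministic
and strand-independent. Pairs across different alternate alleles of one
site are included (same position implies same codon).

## Coverage aggregation

Per-base coverage rows carry mean depth, median depth and the fraction of
individuals covered at each depth cutoff (the cutoff set is parsed from the
file header). Exon summaries average each metric over all bases of the
exon; a base with no coverage row contributes zero to every metric rather
than being dropped — absence of data must read as absence of depth, since
the coverage track exists to qualify the absence of variation. The per-exon
"median" column is the mean of per-base medians (a median of medians across
bases is not well-defined); the choice is recorded in the summary's
`median_statistic` field. An optional symmetric flank (default 0) can
extend exon intervals before aggregation.

## Histograms

Genotype-quality and depth histograms use 20 equal bins over [0, 100] by
default (configurable edges). Binning is `edge[i] <= v < edge[i+1]`, with
values at or above the last edge folded into the last bin and values below
the first edge excluded, so counts conserve the number of in-range values.
Pre-computed histograms arriving in the VCF INFO fields (`GQ_HIST`,
`DP_HIST`, pipe-separated counts) are parsed into the same structure.

## CNV counts

Only confidently called CNVs count: quality SQ strictly greater than 60
(the boundary call at exactly 60.0 is excluded). A call counts toward every
exon it overlaps by at least one base, regardless of the amount of overlap,
and a call overlapping several exons counts in each. Per-population
breakdowns are preserved. Calls and constraint scores are inputs; no CNV
calling or constraint computation happens here.

## Read-support selection

Per variant and genotype class (het/hom), carriers with DP ≥ 10 and
GQ ≥ 20 qualify; if more than five qualify, the five with the highest GQ
are kept. Ties on GQ break by ascending sample id — the choice is
arbitrary but fixed, because the selection must be reproducible. The
display window is 125 bp wide, centered on the first reference base of the
normalized variant (left flank `floor((w-1)/2)`, right flank the
remainder). Manifests record the external reassembly parameters (padding
300 around SNPs and indels, at most 3 alternate alleles, etc.) verbatim so
a downstream caller could regenerate the per-variant read extracts; no
reassembly or BAM handling happens in this package. Batching partitions
manifests in input order and assigns each (variant, sample, class) a
read-group label `variantkey_sampleid_class`, unique across a run.

## Flags

`low_an` marks variants where the called-allele number is low enough to
make the frequency unreliable: `an_total < 0.8 × an_max`, with `an_max` the
dataset-wide maximum AN and the comparison strict. The 0.8 fraction is the
convention of large exome-aggregate release notes and is configurable.

## Store and query semantics

The store is an embedded single-file SQLite database holding JSON-serialized
objects; interval trees (variants, genes, CNVs) and name indexes are rebuilt
in memory on load. It is single-writer/many-reader: the serving layer never
mutates it. All variant lists are returned in (chrom, pos, ref, alt) order.
Duplicate keys after normalization merge when their counts agree (union of
flags and annotations, with a warning) and are fatal otherwise.

Search resolution order: rsID pattern → variant key / `chrom:pos` →
`chrom:start-stop` region → exact gene symbol (case-insensitive) → alias →
Ensembl-style identifiers → not-found with autocomplete suggestions. Exact
symbol deliberately precedes alias so a symbol that doubles as another
gene's alias resolves to its own gene. Autocomplete ranks symbols before
aliases, lexicographically within each.

Region queries take 1-based inclusive coordinates and are rejected when
`stop − start` strictly exceeds 100 000 bases (configurable), so a query of
exactly 100 kb is served. Gene pages aggregate coverage over the canonical
transcript's exons — the canonical transcript is the one with the longest
CDS, ties broken by lexicographically smallest transcript id. Transcript
pages restrict both annotations and coverage to that transcript. A variant
page for a key absent from the dataset still returns coverage for the
surrounding region, so "not in the dataset" is distinguishable from "not
covered". Variant pages group per-transcript annotations by their most
severe term, collapsing transcripts that share an annotation. Gene pages of
variant-rich genes can be precomputed into a cache whose entries are
byte-identical to fresh computation (payload JSON is deterministic:
sorted keys, fixed separators).

CSV export follows RFC 4180 (CRLF, minimal quoting) with allele frequency
printed to 6 significant digits, switching to scientific notation below
1e-4 (`%.6g`). Filtered (non-PASS) variants are exported with their filter
status; hiding them is a display concern.

## Synthetic data generator

`fixtures.generate(seed, out_dir, n_genes=4, variants_per_gene=15)` writes
the complete input bundle and a `truth.json`. Each gene has two transcripts
(three-exon canonical with the longer CDS, two-exon alternative), CDS
lengths divisible by three, and genes alternate between chromosomes and
strands so codon arithmetic is always exercised on the minus strand. Each
gene contains, by construction: one deliberate same-codon SNV pair, one
multi-allelic site (two alternate alleles), one deletion, one insertion,
and one low-AN site (per-population AN ≈ 300 instead of ≈ 1000, landing
well below 80% of the dataset maximum). Per-population AC is drawn by
assigning each of the AC_total alleles to a population with remaining
capacity, so the per-population sum is exactly the total — stricter than
real releases' adjusted counts, which makes conservation assertable.
Homozygote counts respect `2·Hom ≤ AC` per population. CNV qualities
straddle the SQ 60 threshold and include one call at exactly 60.0; carrier
GQ/DP values straddle the 20/10 filters.

All ground truth is computed with naive, implementation-independent
procedures: a per-base codon walk for MNV pairs, an O(n·m) double loop for
exon CNV counts, filter-sort-slice for read-viz selections, and a direct
minimum over severity ranks for worst consequences. The generator emulates
structure, not population genetics: allele frequencies, mutation-rate
spectra and linkage are unrealistic, coverage is i.i.d. per base, and
consequence terms are drawn independently of the actual alleles. Passing
tests therefore demonstrate the correctness of parsing, normalization,
bookkeeping and page assembly — not calibration against real cohort data.

Default problem sizes (4 genes × 15 alleles, ~1 400 coverage rows, 24 CNV
calls, ~320 carriers) keep the full pipeline comfortably sub-second while
covering every structural case; the generator scales to larger bundles via
its parameters.

## Numerical and degenerate-input choices

- Allele frequency for AN = 0 is defined as 0.0 with a warning (a page
  lists the affected populations in its `warnings`), keeping the row
  rather than dropping it.
- Histogram and coverage fraction monotonicity checks use a 1e-12
  tolerance to absorb float rounding in serialized fixtures.
- `minimal_representation` refuses `ref == alt` (not a variant) and empty
  alleles.
- Empty inputs are first-class everywhere: an empty VCF yields an empty
  stream with the header parsed, an empty CNV table yields zero counts, an
  empty carrier list yields a manifest with an empty selection but a valid
  window, an empty variant table exports a header-only CSV.

## Known limitations

- No genotype matrix: MNV candidacy without a co-occurrence table is
  positional and may pair variants never carried by one individual.
- Right/left anchor ambiguity of homopolymer indels is not resolved
  against a reference sequence (none is ingested).
- rsIDs mapping to several normalized alleles attach to each of them; the
  search returns the first key with the rest as suggestions.
- The HTTP layer is a single-threaded reference server intended for local
  use and tests, not production deployment.
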