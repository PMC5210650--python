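# varbrowse

A backend for browsing large population variant-frequency datasets — the
kind of sites-only exome/genome aggregate (tens of thousands of individuals,
millions of variants) that clinical geneticists consult to separate
pathogenic mutations from benign polymorphisms, and that researchers use to
judge gene essentiality. The package ingests an annotated sites VCF plus
gene models and per-base coverage, computes the gene-, transcript- and
variant-level summaries a variant browser displays, and serves them through
a queryable API with search, region limits and CSV export.

## What it computes

For each alternate allele the dataset carries aggregate counts: the allele
count AC, the total number of called alleles AN, and the homozygote count
Hom, broken down by continental population (AFR, AMR, EAS, FIN, NFE, SAS,
OTH by default). The allele frequency is AC/AN. Around this core the
package implements:

- **Variant normalization** — multi-allelic sites are split per alternate
  allele (every allele of such a site is flagged `multiallelic`), and each
  allele is reduced to *minimal representation*: the shared suffix, then
  prefix, is trimmed while both alleles keep length > 1, the position
  advancing per trimmed prefix base. Equivalent descriptions of one allele
  then unify under a single `chrom-pos-ref-alt` key.
- **Consequence ranking** — VEP-style per-transcript annotations (parsed
  from the pipe-delimited consequence INFO field, whose sub-field order is
  read from the VCF header) are ranked by a severity table of Sequence
  Ontology terms; each variant in a gene table shows the worst consequence
  across all transcripts.
- **Same-codon MNV candidates** — two SNVs falling in the same codon of a
  transcript can jointly change the encoded amino acid, making
  single-variant annotations misleading; such pairs are detected
  strand-aware from the CDS structure and flagged `mnv_candidate`.
- **Coverage aggregation** — per-base mean/median depth and the fraction of
  individuals covered above each depth cutoff, averaged per exon; a base
  with no coverage row counts as zero depth, so the *absence* of data reads
  as absence of depth.
- **Exon CNV counts** — confidently called copy-number variants (quality
  SQ strictly above 60) are counted against every exon they overlap by at
  least one base, with per-population breakdowns.
- **Read-support selection** — for each variant, carrier samples with
  DP ≥ 10 and GQ ≥ 20 are selected per genotype class (at most five,
  highest GQ first, ties broken by sample id), and a manifest records the
  125 bp display window and the reassembly parameters for downstream
  pileup extraction.
- **Browser semantics** — a single search bar resolving rsIDs, variant
  keys, positions, regions, gene symbols, aliases and Ensembl identifiers;
  gene/transcript/variant/region pages; region queries limited to 100 kb;
  RFC-4180 CSV export of every variant table.

Constraint scores (expected/observed counts, z-scores, pLI) and CNV calls
are consumed as pre-calculated input tables, never computed here.

## Worked example

Everything runs off a seeded synthetic bundle, so no downloads are needed:

```bash
varbrowse simulate --seed 7 --out bundle
# wrote bundle with 60 variants to bundle
varbrowse build --vcf bundle/sites.vcf --gtf bundle/genes.gtf \
    --coverage bundle/coverage.tsv --constraint bundle/constraint.tsv \
    --cnv bundle/cnv.tsv --dbsnp bundle/dbsnp.tsv \
    --aliases bundle/aliases.tsv --out store
# wrote 60 variants to store/store.sqlite
varbrowse search rs100001 --store store
# {"kind": "variant", "suggestions": ["1-100091-T-C"], "target": "1-100091-T-C"}
varbrowse export-csv GN0 --store store | head -3
# chrom,pos,rsid,ref,alt,consequence,filter,ac,an,hom,af,ac_AFR,an_AFR,...
# 1,100091,rs100001,T,C,stop_gained,PASS,22,2086,5,0.0105465,3,327,0,...
# 1,100092,,T,G,missense_variant,RF,25,7033,8,0.00355467,3,935,0,...
```

The search resolved the rsID to the normalized variant key `1-100091-T-C`.
In the CSV, each row is one normalized allele: the first carries AC = 22 of
AN = 2086 called alleles (allele frequency 0.0105465, printed with 6
significant digits) with 5 homozygotes, its worst annotation across
transcripts is `stop_gained`, and the trailing columns repeat AC/AN/Hom per
population. The second row failed the site filter (`RF`) and is exported
with its filter status rather than hidden.

```bash
varbrowse readviz-manifest --carriers bundle/carriers.tsv --store store --out manifest.tsv
# wrote 322 manifest rows for 60 variants to manifest.tsv
```

Each manifest row records a selected carrier (DP ≥ 10, GQ ≥ 20, top five
per genotype class by GQ), the 125 bp window around the variant and a
unique read-group label such as `1-100091-T-C_SHET000_het`.

To serve a built store over HTTP:

```bash
varbrowse serve --store store --port 8000
# GET /api/gene/ENSGFX00000, /api/variant/1-100091-T-C,
#     /api/region/1-100000-101000, /api/gene/ENSGFX00000/variants.csv ...
```

## Layout

- `src/varbrowse/model.py` — domain types (variants, gene models, coverage,
  histograms, CNVs, page payloads), all JSON round-trippable
- `src/varbrowse/ingest.py` — VCF / GTF / coverage / side-table readers
- `src/varbrowse/variants.py` — normalization, severity ranking, codon
  arithmetic, MNV detection
- `src/varbrowse/summaries.py` — frequencies, coverage aggregation,
  histograms, CNV counts
- `src/varbrowse/readviz.py` — carrier selection and manifests
- `src/varbrowse/store.py` — embedded SQLite store + interval indexes
- `src/varbrowse/query.py` — search, page assembly, CSV export
- `src/varbrowse/service.py` — WSGI endpoints and the `varbrowse` CLI
- `src/varbrowse/fixtures.py` — seeded synthetic-bundle generator
- `docs/methods.md` — models, conventions and design rationale
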