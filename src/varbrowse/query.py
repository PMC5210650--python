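"""Browser semantics: search resolution, page assembly, region limits and
CSV export, all computed against a :class:`~varbrowse.store.BrowserStore`.

Search resolution order (documented, covered by collision tests):
rsid pattern, then variant/position forms, then region, then exact gene
symbol, then alias, then Ensembl-style identifiers, and finally a
``not_found`` result carrying autocomplete suggestions.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

from . import readviz, summaries
from .model import (
    GenomeInterval,
    ModelError,
    PagePayload,
    Variant,
    parse_variant_key,
)
from .store import BrowserStore
from .variants import worst_consequence

_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_VARIANT_KEY_RE = re.compile(r"^([\w.]+)-(\d+)-([ACGTacgt]+)-([ACGTacgt]+)$")
_CHROM_POS_RE = re.compile(r"^([\w.]+):(\d+)$")
_REGION_RE = re.compile(r"^([\w.]+):(\d+)-(\d+)$")

DEFAULT_REGION_MAX_SPAN = 100_000


@dataclass
class SearchResult:
    """Resolution of one search-bar query."""

    kind: str  # gene | transcript | variant | region | not_found
    target: str = ""
    suggestions: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, "target": self.target, "suggestions": self.suggestions}


def resolve_search(q: str, store: BrowserStore) -> SearchResult:
    """Resolve a free-text query to a gene, transcript, variant or region."""
    q = q.strip()
    if not q:
        raise ValueError("empty query")
    # (1) rsid
    if _RSID_RE.match(q):
        hits = store.variants_by_rsid(q.lower())
        if hits:
            keys = sorted(v.key for v in hits)
            return SearchResult(kind="variant", target=keys[0], suggestions=keys)
        return SearchResult(kind="not_found", suggestions=[])
    # (2) chrom-pos-ref-alt or chrom:pos
    m = _VARIANT_KEY_RE.match(q)
    if m:
        chrom, pos, ref, alt = m.group(1), m.group(2), m.group(3).upper(), m.group(4).upper()
        key = f"{chrom}-{pos}-{ref}-{alt}"
        if store.variant_by_key(key) is not None:
            return SearchResult(kind="variant", target=key)
        return SearchResult(kind="not_found", target=key, suggestions=[])
    m = _CHROM_POS_RE.match(q)
    if m:
        chrom, pos = m.group(1), int(m.group(2))
        at_pos = [
            v for v in store.variants_in(GenomeInterval(chrom, pos - 1, pos))
        ]
        if len(at_pos) == 1:
            return SearchResult(kind="variant", target=at_pos[0].key)
        if at_pos:
            return SearchResult(
                kind="region",
                target=f"{chrom}:{pos}-{pos}",
                suggestions=sorted(v.key for v in at_pos),
            )
        return SearchResult(kind="region", target=f"{chrom}:{pos}-{pos}")
    # (3) chrom:start-stop
    m = _REGION_RE.match(q)
    if m:
        return SearchResult(kind="region", target=q)
    # (4) exact gene symbol (case-insensitive)
    gene = store.gene_by_symbol(q)
    if gene is not None:
        return SearchResult(kind="gene", target=gene.gene_id)
    # (5) alias
    gene = store.gene_by_alias(q)
    if gene is not None:
        return SearchResult(kind="gene", target=gene.gene_id)
    # (6) identifiers
    if q in store.genes:
        return SearchResult(kind="gene", target=q)
    if q in store.transcripts:
        return SearchResult(kind="transcript", target=q)
    # (7) not found, with suggestions
    return SearchResult(kind="not_found", suggestions=autocomplete(q, store))


def autocomplete(prefix: str, store: BrowserStore, limit: int = 20) -> list[str]:
    """Case-insensitive prefix matches over symbols then aliases."""
    if not prefix:
        raise ValueError("prefix must be non-empty")
    p = prefix.upper()
    symbols, aliases = store.all_symbols_and_aliases()
    ranked = [s for s in symbols if s.upper().startswith(p)]
    ranked += [a for a in aliases if a.upper().startswith(p) and a not in ranked]
    return ranked[:limit]


def _variant_row(
    v: Variant,
    store: BrowserStore,
    transcript_id: Optional[str] = None,
) -> dict[str, Any]:
    """One variant-table row.  When ``transcript_id`` is given, the
    consequence shown is the worst over that transcript only."""
    consequences = v.consequences
    if transcript_id is not None:
        consequences = [c for c in consequences if c.transcript_id == transcript_id]
    worst = worst_consequence(consequences, store.severity) if consequences else None
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "rsid": v.rsid,
        "ref": v.ref,
        "alt": v.alt,
        "variant_key": v.key,
        "consequence": worst,
        "filter": v.filter_status,
        "ac": v.ac_total,
        "an": v.an_total,
        "hom": v.hom_total,
        "af": summaries.allele_frequency(v.ac_total, v.an_total)
        if v.an_total else 0.0,
        "flags": sorted(v.flags),
        "populations": {
            p: c.to_dict() for p, c in sorted(v.pop_counts.items())
        },
    }


def _not_found(kind_requested: str, identifier: str) -> PagePayload:
    return PagePayload(
        page_kind="not_found",
        metadata={"requested": kind_requested, "identifier": identifier},
        warnings=[f"{kind_requested} {identifier!r} not found"],
    )


def gene_page(gene_id: str, store: BrowserStore, use_cache: bool = True) -> PagePayload:
    """Assemble the gene overview page.

    The variant table covers all variants in the gene span, each annotated
    with the worst consequence across all transcripts; coverage is
    aggregated over the exons of the canonical transcript; exon CNV counts
    use the store's SQ threshold.
    """
    if use_cache and gene_id in store.payload_cache:
        return PagePayload.from_json(store.payload_cache[gene_id])
    gene = store.gene_by_id(gene_id)
    if gene is None:
        return _not_found("gene", gene_id)
    canonical = store.transcript_by_id(gene.canonical_transcript_id)
    exon_ivs = [
        GenomeInterval(gene.chrom, s, e) for s, e in canonical.exon_intervals()
    ] if canonical else []
    cov_rows = store.coverage_in(gene.span)
    exon_summary, series = summaries.aggregate_coverage(cov_rows, exon_ivs)
    table = [
        _variant_row(v, store) for v in store.variants_in(gene.span)
    ]
    cnv_summary = summaries.cnv_counts(
        store.cnvs_in(gene.span),
        exon_ivs,
        sq_threshold=store.config.cnv_sq_threshold,
        populations=store.config.populations,
    )
    mnv = {
        tid: [list(p) for p in store.mnv_pairs.get(tid, [])]
        for tid in gene.transcript_ids
        if tid in store.mnv_pairs
    }
    payload = PagePayload(
        page_kind="gene",
        metadata={
            "gene": gene.to_dict(),
            "coverage_summary": exon_summary,
            "mnv_pairs": mnv,
            "external_links": _external_links(gene.symbol),
        },
        variant_table=table,
        coverage_series=series,
        cnv_summary=cnv_summary,
    )
    return payload


def transcript_page(transcript_id: str, store: BrowserStore) -> PagePayload:
    """Like the gene page, but annotations and coverage are specific to one
    transcript: only variants annotated against it appear, and each row's
    consequence is the worst over this transcript alone."""
    transcript = store.transcript_by_id(transcript_id)
    if transcript is None:
        return _not_found("transcript", transcript_id)
    gene = store.gene_by_id(transcript.gene_id)
    span = transcript.span
    exon_ivs = [
        GenomeInterval(transcript.chrom, s, e)
        for s, e in transcript.exon_intervals()
    ]
    cov_rows = store.coverage_in(span)
    exon_summary, series = summaries.aggregate_coverage(cov_rows, exon_ivs)
    table = [
        _variant_row(v, store, transcript_id=transcript_id)
        for v in store.variants_in(span)
        if any(c.transcript_id == transcript_id for c in v.consequences)
    ]
    cnv_summary = summaries.cnv_counts(
        store.cnvs_in(span),
        exon_ivs,
        sq_threshold=store.config.cnv_sq_threshold,
        populations=store.config.populations,
    )
    payload = PagePayload(
        page_kind="transcript",
        metadata={
            "transcript": transcript.to_dict(),
            "gene": gene.to_dict() if gene else None,
            "coverage_summary": exon_summary,
        },
        variant_table=table,
        coverage_series=series,
        cnv_summary=cnv_summary,
    )
    return payload


def variant_page(
    key: str,
    store: BrowserStore,
    coverage_context: int = readviz.DEFAULT_WINDOW_WIDTH,
) -> PagePayload:
    """Assemble the variant page, or a coverage-context page if absent.

    Per-transcript annotations are grouped by their most severe consequence
    term (transcripts sharing an annotation collapse into one expandable
    group).  When the variant is not in the dataset, the payload is
    ``not_found`` but still carries coverage for the surrounding region.
    """
    chrom, pos, ref, alt = parse_variant_key(key)  # raises ModelError if malformed
    v = store.variant_by_key(key)
    if v is None:
        window = readviz.display_window(chrom, pos, coverage_context)
        series = store.coverage_in(window)
        return PagePayload(
            page_kind="not_found",
            metadata={"requested": "variant", "identifier": key,
                      "region": window.to_dict()},
            coverage_series=series,
            warnings=[
                f"variant {key} is not in the dataset; showing regional coverage"
            ],
        )
    groups: dict[str, list[dict[str, Any]]] = {}
    for cons in sorted(v.consequences, key=lambda c: c.transcript_id):
        term = store.severity.worst(cons.consequence_terms)
        groups.setdefault(term, []).append(cons.to_dict())
    ordered_groups = [
        {"consequence": term, "annotations": groups[term]}
        for term in sorted(groups, key=store.severity.rank)
    ]
    warnings = []
    pops_an0 = [p for p, c in sorted(v.pop_counts.items()) if c.an == 0]
    if pops_an0:
        warnings.append(f"AN is zero for populations: {', '.join(pops_an0)}")
    payload = PagePayload(
        page_kind="variant",
        metadata={
            "variant_key": v.key,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "rsid": v.rsid,
            "site_quality": v.site_quality,
            "filter": v.filter_status,
            "flags": sorted(v.flags),
            "quality_histograms": {
                n: h.to_dict() for n, h in sorted(v.quality_histograms.items())
            },
            "consequence_groups": ordered_groups,
            "population_table": summaries.population_table(
                v, store.config.populations
            ),
            "readviz_manifest": f"readviz/{v.key}.tsv",
            "external_links": _external_links(v.rsid or v.key),
        },
        warnings=warnings,
    )
    return payload


def region_page(
    chrom: str,
    start: int,
    stop: int,
    store: BrowserStore,
    max_span: Optional[int] = None,
) -> PagePayload:
    """Variants, genes and coverage in a 1-based inclusive region.

    Queries spanning more than ``max_span`` bases (strict, measured as
    stop - start) are rejected with a payload naming the limit.
    """
    if start > stop:
        raise ValueError(f"inverted region coordinates {chrom}:{start}-{stop}")
    if max_span is None:
        max_span = store.config.region_max_span
    span = stop - start
    if span > max_span:
        return PagePayload(
            page_kind="region",
            metadata={
                "chrom": chrom, "start": start, "stop": stop,
                "rejected": True, "max_span": max_span,
            },
            warnings=[
                f"region query spans {span} bases; queries are limited to "
                f"{max_span} bases"
            ],
        )
    interval = GenomeInterval(chrom, start - 1, stop)
    table = [_variant_row(v, store) for v in store.variants_in(interval)]
    genes = [g.to_dict() for g in store.genes_in(interval)]
    series = store.coverage_in(interval)
    return PagePayload(
        page_kind="region",
        metadata={
            "chrom": chrom, "start": start, "stop": stop,
            "rejected": False, "max_span": max_span, "genes": genes,
        },
        variant_table=table,
        coverage_series=series,
    )


def format_af(af: float) -> str:
    """Allele-frequency display format: 6 significant digits, scientific
    notation below 1e-4 (Python ``%.6g``)."""
    return f"{af:.6g}"


def export_variant_table_csv(
    payload: PagePayload,
    populations: Sequence[str] = None,
) -> str:
    """RFC-4180 CSV of a page's variant table (header + one row per variant)."""
    if populations is None:
        pops = sorted({
            p for row in payload.variant_table for p in row.get("populations", {})
        })
    else:
        pops = list(populations)
    header = ["chrom", "pos", "rsid", "ref", "alt", "consequence", "filter",
              "ac", "an", "hom", "af"]
    for p in pops:
        header += [f"ac_{p}", f"an_{p}", f"hom_{p}"]
    buf = io.StringIO()
    writer = csv.writer(buf, quoting=csv.QUOTE_MINIMAL, lineterminator="\r\n")
    writer.writerow(header)
    for row in payload.variant_table:
        out = [
            row["chrom"], row["pos"], row["rsid"] or "", row["ref"], row["alt"],
            row["consequence"] or "", row["filter"], row["ac"], row["an"],
            row["hom"], format_af(row["af"]),
        ]
        for p in pops:
            counts = row.get("populations", {}).get(p, {"ac": 0, "an": 0, "hom": 0})
            out += [counts["ac"], counts["an"], counts["hom"]]
        writer.writerow(out)
    return buf.getvalue()


def _external_links(identifier: str) -> dict[str, str]:
    """Templated link-outs only; the client renders them."""
    return {
        "ucsc": "https://genome.ucsc.edu/cgi-bin/hgTracks?position={id}",
        "dbsnp": "https://www.ncbi.nlm.nih.gov/snp/{id}",
        "clinvar": "https://www.ncbi.nlm.nih.gov/clinvar/?term={id}",
    }
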