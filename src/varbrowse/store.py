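"""The browser store: a queryable index over all ingested content.

``build`` runs the full ingest/normalize/flag pipeline and yields a
:class:`BrowserStore` supporting key, interval and name lookups.  The store
persists to a single embedded SQLite file; interval trees are rebuilt in
memory on load.  The store is single-writer / many-reader: the serving layer
never mutates it.
"""

from __future__ import annotations

import bisect
import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

from intervaltree import IntervalTree

from . import ingest, variants as varmod
from .model import (
    CNVCall,
    CoverageRow,
    DEFAULT_POPULATIONS,
    GeneModel,
    GenomeInterval,
    TranscriptModel,
    Variant,
    variant_key,
)
from .variants import SeverityTable

logger = logging.getLogger(__name__)

STORE_FILENAME = "store.sqlite"

#: Genes with at least this many variants get their page payload precomputed.
DEFAULT_PRECOMPUTE_THRESHOLD = 50


class StoreError(RuntimeError):
    pass


@dataclass
class StoreConfig:
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    csq_field_name: str = "CSQ"
    low_an_threshold_fraction: float = 0.8
    cnv_sq_threshold: float = 60.0
    region_max_span: int = 100_000

    def to_dict(self) -> dict[str, Any]:
        return {
            "populations": list(self.populations),
            "csq_field_name": self.csq_field_name,
            "low_an_threshold_fraction": self.low_an_threshold_fraction,
            "cnv_sq_threshold": self.cnv_sq_threshold,
            "region_max_span": self.region_max_span,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StoreConfig":
        return cls(
            populations=tuple(d.get("populations", DEFAULT_POPULATIONS)),
            csq_field_name=d.get("csq_field_name", "CSQ"),
            low_an_threshold_fraction=float(d.get("low_an_threshold_fraction", 0.8)),
            cnv_sq_threshold=float(d.get("cnv_sq_threshold", 60.0)),
            region_max_span=int(d.get("region_max_span", 100_000)),
        )


def _variant_sort_key(v: Variant) -> tuple[str, int, str, str]:
    return (v.chrom, v.pos, v.ref, v.alt)


@dataclass
class BrowserStore:
    """In-memory queryable index; see module docstring."""

    config: StoreConfig = field(default_factory=StoreConfig)
    severity: SeverityTable = field(default_factory=SeverityTable.default)
    variants: dict[str, Variant] = field(default_factory=dict)
    genes: dict[str, GeneModel] = field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    coverage: dict[str, list[CoverageRow]] = field(default_factory=dict)  # per chrom, pos-sorted
    cnv_calls: list[CNVCall] = field(default_factory=list)
    rsid_index: dict[str, list[str]] = field(default_factory=dict)
    mnv_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    an_max: int = 0
    payload_cache: dict[str, str] = field(default_factory=dict)

    # rebuilt, never persisted
    _variant_tree: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _gene_tree: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _cnv_tree: dict[str, IntervalTree] = field(default_factory=dict, repr=False)
    _symbol_index: dict[str, str] = field(default_factory=dict, repr=False)
    _alias_index: dict[str, str] = field(default_factory=dict, repr=False)
    _coverage_pos: dict[str, list[int]] = field(default_factory=dict, repr=False)

    # -- index construction -------------------------------------------------

    def reindex(self) -> None:
        """Rebuild all derived in-memory indexes from the primary maps."""
        self._variant_tree = {}
        for v in self.variants.values():
            start0 = v.pos - 1
            self._variant_tree.setdefault(v.chrom, IntervalTree()).addi(
                start0, start0 + len(v.ref), v.key
            )
        self._gene_tree = {}
        self._symbol_index = {}
        self._alias_index = {}
        for g in self.genes.values():
            self._gene_tree.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g.gene_id
            )
            self._symbol_index[g.symbol.upper()] = g.gene_id
            for alias in g.aliases:
                self._alias_index.setdefault(alias.upper(), g.gene_id)
        self._cnv_tree = {}
        for i, call in enumerate(self.cnv_calls):
            self._cnv_tree.setdefault(call.chrom, IntervalTree()).addi(
                call.start, call.end, i
            )
        for chrom in self.coverage:
            self.coverage[chrom].sort(key=lambda r: r.pos)
        self._coverage_pos = {
            chrom: [r.pos for r in rows] for chrom, rows in self.coverage.items()
        }

    # -- lookups -------------------------------------------------------------

    def variant_by_key(self, key: str) -> Optional[Variant]:
        return self.variants.get(key)

    def variants_in(self, interval: GenomeInterval) -> list[Variant]:
        """Variants whose reference span overlaps the interval, sorted by
        (chrom, pos, ref, alt)."""
        tree = self._variant_tree.get(interval.chrom)
        if tree is None:
            return []
        found = [self.variants[hit.data] for hit in tree.overlap(interval.start, interval.end)]
        return sorted(found, key=_variant_sort_key)

    def gene_by_id(self, gene_id: str) -> Optional[GeneModel]:
        return self.genes.get(gene_id)

    def gene_by_symbol(self, symbol: str) -> Optional[GeneModel]:
        gid = self._symbol_index.get(symbol.upper())
        return self.genes.get(gid) if gid else None

    def gene_by_alias(self, alias: str) -> Optional[GeneModel]:
        gid = self._alias_index.get(alias.upper())
        return self.genes.get(gid) if gid else None

    def genes_in(self, interval: GenomeInterval) -> list[GeneModel]:
        tree = self._gene_tree.get(interval.chrom)
        if tree is None:
            return []
        found = [self.genes[hit.data] for hit in tree.overlap(interval.start, interval.end)]
        return sorted(found, key=lambda g: (g.chrom, g.start, g.gene_id))

    def transcript_by_id(self, transcript_id: str) -> Optional[TranscriptModel]:
        return self.transcripts.get(transcript_id)

    def variants_by_rsid(self, rsid: str) -> list[Variant]:
        return [
            self.variants[k] for k in self.rsid_index.get(rsid, [])
            if k in self.variants
        ]

    def coverage_in(self, interval: GenomeInterval) -> list[CoverageRow]:
        rows = self.coverage.get(interval.chrom, [])
        positions = self._coverage_pos.get(interval.chrom, [])
        # rows carry 1-based positions; interval is 0-based half-open
        lo = bisect.bisect_left(positions, interval.start + 1)
        hi = bisect.bisect_right(positions, interval.end)
        return rows[lo:hi]

    def cnvs_in(self, interval: GenomeInterval) -> list[CNVCall]:
        tree = self._cnv_tree.get(interval.chrom)
        if tree is None:
            return []
        found = [self.cnv_calls[hit.data] for hit in tree.overlap(interval.start, interval.end)]
        return sorted(found, key=lambda c: (c.chrom, c.start, c.end, c.sample_id))

    def all_symbols_and_aliases(self) -> tuple[list[str], list[str]]:
        symbols = sorted(g.symbol for g in self.genes.values())
        aliases = sorted(a for g in self.genes.values() for a in g.aliases)
        return symbols, aliases

    # -- mutation during build ----------------------------------------------

    def add_variant(self, v: Variant) -> None:
        existing = self.variants.get(v.key)
        if existing is not None:
            same_counts = (
                existing.ac_total == v.ac_total
                and existing.an_total == v.an_total
                and existing.hom_total == v.hom_total
            )
            if not same_counts:
                raise StoreError(
                    f"duplicate variant key {v.key} after normalization with "
                    f"conflicting counts"
                )
            logger.warning("merging duplicate variant %s (identical counts)", v.key)
            existing.flags |= v.flags
            seen = {
                (c.transcript_id, tuple(c.consequence_terms))
                for c in existing.consequences
            }
            for c in v.consequences:
                if (c.transcript_id, tuple(c.consequence_terms)) not in seen:
                    existing.consequences.append(c)
            if existing.rsid is None:
                existing.rsid = v.rsid
            return
        self.variants[v.key] = v


def build(
    vcf_path: str | Path,
    gtf_path: str | Path,
    coverage_path: Optional[str | Path] = None,
    constraint_path: Optional[str | Path] = None,
    cnv_path: Optional[str | Path] = None,
    dbsnp_path: Optional[str | Path] = None,
    alias_path: Optional[str | Path] = None,
    config: Optional[StoreConfig] = None,
    severity: Optional[SeverityTable] = None,
) -> BrowserStore:
    """Ingest all inputs, normalize and flag every variant, build indexes."""
    config = config or StoreConfig()
    store = BrowserStore(config=config, severity=severity or SeverityTable.default())

    genes, transcripts = ingest.read_gene_models(gtf_path, alias_path=alias_path)
    constraint, cnv_calls, dbsnp = ingest.read_side_tables(
        constraint_path, cnv_path, dbsnp_path
    )
    for tid, rec in constraint.items():
        t = transcripts.get(tid)
        if t is not None:
            g = genes.get(t.gene_id)
            if g is not None and g.canonical_transcript_id == tid:
                g.constraint = rec
    store.genes = genes
    store.transcripts = transcripts
    store.cnv_calls = cnv_calls

    # position -> rsid lookup built from the dbSNP table
    dbsnp_by_site: dict[tuple[str, int, str, str], str] = {}
    for rsid, entries in dbsnp.items():
        for (chrom, pos, ref, alt) in entries:
            npos, nref, nalt = varmod.minimal_representation(pos, ref, alt)
            dbsnp_by_site[(chrom, npos, nref, nalt)] = rsid

    reader = ingest.read_sites_vcf(
        vcf_path,
        csq_field_name=config.csq_field_name,
        populations=config.populations,
    )
    for record in reader:
        for v in varmod.split_multiallelic(record, populations=config.populations):
            varmod.normalize_variant(v)
            site = (v.chrom, v.pos, v.ref, v.alt)
            if site in dbsnp_by_site:
                v.rsid = dbsnp_by_site[site]
            v.validate()
            store.add_variant(v)

    store.an_max = max((v.an_total for v in store.variants.values()), default=0)
    if store.an_max > 0:
        for v in store.variants.values():
            varmod.flag_low_an(
                v, store.an_max, threshold_fraction=config.low_an_threshold_fraction
            )

    # same-codon MNV candidates, per transcript
    variants_sorted = sorted(store.variants.values(), key=_variant_sort_key)
    by_transcript: dict[str, list[Variant]] = {}
    for v in variants_sorted:
        for cons in v.consequences:
            if cons.transcript_id in transcripts:
                by_transcript.setdefault(cons.transcript_id, []).append(v)
    for tid in sorted(by_transcript):
        pairs = varmod.detect_mnv_candidates(by_transcript[tid], transcripts[tid])
        if pairs:
            store.mnv_pairs[tid] = pairs

    # rsid index (from VCF ID column and dbSNP table alike)
    for v in variants_sorted:
        if v.rsid:
            store.rsid_index.setdefault(v.rsid, []).append(v.key)

    if coverage_path is not None:
        for row in ingest.read_coverage(coverage_path):
            row.validate()
            store.coverage.setdefault(row.chrom, []).append(row)

    store.reindex()
    return store


def precompute_large_gene_payloads(
    store: BrowserStore,
    variant_count_threshold: int = DEFAULT_PRECOMPUTE_THRESHOLD,
) -> dict[str, str]:
    """Serialize gene-page payloads for genes with many variants into a cache.

    A cache hit later returns a payload whose serialization is byte-identical
    to a fresh computation (payload JSON is deterministic).
    """
    from . import query  # local import: query consumes the store, not vice versa

    cache: dict[str, str] = {}
    for gene_id in sorted(store.genes):
        gene = store.genes[gene_id]
        n = len(store.variants_in(gene.span))
        if n >= variant_count_threshold:
            payload = query.gene_page(gene_id, store, use_cache=False)
            cache[gene_id] = payload.to_json()
    store.payload_cache = cache
    return cache


# ---------------------------------------------------------------------------
# Persistence (single-file embedded SQLite)
# ---------------------------------------------------------------------------

def save(store: BrowserStore, out_dir: str | Path) -> Path:
    """Write the store to ``out_dir/store.sqlite``; returns the file path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    db_path = out_dir / STORE_FILENAME
    if db_path.exists():
        db_path.unlink()
    con = sqlite3.connect(db_path)
    try:
        con.execute(
            "CREATE TABLE objects (kind TEXT NOT NULL, key TEXT NOT NULL, "
            "value TEXT NOT NULL, PRIMARY KEY (kind, key))"
        )

        def put(kind: str, key: str, obj: Any) -> None:
            con.execute(
                "INSERT INTO objects (kind, key, value) VALUES (?, ?, ?)",
                (kind, key, json.dumps(obj, sort_keys=True)),
            )

        put("meta", "config", store.config.to_dict())
        put("meta", "an_max", store.an_max)
        put("meta", "severity", list(store.severity.terms))
        for key in sorted(store.variants):
            put("variant", key, store.variants[key].to_dict())
        for gid in sorted(store.genes):
            put("gene", gid, store.genes[gid].to_dict())
        for tid in sorted(store.transcripts):
            put("transcript", tid, store.transcripts[tid].to_dict())
        for chrom in sorted(store.coverage):
            put("coverage", chrom, [r.to_dict() for r in store.coverage[chrom]])
        put("cnv", "calls", [c.to_dict() for c in store.cnv_calls])
        put("rsid", "index", store.rsid_index)
        put("mnv", "pairs", {t: [list(p) for p in ps] for t, ps in store.mnv_pairs.items()})
        for gid in sorted(store.payload_cache):
            put("payload", gid, store.payload_cache[gid])
        con.commit()
    finally:
        con.close()
    return db_path


def load(store_dir: str | Path) -> BrowserStore:
    """Load a store previously written by :func:`save`."""
    db_path = Path(store_dir) / STORE_FILENAME
    if not db_path.exists():
        raise StoreError(f"store file not found: {db_path}")
    con = sqlite3.connect(db_path)
    try:
        rows = con.execute("SELECT kind, key, value FROM objects").fetchall()
    finally:
        con.close()
    by_kind: dict[str, dict[str, Any]] = {}
    for kind, key, value in rows:
        by_kind.setdefault(kind, {})[key] = json.loads(value)
    meta = by_kind.get("meta", {})
    store = BrowserStore(
        config=StoreConfig.from_dict(meta.get("config", {})),
        severity=SeverityTable(meta["severity"]) if "severity" in meta
        else SeverityTable.default(),
    )
    store.an_max = int(meta.get("an_max", 0))
    store.variants = {
        k: Variant.from_dict(d) for k, d in by_kind.get("variant", {}).items()
    }
    store.genes = {k: GeneModel.from_dict(d) for k, d in by_kind.get("gene", {}).items()}
    store.transcripts = {
        k: TranscriptModel.from_dict(d) for k, d in by_kind.get("transcript", {}).items()
    }
    store.coverage = {
        chrom: [CoverageRow.from_dict(r) for r in rows]
        for chrom, rows in by_kind.get("coverage", {}).items()
    }
    store.cnv_calls = [
        CNVCall.from_dict(c) for c in by_kind.get("cnv", {}).get("calls", [])
    ]
    store.rsid_index = by_kind.get("rsid", {}).get("index", {})
    store.mnv_pairs = {
        t: [tuple(p) for p in ps]
        for t, ps in by_kind.get("mnv", {}).get("pairs", {}).items()
    }
    store.payload_cache = dict(by_kind.get("payload", {}))
    store.reindex()
    return store
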