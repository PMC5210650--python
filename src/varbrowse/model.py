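"""Shared domain types for the variant-browser backend.

Conventions
-----------
* Internal coordinates are 0-based half-open intervals.  VCF and GTF
  coordinates (1-based, inclusive) are converted at the I/O boundary and
  converted back on output.
* A variant is identified by the string ``chrom-pos-ref-alt`` where ``pos``
  is the 1-based position of the first reference base *after* normalization
  to minimal representation.
* Population codes default to the seven continental groups of the source
  exome dataset; the set is configurable everywhere it is consumed.

All types serialize to plain JSON-compatible dictionaries via ``to_dict`` /
``from_dict`` so page payloads and the embedded store can persist them
without loss (bit-identical integers, floats carried as-is).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

DEFAULT_POPULATIONS: tuple[str, ...] = ("AFR", "AMR", "EAS", "FIN", "NFE", "SAS", "OTH")

#: Flags a variant record may carry.
VARIANT_FLAGS = frozenset({"multiallelic", "low_an", "mnv_candidate"})

_ALLELE_ALPHABET = frozenset("ACGT")


class ModelError(ValueError):
    """An invariant of a domain type was violated."""


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical ``chrom-pos-ref-alt`` identity key (pos 1-based)."""
    return f"{chrom}-{pos}-{ref}-{alt}"


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    """Parse a ``chrom-pos-ref-alt`` key; raises ModelError naming the format."""
    parts = key.split("-")
    if len(parts) != 4:
        raise ModelError(
            f"malformed variant key {key!r}: expected format chrom-pos-ref-alt"
        )
    chrom, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise ModelError(
            f"malformed variant key {key!r}: expected format chrom-pos-ref-alt "
            f"with integer position, got {pos_s!r}"
        ) from None
    if not chrom or not ref or not alt:
        raise ModelError(
            f"malformed variant key {key!r}: expected format chrom-pos-ref-alt"
        )
    return chrom, pos, ref, alt


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ModelError("GenomeInterval.chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"GenomeInterval requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos0: int) -> bool:
        """Membership of a 0-based position."""
        return self.start <= pos0 < self.end

    def to_dict(self) -> dict[str, Any]:
        return {"chrom": self.chrom, "start": self.start, "end": self.end}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GenomeInterval":
        return cls(chrom=d["chrom"], start=int(d["start"]), end=int(d["end"]))


@dataclass
class PopulationCounts:
    """Per-population allele count (AC), allele number (AN), homozygote count."""

    ac: int
    an: int
    hom: int

    def validate(self) -> None:
        if self.ac < 0 or self.an < 0 or self.hom < 0:
            raise ModelError("population counts must be non-negative")
        if self.ac > self.an:
            raise ModelError(f"population ac ({self.ac}) exceeds an ({self.an})")
        if 2 * self.hom > self.ac:
            raise ModelError(f"2*hom ({2 * self.hom}) exceeds ac ({self.ac})")

    def to_dict(self) -> dict[str, int]:
        return {"ac": self.ac, "an": self.an, "hom": self.hom}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PopulationCounts":
        return cls(ac=int(d["ac"]), an=int(d["an"]), hom=int(d["hom"]))


@dataclass
class MetricHistogram:
    """Pre-binned histogram of a genotype-level quality metric."""

    metric_name: str
    bin_edges: list[float]
    counts: list[int]

    def validate(self) -> None:
        if any(nxt <= prev for prev, nxt in zip(self.bin_edges, self.bin_edges[1:])):
            raise ModelError("histogram bin_edges must be strictly ascending")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ModelError(
                f"histogram needs len(counts) == len(bin_edges) - 1, got "
                f"{len(self.counts)} counts for {len(self.bin_edges)} edges"
            )
        if any(c < 0 for c in self.counts):
            raise ModelError("histogram counts must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "metric_name": self.metric_name,
            "bin_edges": list(self.bin_edges),
            "counts": list(self.counts),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MetricHistogram":
        return cls(
            metric_name=d["metric_name"],
            bin_edges=[float(x) for x in d["bin_edges"]],
            counts=[int(x) for x in d["counts"]],
        )


@dataclass
class TranscriptConsequence:
    """One VEP-style annotation of a variant against one transcript."""

    transcript_id: str
    gene_id: str
    consequence_terms: list[str]
    polyphen: Optional[tuple[str, float]] = None
    sift: Optional[tuple[str, float]] = None
    lof: Optional[str] = None
    is_canonical: bool = False

    def validate(self) -> None:
        if not self.consequence_terms:
            raise ModelError("consequence_terms must be non-empty")

    def to_dict(self) -> dict[str, Any]:
        return {
            "transcript_id": self.transcript_id,
            "gene_id": self.gene_id,
            "consequence_terms": list(self.consequence_terms),
            "polyphen": list(self.polyphen) if self.polyphen else None,
            "sift": list(self.sift) if self.sift else None,
            "lof": self.lof,
            "is_canonical": self.is_canonical,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TranscriptConsequence":
        def _pair(v: Any) -> Optional[tuple[str, float]]:
            return (v[0], float(v[1])) if v else None

        return cls(
            transcript_id=d["transcript_id"],
            gene_id=d["gene_id"],
            consequence_terms=list(d["consequence_terms"]),
            polyphen=_pair(d.get("polyphen")),
            sift=_pair(d.get("sift")),
            lof=d.get("lof"),
            is_canonical=bool(d.get("is_canonical", False)),
        )


@dataclass
class Variant:
    """One normalized alternate allele at a site, with aggregate counts.

    ``pos`` is 1-based (VCF convention) for the first reference base.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: Optional[str] = None
    site_quality: float = 0.0
    filter_status: str = "PASS"
    ac_total: int = 0
    an_total: int = 0
    hom_total: int = 0
    pop_counts: dict[str, PopulationCounts] = field(default_factory=dict)
    quality_histograms: dict[str, MetricHistogram] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    consequences: list[TranscriptConsequence] = field(default_factory=list)

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def validate(self) -> None:
        if self.ref == self.alt:
            raise ModelError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_ALPHABET:
                raise ModelError(f"allele {allele!r} is not a non-empty ACGT string")
        if not (0 <= self.ac_total <= self.an_total):
            raise ModelError(
                f"ac_total ({self.ac_total}) must lie in [0, an_total={self.an_total}]"
            )
        if 2 * self.hom_total > self.ac_total:
            raise ModelError("2*hom_total exceeds ac_total")
        if not self.flags <= VARIANT_FLAGS:
            raise ModelError(f"unknown flags: {sorted(self.flags - VARIANT_FLAGS)}")
        pop_ac = 0
        for pop, pc in self.pop_counts.items():
            try:
                pc.validate()
            except ModelError as exc:
                raise ModelError(f"population {pop}: {exc}") from None
            pop_ac += pc.ac
        if pop_ac > self.ac_total:
            raise ModelError(
                f"sum of population ac ({pop_ac}) exceeds ac_total ({self.ac_total})"
            )
        for cons in self.consequences:
            cons.validate()
        for hist in self.quality_histograms.values():
            hist.validate()

    def to_dict(self) -> dict[str, Any]:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "ref": self.ref,
            "alt": self.alt,
            "rsid": self.rsid,
            "site_quality": self.site_quality,
            "filter_status": self.filter_status,
            "ac_total": self.ac_total,
            "an_total": self.an_total,
            "hom_total": self.hom_total,
            "pop_counts": {p: c.to_dict() for p, c in sorted(self.pop_counts.items())},
            "quality_histograms": {
                n: h.to_dict() for n, h in sorted(self.quality_histograms.items())
            },
            "flags": sorted(self.flags),
            "consequences": [c.to_dict() for c in self.consequences],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Variant":
        return cls(
            chrom=d["chrom"],
            pos=int(d["pos"]),
            ref=d["ref"],
            alt=d["alt"],
            rsid=d.get("rsid"),
            site_quality=float(d.get("site_quality", 0.0)),
            filter_status=d.get("filter_status", "PASS"),
            ac_total=int(d["ac_total"]),
            an_total=int(d["an_total"]),
            hom_total=int(d["hom_total"]),
            pop_counts={
                p: PopulationCounts.from_dict(c)
                for p, c in d.get("pop_counts", {}).items()
            },
            quality_histograms={
                n: MetricHistogram.from_dict(h)
                for n, h in d.get("quality_histograms", {}).items()
            },
            flags=set(d.get("flags", [])),
            consequences=[
                TranscriptConsequence.from_dict(c) for c in d.get("consequences", [])
            ],
        )


@dataclass
class ConstraintRecord:
    """Pre-calculated per-transcript constraint scores (consumed, never computed)."""

    transcript_id: str
    exp_syn: float = 0.0
    obs_syn: int = 0
    syn_z: float = 0.0
    exp_mis: float = 0.0
    obs_mis: int = 0
    mis_z: float = 0.0
    exp_lof: float = 0.0
    obs_lof: int = 0
    lof_z: float = 0.0
    pli: float = 0.0

    def validate(self) -> None:
        for name in ("exp_syn", "exp_mis", "exp_lof"):
            if getattr(self, name) < 0:
                raise ModelError(f"{name} must be >= 0")
        if not (0.0 <= self.pli <= 1.0):
            raise ModelError(f"pli must lie in [0, 1], got {self.pli}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "transcript_id": self.transcript_id,
            "exp_syn": self.exp_syn,
            "obs_syn": self.obs_syn,
            "syn_z": self.syn_z,
            "exp_mis": self.exp_mis,
            "obs_mis": self.obs_mis,
            "mis_z": self.mis_z,
            "exp_lof": self.exp_lof,
            "obs_lof": self.obs_lof,
            "lof_z": self.lof_z,
            "pli": self.pli,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ConstraintRecord":
        return cls(
            transcript_id=d["transcript_id"],
            exp_syn=float(d["exp_syn"]),
            obs_syn=int(d["obs_syn"]),
            syn_z=float(d["syn_z"]),
            exp_mis=float(d["exp_mis"]),
            obs_mis=int(d["obs_mis"]),
            mis_z=float(d["mis_z"]),
            exp_lof=float(d["exp_lof"]),
            obs_lof=int(d["obs_lof"]),
            lof_z=float(d["lof_z"]),
            pli=float(d["pli"]),
        )


@dataclass
class ExonFeature:
    """One structural feature of a transcript, in genomic coordinates."""

    start: int
    end: int
    kind: str  # exon | CDS | UTR

    def validate(self) -> None:
        if self.kind not in ("exon", "CDS", "UTR"):
            raise ModelError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ModelError("feature requires 0 <= start < end")

    def to_dict(self) -> dict[str, Any]:
        return {"start": self.start, "end": self.end, "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExonFeature":
        return cls(start=int(d["start"]), end=int(d["end"]), kind=d["kind"])


@dataclass
class TranscriptModel:
    """Genomic structure of a transcript; exons kept in genomic order."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonFeature] = field(default_factory=list)

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be + or -, got {self.strand!r}")
        by_kind: dict[str, list[ExonFeature]] = {}
        for f in self.exons:
            f.validate()
            by_kind.setdefault(f.kind, []).append(f)
        for kind, feats in by_kind.items():
            feats = sorted(feats, key=lambda f: f.start)
            for a, b in zip(feats, feats[1:]):
                if b.start < a.end:
                    raise ModelError(
                        f"{kind} features overlap in transcript {self.transcript_id}"
                    )

    def intervals(self, kind: str) -> list[tuple[int, int]]:
        """Genomic-order (start, end) spans of the given feature kind."""
        return sorted(
            (f.start, f.end) for f in self.exons if f.kind == kind
        )

    def cds_intervals(self) -> list[tuple[int, int]]:
        return self.intervals("CDS")

    def exon_intervals(self) -> list[tuple[int, int]]:
        return self.intervals("exon")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals())

    @property
    def span(self) -> GenomeInterval:
        starts = [f.start for f in self.exons]
        ends = [f.end for f in self.exons]
        return GenomeInterval(self.chrom, min(starts), max(ends))

    def to_dict(self) -> dict[str, Any]:
        return {
            "transcript_id": self.transcript_id,
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "exons": [f.to_dict() for f in self.exons],
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TranscriptModel":
        return cls(
            transcript_id=d["transcript_id"],
            gene_id=d["gene_id"],
            chrom=d["chrom"],
            strand=d["strand"],
            exons=[ExonFeature.from_dict(f) for f in d["exons"]],
        )


@dataclass
class GeneModel:
    """A gene with symbol/alias metadata, transcript membership and constraint."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    canonical_transcript_id: str
    transcript_ids: list[str] = field(default_factory=list)
    aliases: list[str] = field(default_factory=list)
    constraint: Optional[ConstraintRecord] = None

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end)

    def validate(self) -> None:
        if self.canonical_transcript_id not in self.transcript_ids:
            raise ModelError(
                f"canonical transcript {self.canonical_transcript_id} of gene "
                f"{self.gene_id} is not among its transcripts"
            )
        if self.constraint is not None:
            self.constraint.validate()

    def to_dict(self) -> dict[str, Any]:
        return {
            "gene_id": self.gene_id,
            "symbol": self.symbol,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "canonical_transcript_id": self.canonical_transcript_id,
            "transcript_ids": list(self.transcript_ids),
            "aliases": list(self.aliases),
            "constraint": self.constraint.to_dict() if self.constraint else None,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GeneModel":
        return cls(
            gene_id=d["gene_id"],
            symbol=d["symbol"],
            chrom=d["chrom"],
            start=int(d["start"]),
            end=int(d["end"]),
            strand=d["strand"],
            canonical_transcript_id=d["canonical_transcript_id"],
            transcript_ids=list(d["transcript_ids"]),
            aliases=list(d.get("aliases", [])),
            constraint=(
                ConstraintRecord.from_dict(d["constraint"]) if d.get("constraint") else None
            ),
        )


@dataclass
class CoverageRow:
    """Per-base depth metrics; ``frac_over`` maps depth cutoff -> fraction."""

    chrom: str
    pos: int  # 1-based
    mean_depth: float
    median_depth: float
    frac_over: dict[int, float] = field(default_factory=dict)

    def validate(self) -> None:
        prev = 1.0 + 1e-12
        for cutoff in sorted(self.frac_over):
            frac = self.frac_over[cutoff]
            if not (0.0 <= frac <= 1.0):
                raise ModelError(
                    f"coverage fraction {frac} at {self.chrom}:{self.pos} "
                    f"cutoff {cutoff} outside [0, 1]"
                )
            if frac > prev + 1e-12:
                raise ModelError(
                    f"frac_over increases with cutoff at {self.chrom}:{self.pos}"
                )
            prev = frac

    def to_dict(self) -> dict[str, Any]:
        return {
            "chrom": self.chrom,
            "pos": self.pos,
            "mean_depth": self.mean_depth,
            "median_depth": self.median_depth,
            "frac_over": {str(k): v for k, v in sorted(self.frac_over.items())},
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CoverageRow":
        return cls(
            chrom=d["chrom"],
            pos=int(d["pos"]),
            mean_depth=float(d["mean_depth"]),
            median_depth=float(d["median_depth"]),
            frac_over={int(k): float(v) for k, v in d.get("frac_over", {}).items()},
        )


@dataclass
class CNVCall:
    """One copy-number call with its quality score and source sample."""

    chrom: str
    start: int
    end: int
    kind: str  # DEL | DUP
    sq_score: float
    population: str
    sample_id: str

    def validate(self) -> None:
        if self.kind not in ("DEL", "DUP"):
            raise ModelError(f"CNV kind must be DEL or DUP, got {self.kind!r}")
        if self.start >= self.end:
            raise ModelError("CNV requires start < end")
        if self.sq_score < 0:
            raise ModelError("CNV sq_score must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return {
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "kind": self.kind,
            "sq_score": self.sq_score,
            "population": self.population,
            "sample_id": self.sample_id,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CNVCall":
        return cls(
            chrom=d["chrom"],
            start=int(d["start"]),
            end=int(d["end"]),
            kind=d["kind"],
            sq_score=float(d["sq_score"]),
            population=d["population"],
            sample_id=d["sample_id"],
        )


@dataclass
class ReadVizSample:
    """A carrier sample considered for the read-support display."""

    sample_id: str
    genotype_class: str  # het | hom
    gq: int
    dp: int

    def validate(self) -> None:
        if self.genotype_class not in ("het", "hom"):
            raise ModelError("genotype_class must be het or hom")
        if self.gq < 0 or self.dp < 0:
            raise ModelError("gq and dp must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return {
            "sample_id": self.sample_id,
            "genotype_class": self.genotype_class,
            "gq": self.gq,
            "dp": self.dp,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ReadVizSample":
        return cls(
            sample_id=d["sample_id"],
            genotype_class=d["genotype_class"],
            gq=int(d["gq"]),
            dp=int(d["dp"]),
        )


@dataclass
class ReadVizManifest:
    """Selected carriers and display window backing one variant's read view."""

    variant_key: str
    selected: list[ReadVizSample]
    window: GenomeInterval
    parameters: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "variant_key": self.variant_key,
            "selected": [s.to_dict() for s in self.selected],
            "window": self.window.to_dict(),
            "parameters": dict(self.parameters),
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ReadVizManifest":
        return cls(
            variant_key=d["variant_key"],
            selected=[ReadVizSample.from_dict(s) for s in d["selected"]],
            window=GenomeInterval.from_dict(d["window"]),
            parameters=dict(d.get("parameters", {})),
        )


PAGE_KINDS = ("gene", "transcript", "variant", "region", "not_found")


@dataclass
class PagePayload:
    """Assembled, JSON-serializable content of one browser page."""

    page_kind: str
    metadata: dict[str, Any] = field(default_factory=dict)
    variant_table: list[dict[str, Any]] = field(default_factory=list)
    coverage_series: list[CoverageRow] = field(default_factory=list)
    cnv_summary: Optional[dict[str, Any]] = None
    warnings: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.page_kind not in PAGE_KINDS:
            raise ModelError(f"unknown page_kind {self.page_kind!r}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "page_kind": self.page_kind,
            "metadata": self.metadata,
            "variant_table": self.variant_table,
            "coverage_series": [r.to_dict() for r in self.coverage_series],
            "cnv_summary": self.cnv_summary,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        """Deterministic serialization (sorted keys, compact separators)."""
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PagePayload":
        return cls(
            page_kind=d["page_kind"],
            metadata=d.get("metadata", {}),
            variant_table=d.get("variant_table", []),
            coverage_series=[CoverageRow.from_dict(r) for r in d.get("coverage_series", [])],
            cnv_summary=d.get("cnv_summary"),
            warnings=list(d.get("warnings", [])),
        )

    @classmethod
    def from_json(cls, text: str) -> "PagePayload":
        return cls.from_dict(json.loads(text))
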