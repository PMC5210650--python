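"""Variant-level semantics: multi-allelic splitting, minimal representation,
consequence severity ranking, same-codon MNV candidate detection, low-AN flag.

Minimal representation trims shared flanking bases so that equivalent VCF
descriptions of one allele (padded, shifted by joint representation with
other alts) unify under a single ``chrom-pos-ref-alt`` key.

MNV candidacy is positional: two SNVs falling in the same codon of a
transcript can jointly alter one amino acid, so each is flagged and the pair
reported.  In a sites-only model there are no per-individual genotypes, so
an optional co-occurrence table can restrict pairs to those actually seen in
one individual.
"""

from __future__ import annotations

import logging
from importlib import resources
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .ingest import SiteRecord, parse_consequences
from .model import (
    DEFAULT_POPULATIONS,
    PopulationCounts,
    TranscriptConsequence,
    TranscriptModel,
    Variant,
)

logger = logging.getLogger(__name__)


class UnknownConsequenceError(KeyError):
    """A consequence term is absent from the severity table."""

    def __init__(self, term: str):
        super().__init__(term)
        self.term = term

    def __str__(self) -> str:
        return f"consequence term {self.term!r} is not in the severity table"


class SeverityTable:
    """Ordered ranking of Sequence Ontology consequence terms, worst first.

    The default order ships as a plain-text data file (one term per line)
    following the VEP convention, so it is inspectable and overridable.
    """

    def __init__(self, terms: Sequence[str]):
        if len(set(terms)) != len(terms):
            raise ValueError("severity table contains duplicate terms")
        self.terms: tuple[str, ...] = tuple(terms)
        self._rank = {t: i for i, t in enumerate(terms)}

    @classmethod
    def from_file(cls, path) -> "SeverityTable":
        with open(path) as fh:
            terms = [
                line.strip() for line in fh
                if line.strip() and not line.startswith("#")
            ]
        return cls(terms)

    @classmethod
    def default(cls) -> "SeverityTable":
        text = (
            resources.files("varbrowse").joinpath("data/severity_order.txt").read_text()
        )
        terms = [
            line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(terms)

    def __contains__(self, term: str) -> bool:
        return term in self._rank

    def __len__(self) -> int:
        return len(self.terms)

    def rank(self, term: str) -> int:
        """Severity index of a term (0 = most severe)."""
        try:
            return self._rank[term]
        except KeyError:
            raise UnknownConsequenceError(term) from None

    def worst(self, terms: Iterable[str]) -> str:
        """Most severe term of a non-empty collection."""
        terms = list(terms)
        if not terms:
            raise ValueError("cannot rank an empty set of consequence terms")
        return min(terms, key=self.rank)


def minimal_representation(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize (1-based pos, ref, alt) by trimming shared flanking bases.

    The rightmost shared suffix is trimmed while both alleles keep length
    > 1, then the shared prefix likewise, advancing ``pos`` one base per
    trimmed prefix base.  The result is idempotent and position-monotone.
    """
    if ref == alt:
        raise ValueError(f"ref and alt are identical ({ref!r}): not a variant")
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(variant: Variant) -> Variant:
    """Apply minimal representation to a Variant in place; returns it."""
    pos, ref, alt = minimal_representation(variant.pos, variant.ref, variant.alt)
    variant.pos, variant.ref, variant.alt = pos, ref, alt
    return variant


def split_multiallelic(
    record: SiteRecord,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> list[Variant]:
    """Split a raw site record into one Variant per alternate allele.

    Each output carries its own AC/Hom and the shared AN; all outputs of a
    site with more than one ALT are flagged ``multiallelic``.  Consequence
    entries are partitioned to their alt via the ``Allele`` sub-field when
    the annotation format declares one.  Spanning-deletion ``*`` alleles are
    dropped with a warning (AN is shared, so totals are unaffected).
    """
    if not record.alts:
        raise ValueError(f"site {record.chrom}:{record.pos} has no alt alleles")
    if len(record.ac) != len(record.alts) or len(record.hom) != len(record.alts):
        raise ValueError(
            f"site {record.chrom}:{record.pos}: per-alt AC/Hom list length "
            f"does not match alt count {len(record.alts)}"
        )
    is_multi = len(record.alts) > 1
    out: list[Variant] = []
    for i, alt in enumerate(record.alts):
        if alt == "*":
            logger.warning(
                "dropping spanning-deletion allele '*' at %s:%d",
                record.chrom, record.pos,
            )
            continue
        pop_counts = {}
        for p in populations:
            if p not in record.pop:
                continue
            raw = record.pop[p]
            pop_counts[p] = PopulationCounts(ac=raw.ac[i], an=raw.an, hom=raw.hom[i])
        consequences = parse_consequences(record, alt=alt)
        variant = Variant(
            chrom=record.chrom,
            pos=record.pos,
            ref=record.ref,
            alt=alt,
            rsid=record.rsid,
            site_quality=record.site_quality,
            filter_status=record.filter_status,
            ac_total=record.ac[i],
            an_total=record.an,
            hom_total=record.hom[i],
            pop_counts=pop_counts,
            quality_histograms=dict(record.histograms),
            flags={"multiallelic"} if is_multi else set(),
            consequences=consequences,
        )
        out.append(variant)
    return out


def worst_consequence(
    consequences: Sequence[TranscriptConsequence],
    table: SeverityTable,
) -> str:
    """Most severe term over all terms of all per-transcript annotations."""
    all_terms = [t for c in consequences for t in c.consequence_terms]
    if not all_terms:
        raise ValueError("no consequence terms to rank")
    return table.worst(all_terms)


def codon_index(
    transcript: TranscriptModel,
    genomic_pos: int,
) -> Optional[tuple[int, int]]:
    """Codon number and within-codon offset of a 1-based genomic position.

    Returns None outside the CDS.  The CDS offset counts coding bases
    strictly 5' of the position in transcript orientation; on the minus
    strand the walk starts from the highest genomic coordinate.
    """
    cds = transcript.cds_intervals()
    if not cds:
        return None
    pos0 = genomic_pos - 1
    hit = None
    for (s, e) in cds:
        if s <= pos0 < e:
            hit = (s, e)
            break
    if hit is None:
        return None
    if transcript.strand == "+":
        offset = sum(e - s for (s, e) in cds if e <= hit[0])
        offset += pos0 - hit[0]
    else:
        offset = sum(e - s for (s, e) in cds if s >= hit[1])
        offset += hit[1] - 1 - pos0
    return offset // 3, offset % 3


def detect_mnv_candidates(
    variants: Sequence[Variant],
    transcript: TranscriptModel,
    cooccurrence: Optional[set[frozenset[str]]] = None,
) -> list[tuple[str, str]]:
    """All unordered pairs of SNVs sharing a codon in this transcript.

    Each member of a pair gains the ``mnv_candidate`` flag.  Pairs are
    reported once, members ordered by ascending (pos, ref, alt).  When a
    co-occurrence set (frozensets of two variant keys observed in one
    individual) is supplied, pairs outside it are discarded.
    """
    by_codon: dict[int, list[Variant]] = {}
    for v in variants:
        if not v.is_snv:
            continue
        ci = codon_index(transcript, v.pos)
        if ci is None:
            continue
        by_codon.setdefault(ci[0], []).append(v)
    raw: list[tuple[tuple, str, str]] = []
    for codon in sorted(by_codon):
        members = sorted(by_codon[codon], key=lambda v: (v.pos, v.ref, v.alt))
        for a, b in combinations(members, 2):
            if cooccurrence is not None and frozenset((a.key, b.key)) not in cooccurrence:
                continue
            a.flags.add("mnv_candidate")
            b.flags.add("mnv_candidate")
            sort_key = (a.pos, a.ref, a.alt, b.pos, b.ref, b.alt)
            raw.append((sort_key, a.key, b.key))
    return [(k1, k2) for _, k1, k2 in sorted(set(raw))]


def flag_low_an(
    variant: Variant,
    an_max: int,
    threshold_fraction: float = 0.8,
) -> Variant:
    """Flag the variant ``low_an`` iff an_total < threshold_fraction * an_max.

    The comparison is strict, so a variant at exactly the threshold is not
    flagged.  ``an_max`` is the highest AN observed in the dataset.
    """
    if an_max <= 0:
        raise ValueError("an_max must be positive")
    if variant.an_total < threshold_fraction * an_max:
        variant.flags.add("low_an")
    else:
        variant.flags.discard("low_an")
    return variant
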