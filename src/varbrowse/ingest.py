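"""Readers for the browser's input formats.

Every reader converts external records into :mod:`varbrowse.model` types and
applies the package-wide conventions at the boundary:

* 1-based VCF/GTF coordinates become 0-based half-open internally (variant
  positions stay 1-based because the variant identity key uses the VCF
  convention);
* chromosome names are unified by stripping a leading ``chr`` prefix;
* the per-transcript consequence sub-field order is taken from the VCF
  header, never hard-coded.

The VCF and coverage readers are generators: memory use is independent of
file length.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gffutils
import pandas as pd
from cyvcf2 import VCF

from .model import (
    CNVCall,
    ConstraintRecord,
    CoverageRow,
    ExonFeature,
    GeneModel,
    MetricHistogram,
    TranscriptConsequence,
    TranscriptModel,
)

logger = logging.getLogger(__name__)

#: Default histogram bin edges for genotype quality and depth (20 bins over [0, 100]).
DEFAULT_HIST_EDGES = [float(x) for x in range(0, 105, 5)]


class IngestError(ValueError):
    """Raised when an input file violates its documented contract."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` so "1" and "chr1" unify."""
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


# ---------------------------------------------------------------------------
# Sites VCF
# ---------------------------------------------------------------------------

@dataclass
class PopulationSiteCounts:
    """Raw per-population counts at a site: shared AN, per-alt AC and Hom."""

    an: int
    ac: list[int]
    hom: list[int]


@dataclass
class SiteRecord:
    """One VCF line with all alternate alleles intact.

    Splitting into per-alt :class:`~varbrowse.model.Variant` records happens
    downstream in :func:`varbrowse.variants.split_multiallelic`.
    """

    chrom: str
    pos: int  # 1-based
    rsid: Optional[str]
    ref: str
    alts: list[str]
    site_quality: float
    filter_status: str
    an: int
    ac: list[int]
    hom: list[int]
    pop: dict[str, PopulationSiteCounts] = field(default_factory=dict)
    csq_entries: list[str] = field(default_factory=list)
    csq_format: list[str] = field(default_factory=list)
    histograms: dict[str, MetricHistogram] = field(default_factory=dict)


def _csq_format_from_header(vcf: VCF, csq_field_name: str) -> list[str]:
    try:
        header = vcf.get_header_type(csq_field_name)
    except KeyError:
        raise IngestError(
            f"consequence INFO field {csq_field_name!r} is missing from the VCF header"
        ) from None
    description = header.get("Description", "").strip('"')
    marker = "Format: "
    idx = description.find(marker)
    if idx < 0:
        raise IngestError(
            f"header of INFO field {csq_field_name!r} does not declare a "
            f"'Format: ...' sub-field order"
        )
    return description[idx + len(marker):].strip().strip('"').split("|")


def _as_int_list(value, n_alt: int, what: str, pos: int) -> list[int]:
    if value is None:
        return [0] * n_alt
    if isinstance(value, (int, float)):
        values = [int(value)]
    else:
        values = [int(v) for v in value]
    if len(values) != n_alt:
        raise IngestError(
            f"{what} at position {pos} has {len(values)} values for {n_alt} alt alleles"
        )
    return values


def _parse_hist_info(raw, metric_name: str, edges: list[float]) -> Optional[MetricHistogram]:
    if raw is None:
        return None
    counts = [int(c) for c in str(raw).split("|")]
    hist = MetricHistogram(metric_name=metric_name, bin_edges=list(edges), counts=counts)
    hist.validate()
    return hist


class SitesVcfReader:
    """Streaming reader over a sites VCF.

    Parameters
    ----------
    path:
        VCF file (plain or bgzip).
    csq_field_name:
        Name of the pipe-delimited per-transcript consequence INFO field.
    populations:
        Population codes whose ``AC_<pop>/AN_<pop>/Hom_<pop>`` INFO keys are
        collected when present.
    """

    HIST_FIELDS = {"GQ_HIST": "genotype_quality", "DP_HIST": "depth"}

    def __init__(
        self,
        path: str | Path,
        csq_field_name: str = "CSQ",
        populations: Iterable[str] = (),
        hist_edges: Optional[list[float]] = None,
    ) -> None:
        self.path = str(path)
        self.csq_field_name = csq_field_name
        self.populations = tuple(populations)
        self.hist_edges = list(hist_edges) if hist_edges else list(DEFAULT_HIST_EDGES)
        vcf = VCF(self.path)
        try:
            self.csq_format = _csq_format_from_header(vcf, csq_field_name)
        finally:
            vcf.close()

    def __iter__(self) -> Iterator[SiteRecord]:
        vcf = VCF(self.path)
        try:
            for line_no, rec in enumerate(vcf, start=1):
                try:
                    yield self._convert(rec)
                except IngestError:
                    raise
                except Exception as exc:  # pragma: no cover - defensive
                    raise IngestError(
                        f"malformed VCF data line {line_no} "
                        f"({rec.CHROM}:{rec.POS}): {exc}"
                    ) from exc
        finally:
            vcf.close()

    def _convert(self, rec) -> SiteRecord:
        n_alt = len(rec.ALT)
        pos = rec.POS
        ac = _as_int_list(rec.INFO.get("AC"), n_alt, "AC", pos)
        hom = _as_int_list(rec.INFO.get("Hom"), n_alt, "Hom", pos)
        an = int(rec.INFO.get("AN") or 0)
        pops: dict[str, PopulationSiteCounts] = {}
        for p in self.populations:
            if rec.INFO.get(f"AN_{p}") is None:
                continue
            pops[p] = PopulationSiteCounts(
                an=int(rec.INFO.get(f"AN_{p}") or 0),
                ac=_as_int_list(rec.INFO.get(f"AC_{p}"), n_alt, f"AC_{p}", pos),
                hom=_as_int_list(rec.INFO.get(f"Hom_{p}"), n_alt, f"Hom_{p}", pos),
            )
        histograms: dict[str, MetricHistogram] = {}
        for info_key, metric in self.HIST_FIELDS.items():
            hist = _parse_hist_info(rec.INFO.get(info_key), metric, self.hist_edges)
            if hist is not None:
                histograms[metric] = hist
        csq_raw = rec.INFO.get(self.csq_field_name)
        csq_entries = str(csq_raw).split(",") if csq_raw else []
        filt = rec.FILTER or "PASS"
        return SiteRecord(
            chrom=normalize_chrom(rec.CHROM),
            pos=pos,
            rsid=rec.ID or None,
            ref=rec.REF,
            alts=list(rec.ALT),
            site_quality=float(rec.QUAL or 0.0),
            filter_status=filt,
            an=an,
            ac=ac,
            hom=hom,
            pop=pops,
            csq_entries=csq_entries,
            csq_format=self.csq_format,
            histograms=histograms,
        )


def read_sites_vcf(
    path: str | Path,
    csq_field_name: str = "CSQ",
    populations: Iterable[str] = (),
) -> SitesVcfReader:
    """Open a sites VCF; returns an iterable reader with ``csq_format`` captured."""
    return SitesVcfReader(path, csq_field_name=csq_field_name, populations=populations)


def _parse_prediction(raw: str) -> Optional[tuple[str, float]]:
    # VEP writes e.g. "probably_damaging(0.98)"
    raw = raw.strip()
    if not raw:
        return None
    if raw.endswith(")") and "(" in raw:
        label, score = raw[:-1].rsplit("(", 1)
        try:
            return (label, float(score))
        except ValueError:
            return (raw, float("nan"))
    return (raw, float("nan"))


def parse_consequences(
    record: SiteRecord,
    csq_format: Optional[list[str]] = None,
    alt: Optional[str] = None,
) -> list[TranscriptConsequence]:
    """Parse the VEP-style consequence entries of one site.

    When the sub-field order includes ``Allele`` and ``alt`` is given, entries
    whose allele sub-field does not match ``alt`` are excluded, partitioning
    annotations between the alternate alleles of a multi-allelic site.
    Entries with fewer sub-fields than the declared format are rejected with a
    log message and parsing continues.
    """
    fmt = csq_format if csq_format is not None else record.csq_format
    if not fmt:
        raise IngestError("consequence sub-field order (csq_format) is empty")
    index = {name: i for i, name in enumerate(fmt)}
    for required in ("Consequence", "Gene", "Feature"):
        if required not in index:
            raise IngestError(f"csq_format lacks required sub-field {required!r}")
    out: list[TranscriptConsequence] = []
    for entry in record.csq_entries:
        if not entry:
            continue
        parts = entry.split("|")
        if len(parts) < len(fmt):
            logger.warning(
                "rejecting consequence entry with %d sub-fields (expected %d) at %s:%d",
                len(parts), len(fmt), record.chrom, record.pos,
            )
            continue
        if alt is not None and "Allele" in index and parts[index["Allele"]] != alt:
            continue
        terms = [t for t in parts[index["Consequence"]].split("&") if t]
        if not terms:
            continue

        def _get(name: str) -> str:
            return parts[index[name]] if name in index else ""

        cons = TranscriptConsequence(
            transcript_id=_get("Feature"),
            gene_id=_get("Gene"),
            consequence_terms=terms,
            polyphen=_parse_prediction(_get("PolyPhen")),
            sift=_parse_prediction(_get("SIFT")),
            lof=_get("LoF") or None,
            is_canonical=_get("CANONICAL") == "YES",
        )
        out.append(cons)
    return out


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------

def _attr(feature, name: str) -> Optional[str]:
    values = feature.attributes.get(name)
    return values[0] if values else None


def read_gene_models(
    path: str | Path,
    alias_path: Optional[str | Path] = None,
) -> tuple[dict[str, GeneModel], dict[str, TranscriptModel]]:
    """Read Gencode-dialect GTF gene models.

    GTF 1-based inclusive coordinates become 0-based half-open.  The canonical
    transcript of each gene is the one with the longest CDS, ties broken by
    lexicographically smallest transcript id (an explicit tag in the VCF
    consequence field, when present, is honored separately at annotation
    time).  Aliases are attached from ``alias_path`` (TSV: symbol, alias).
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    transcripts: dict[str, TranscriptModel] = {}
    gene_meta: dict[str, dict] = {}
    gene_transcripts: dict[str, list[str]] = {}

    for f in db.features_of_type("gene"):
        gid = _attr(f, "gene_id")
        if gid is None:
            raise IngestError("gene feature without gene_id attribute")
        gene_meta[gid] = {
            "symbol": _attr(f, "gene_name") or gid,
            "chrom": normalize_chrom(f.seqid),
            "start": f.start - 1,
            "end": f.end,
            "strand": f.strand,
        }
        gene_transcripts.setdefault(gid, [])

    for f in db.features_of_type("transcript"):
        tid = _attr(f, "transcript_id")
        gid = _attr(f, "gene_id")
        if tid is None or gid is None:
            raise IngestError("transcript feature lacks transcript_id/gene_id")
        if gid not in gene_meta:
            raise IngestError(f"transcript {tid} references unknown gene {gid}")
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            chrom=normalize_chrom(f.seqid),
            strand=f.strand,
            exons=[],
        )
        gene_transcripts[gid].append(tid)

    for kind in ("exon", "CDS", "UTR"):
        for f in db.features_of_type(kind):
            tid = _attr(f, "transcript_id")
            if tid is None or tid not in transcripts:
                raise IngestError(
                    f"{kind} feature references unknown transcript {tid!r}"
                )
            transcripts[tid].exons.append(
                ExonFeature(start=f.start - 1, end=f.end, kind=kind)
            )

    for t in transcripts.values():
        t.exons.sort(key=lambda e: (e.start, e.end, e.kind))
        t.validate()

    aliases: dict[str, list[str]] = {}
    if alias_path is not None:
        with open(alias_path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                aliases.setdefault(row[0], []).append(row[1])

    genes: dict[str, GeneModel] = {}
    for gid, meta in gene_meta.items():
        tids = sorted(gene_transcripts[gid])
        if not tids:
            raise IngestError(f"gene {gid} has no transcripts")
        # longest CDS wins; lexicographic tie-break is given by the sort above
        canonical = max(tids, key=lambda tid: (transcripts[tid].cds_length, ), default=tids[0])
        best_len = transcripts[canonical].cds_length
        canonical = min(t for t in tids if transcripts[t].cds_length == best_len)
        genes[gid] = GeneModel(
            gene_id=gid,
            symbol=meta["symbol"],
            chrom=meta["chrom"],
            start=meta["start"],
            end=meta["end"],
            strand=meta["strand"],
            canonical_transcript_id=canonical,
            transcript_ids=tids,
            aliases=sorted(aliases.get(meta["symbol"], [])),
        )
        genes[gid].validate()
    return genes, transcripts


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def read_coverage(path: str | Path) -> Iterator[CoverageRow]:
    """Stream per-base coverage rows from a (possibly gzipped) TSV.

    Header: ``#chrom  pos  mean  median  <cutoff> ...`` — the depth-cutoff
    set is parsed from the header columns.  Fractions outside [0, 1] are
    fatal, reported with their position.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        header = fh.readline()
        if not header:
            return
        cols = header.lstrip("#").split()
        if len(cols) < 4 or cols[1] != "pos":
            raise IngestError(
                f"unexpected coverage header {header.strip()!r}; "
                "expected '#chrom pos mean median <cutoffs...>'"
            )
        cutoffs = [int(c) for c in cols[4:]]
        for line in fh:
            if not line.strip():
                continue
            parts = line.split()
            chrom = normalize_chrom(parts[0])
            pos = int(parts[1])
            fracs = {}
            for cutoff, raw in zip(cutoffs, parts[4:]):
                frac = float(raw)
                if not (0.0 <= frac <= 1.0):
                    raise IngestError(
                        f"coverage fraction {frac} outside [0, 1] at {chrom}:{pos}"
                    )
                fracs[cutoff] = frac
            row = CoverageRow(
                chrom=chrom,
                pos=pos,
                mean_depth=float(parts[2]),
                median_depth=float(parts[3]),
                frac_over=fracs,
            )
            yield row


# ---------------------------------------------------------------------------
# Side tables: constraint, CNV calls, dbSNP
# ---------------------------------------------------------------------------

CONSTRAINT_COLUMNS = [
    "transcript_id", "exp_syn", "obs_syn", "syn_z", "exp_mis", "obs_mis",
    "mis_z", "exp_lof", "obs_lof", "lof_z", "pli",
]
CNV_COLUMNS = ["chrom", "start", "end", "kind", "sq", "population", "sample_id"]
DBSNP_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt"]


def read_constraint(path: str | Path) -> dict[str, ConstraintRecord]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise IngestError(f"cannot parse constraint table {path}: {exc}") from exc
    missing = set(CONSTRAINT_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"constraint table lacks columns: {sorted(missing)}")
    out: dict[str, ConstraintRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = ConstraintRecord(
                transcript_id=str(row.transcript_id),
                exp_syn=float(row.exp_syn), obs_syn=int(row.obs_syn), syn_z=float(row.syn_z),
                exp_mis=float(row.exp_mis), obs_mis=int(row.obs_mis), mis_z=float(row.mis_z),
                exp_lof=float(row.exp_lof), obs_lof=int(row.obs_lof), lof_z=float(row.lof_z),
                pli=float(row.pli),
            )
        except (TypeError, ValueError) as exc:
            raise IngestError(f"constraint table row {i}: unparsable field ({exc})") from None
        rec.validate()
        out[rec.transcript_id] = rec
    return out


def read_cnv_calls(path: str | Path) -> list[CNVCall]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return []
    except Exception as exc:
        raise IngestError(f"cannot parse CNV table {path}: {exc}") from exc
    missing = set(CNV_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"CNV table lacks columns: {sorted(missing)}")
    calls: list[CNVCall] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            call = CNVCall(
                chrom=normalize_chrom(str(row.chrom)),
                start=int(row.start), end=int(row.end), kind=str(row.kind),
                sq_score=float(row.sq), population=str(row.population),
                sample_id=str(row.sample_id),
            )
        except (TypeError, ValueError) as exc:
            raise IngestError(f"CNV table row {i}: unparsable field ({exc})") from None
        call.validate()
        calls.append(call)
    return calls


def read_dbsnp(path: str | Path) -> dict[str, list[tuple[str, int, str, str]]]:
    """rsid -> list of (chrom, pos, ref, alt); duplicate rows last-wins with a warning."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return {}
    except Exception as exc:
        raise IngestError(f"cannot parse dbSNP table {path}: {exc}") from exc
    missing = set(DBSNP_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"dbSNP table lacks columns: {sorted(missing)}")
    out: dict[str, dict[tuple, tuple]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entry = (normalize_chrom(str(row.chrom)), int(row.pos), str(row.ref), str(row.alt))
        except (TypeError, ValueError) as exc:
            raise IngestError(f"dbSNP table row {i}: unparsable field ({exc})") from None
        rsid = str(row.rsid)
        slot = out.setdefault(rsid, {})
        if entry in slot:
            logger.warning("duplicate dbSNP row for %s at line %d; last wins", rsid, i)
        slot[entry] = entry
    return {rsid: sorted(entries) for rsid, entries in out.items()}


def read_side_tables(
    constraint_path: Optional[str | Path],
    cnv_path: Optional[str | Path],
    dbsnp_path: Optional[str | Path],
) -> tuple[dict[str, ConstraintRecord], list[CNVCall], dict[str, list[tuple[str, int, str, str]]]]:
    """Read the constraint, CNV and dbSNP side tables (any may be None)."""
    constraint = read_constraint(constraint_path) if constraint_path else {}
    cnvs = read_cnv_calls(cnv_path) if cnv_path else []
    dbsnp = read_dbsnp(dbsnp_path) if dbsnp_path else {}
    return constraint, cnvs, dbsnp


def read_carriers(path: str | Path) -> dict[str, list]:
    """Read a read-viz carrier table (TSV: variant_key, sample_id, genotype_class, gq, dp)."""
    from .model import ReadVizSample

    out: dict[str, list] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            sample = ReadVizSample(
                sample_id=row["sample_id"],
                genotype_class=row["genotype_class"],
                gq=int(row["gq"]),
                dp=int(row["dp"]),
            )
            sample.validate()
            out.setdefault(row["variant_key"], []).append(sample)
    return out
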