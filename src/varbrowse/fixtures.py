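"""Seeded synthetic-data generator.

``generate`` writes a complete, mutually consistent input bundle — GTF gene
models, sites VCF with per-population counts and VEP-style consequence
strings, per-base coverage TSV, constraint TSV, CNV call TSV, dbSNP TSV,
gene-alias TSV and a read-viz carrier table — plus a ``truth.json`` with
the expected downstream answers (variant counts, worst consequences,
same-codon SNV pairs, exon CNV counts, read-viz selections).

The generator aims at structural consistency, not population-genetic
realism: allele counts are drawn so per-population AC sums exactly to the
total AC, every bundle contains negative-strand genes so codon arithmetic
is exercised on both strands, multi-allelic sites and indels are always
present, and CNV qualities straddle the confidence threshold.  All ground
truth is computed with naive, implementation-independent procedures (e.g. a
per-base codon walk) so it can serve as an oracle for the pipeline.
"""

from __future__ import annotations

import json
import math
import random
from pathlib import Path
from typing import Any, Optional, Sequence

from .model import DEFAULT_POPULATIONS
from .variants import SeverityTable

BASES = "ACGT"

CSQ_FORMAT = ["Allele", "Consequence", "Gene", "Feature", "CANONICAL",
              "PolyPhen", "SIFT", "LoF"]

COVERAGE_CUTOFFS = [1, 5, 10, 15, 20, 25, 30, 50, 100]

SNV_TERM_CHOICES = [
    ["missense_variant"],
    ["synonymous_variant"],
    ["stop_gained"],
    ["missense_variant", "splice_region_variant"],
    ["synonymous_variant", "splice_region_variant"],
]
DEL_TERM_CHOICES = [["frameshift_variant"], ["inframe_deletion"]]
INS_TERM_CHOICES = [["frameshift_variant"], ["inframe_insertion"]]

_HIST_NBINS = 20
_HIST_STEP = 5

#: Carriers needed to exercise the read-viz selection cap and filters.
_N_HET_RANGE = (6, 10)
_N_HOM_RANGE = (0, 4)


def _hist_counts(values: Sequence[int]) -> list[int]:
    # independent binning: 20 bins of width 5 over [0, 100], last bin closed
    counts = [0] * _HIST_NBINS
    for v in values:
        if v < 0:
            continue
        counts[min(v // _HIST_STEP, _HIST_NBINS - 1)] += 1
    return counts


def _oriented_cds_bases(cds: list[tuple[int, int]], strand: str) -> list[int]:
    bases = [p for (s, e) in sorted(cds) for p in range(s, e)]
    if strand == "-":
        bases.reverse()
    return bases


def _codon_of(cds: list[tuple[int, int]], strand: str, pos0: int) -> Optional[int]:
    """Naive per-base codon walk (0-based genomic position -> codon number)."""
    bases = _oriented_cds_bases(cds, strand)
    try:
        return bases.index(pos0) // 3
    except ValueError:
        return None


def _draw_pop_counts(
    rng: random.Random,
    populations: Sequence[str],
    an_by_pop: dict[str, int],
    ac_total: int,
) -> dict[str, dict[str, int]]:
    """Distribute ac_total over populations so the per-pop sum is exact."""
    ac = {p: 0 for p in populations}
    pops = list(populations)
    for _ in range(ac_total):
        eligible = [p for p in pops if ac[p] < an_by_pop[p]]
        ac[rng.choice(eligible)] += 1
    out = {}
    for p in populations:
        hom = rng.randint(0, ac[p] // 2)
        out[p] = {"ac": ac[p], "an": an_by_pop[p], "hom": hom}
    return out


class _Gene:
    def __init__(self, g: int, n_genes: int):
        self.gene_id = f"ENSGFX{g:05d}"
        self.symbol = f"GN{g}"
        self.chrom = str(1 + (g % 2))
        self.strand = "+" if (g // 2) % 2 == 0 else "-"
        o = 100_000 + g * 50_000
        self.origin = o
        tid_a = f"ENSTFX{g:05d}A"
        tid_b = f"ENSTFX{g:05d}B"
        self.canonical = tid_a
        self.transcripts = {
            tid_a: {
                "exon": [(o, o + 150), (o + 300, o + 450), (o + 600, o + 690)],
                "CDS": [(o + 60, o + 150), (o + 300, o + 450), (o + 600, o + 660)],
                "UTR": [(o, o + 60), (o + 660, o + 690)],
            },
            tid_b: {
                "exon": [(o, o + 150), (o + 300, o + 420)],
                "CDS": [(o + 60, o + 150), (o + 300, o + 399)],
                "UTR": [(o, o + 60)],
            },
        }
        self.start = o
        self.end = o + 690

    def span_contains(self, tid: str, pos0: int) -> bool:
        feats = self.transcripts[tid]["exon"]
        return feats[0][0] <= pos0 < feats[-1][1]


def generate(
    seed: int,
    out_dir: str | Path,
    n_genes: int = 4,
    variants_per_gene: int = 15,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
) -> dict[str, Any]:
    """Write the full synthetic bundle into ``out_dir``; returns the truth dict.

    ``variants_per_gene`` counts alternate alleles (one multi-allelic site
    contributes two).  Requires ``variants_per_gene >= 7`` so each gene can
    contain the deliberate same-codon SNV pair, a multi-allelic site and two
    indels.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if variants_per_gene < 7:
        raise ValueError("variants_per_gene must be >= 7")
    rng = random.Random(seed)
    severity = SeverityTable.default()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pops = list(populations)

    genes = [_Gene(g, n_genes) for g in range(n_genes)]

    truth: dict[str, Any] = {
        "seed": seed,
        "populations": pops,
        "genes": {},
        "variants": {},
        "mnv_pairs": {},
        "readviz": {},
        "rsids": {},
    }

    gtf_lines: list[str] = []
    vcf_sites: list[dict[str, Any]] = []
    coverage_rows: list[tuple[str, int, float, float, list[float]]] = []
    constraint_rows: list[str] = []
    cnv_rows: list[str] = []
    dbsnp_rows: list[str] = []
    alias_rows: list[str] = []
    carrier_rows: list[str] = []

    forced_sq_boundary_emitted = False
    rs_counter = 100_000

    for gi, gene in enumerate(genes):
        o = gene.origin
        # ---- GTF ----------------------------------------------------------
        attrs = f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}";'
        gtf_lines.append(
            f"{gene.chrom}\tfixture\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
            f"{gene.strand}\t.\t{attrs}"
        )
        for tid in sorted(gene.transcripts):
            feats = gene.transcripts[tid]
            t_start = feats["exon"][0][0]
            t_end = feats["exon"][-1][1]
            tattrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{tid}"; '
                f'gene_name "{gene.symbol}";'
            )
            gtf_lines.append(
                f"{gene.chrom}\tfixture\ttranscript\t{t_start + 1}\t{t_end}\t.\t"
                f"{gene.strand}\t.\t{tattrs}"
            )
            for kind in ("exon", "CDS", "UTR"):
                for (s, e) in feats[kind]:
                    gtf_lines.append(
                        f"{gene.chrom}\tfixture\t{kind}\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{tattrs}"
                    )

        # ---- aliases ------------------------------------------------------
        alias_rows.append(f"{gene.symbol}\t{gene.symbol}X")
        alias_rows.append(f"{gene.symbol}\tALIAS{gi}")
        if gi == 1:
            # deliberate symbol/alias collision: gene 1 gains gene 0's symbol
            # as an alias, so exact-symbol resolution must win over alias
            alias_rows.append(f"{gene.symbol}\t{genes[0].symbol}")

        # ---- constraint ---------------------------------------------------
        canon_feats = gene.transcripts[gene.canonical]
        constraint_rows.append("\t".join(str(x) for x in [
            gene.canonical,
            round(rng.uniform(5, 40), 2), rng.randint(0, 45), round(rng.uniform(-3, 3), 2),
            round(rng.uniform(10, 80), 2), rng.randint(0, 90), round(rng.uniform(-3, 3), 2),
            round(rng.uniform(1, 20), 2), rng.randint(0, 25), round(rng.uniform(-3, 6), 2),
            round(rng.uniform(0, 1), 4),
        ]))

        # ---- variant sites ------------------------------------------------
        cds = canon_feats["CDS"]
        oriented = _oriented_cds_bases(cds, gene.strand)
        pair_codon = rng.randint(35, 65)
        pair_pos = sorted((oriented[3 * pair_codon], oriented[3 * pair_codon + 2]))
        pool = sorted(set(oriented) - set(pair_pos))
        n_extra_snv = variants_per_gene - 6  # pair(2) + multi(2) + indels(2)
        n_positions = 1 + 2 + n_extra_snv  # multi site + 2 indel sites + SNVs
        positions = sorted(rng.sample(pool, n_positions))
        rng.shuffle(positions)
        multi_pos = positions[0]
        indel_pos = positions[1:3]
        snv_pos = sorted(positions[3:])
        low_an_pos = snv_pos[0] if snv_pos else multi_pos

        site_specs: list[dict[str, Any]] = []
        for p0 in sorted(pair_pos):
            ref = rng.choice(BASES)
            alt = rng.choice([b for b in BASES if b != ref])
            site_specs.append({"pos0": p0, "ref": ref, "alts": [alt], "kind": "snv"})
        ref = rng.choice(BASES)
        alt_pair = rng.sample([b for b in BASES if b != ref], 2)
        site_specs.append({"pos0": multi_pos, "ref": ref, "alts": sorted(alt_pair),
                           "kind": "snv"})
        for j, p0 in enumerate(indel_pos):
            anchor = rng.choice(BASES)
            if j == 0:  # deletion: ref two bases, alt the anchor
                second = rng.choice([b for b in BASES if b != anchor])
                site_specs.append({"pos0": p0, "ref": anchor + second,
                                   "alts": [anchor], "kind": "del"})
            else:  # insertion
                inserted = rng.choice(BASES)
                site_specs.append({"pos0": p0, "ref": anchor,
                                   "alts": [anchor + inserted], "kind": "ins"})
        for p0 in snv_pos:
            ref = rng.choice(BASES)
            alt = rng.choice([b for b in BASES if b != ref])
            site_specs.append({"pos0": p0, "ref": ref, "alts": [alt], "kind": "snv"})
        site_specs.sort(key=lambda s: s["pos0"])

        gene_variant_keys: list[str] = []
        for spec in site_specs:
            pos1 = spec["pos0"] + 1
            low_an = spec["pos0"] == low_an_pos
            an_by_pop = {
                p: rng.randint(250, 350) if low_an else rng.randint(900, 1100)
                for p in pops
            }
            an_total = sum(an_by_pop.values())
            alts_payload = []
            site_gq_values: list[int] = []
            site_dp_values: list[int] = []
            for alt in spec["alts"]:
                key = f"{gene.chrom}-{pos1}-{spec['ref']}-{alt}"
                gene_variant_keys.append(key)
                ac_total = rng.randint(1, 40)
                pop_counts = _draw_pop_counts(rng, pops, an_by_pop, ac_total)
                hom_total = sum(c["hom"] for c in pop_counts.values())
                # consequence entries per overlapping transcript
                entries = []
                all_terms: list[str] = []
                for tid in sorted(gene.transcripts):
                    if not gene.span_contains(tid, spec["pos0"]):
                        continue
                    if spec["kind"] == "snv":
                        terms = list(rng.choice(SNV_TERM_CHOICES))
                    elif spec["kind"] == "del":
                        terms = list(rng.choice(DEL_TERM_CHOICES))
                    else:
                        terms = list(rng.choice(INS_TERM_CHOICES))
                    all_terms.extend(terms)
                    polyphen = sift = ""
                    if "missense_variant" in terms:
                        polyphen = f"probably_damaging({round(rng.uniform(0.5, 1.0), 3)})"
                        sift = f"deleterious({round(rng.uniform(0.0, 0.05), 3)})"
                    lof = "HC" if {"stop_gained", "frameshift_variant"} & set(terms) else ""
                    canonical = "YES" if tid == gene.canonical else ""
                    entries.append("|".join([
                        alt, "&".join(terms), gene.gene_id, tid, canonical,
                        polyphen, sift, lof,
                    ]))
                # carriers for the read-viz display
                n_het = rng.randint(*_N_HET_RANGE)
                n_hom = rng.randint(*_N_HOM_RANGE)
                selected_truth = {"het": [], "hom": []}
                qualifying: dict[str, list[tuple[int, str]]] = {"het": [], "hom": []}
                for cls, count in (("het", n_het), ("hom", n_hom)):
                    for j in range(count):
                        sid = f"S{cls.upper()}{j:03d}"
                        gq = rng.randint(0, 100)
                        dp = rng.randint(1, 40)
                        carrier_rows.append(f"{key}\t{sid}\t{cls}\t{gq}\t{dp}")
                        site_gq_values.append(gq)
                        site_dp_values.append(dp)
                        if dp >= 10 and gq >= 20:
                            qualifying[cls].append((gq, sid))
                for cls in ("het", "hom"):
                    ordered = sorted(qualifying[cls], key=lambda t: (-t[0], t[1]))
                    selected_truth[cls] = [sid for _, sid in ordered[:5]]
                truth["readviz"][key] = selected_truth
                truth["variants"][key] = {
                    "gene": gene.gene_id,
                    "worst_consequence": min(all_terms, key=severity.rank),
                    "multiallelic": len(spec["alts"]) > 1,
                    "an_total": an_total,
                    "ac_total": ac_total,
                    "hom_total": hom_total,
                }
                alts_payload.append({
                    "alt": alt, "ac": ac_total, "hom": hom_total,
                    "pop": pop_counts, "csq": entries,
                })
            filter_status = "PASS" if rng.random() > 0.08 else "RF"
            vcf_sites.append({
                "chrom": gene.chrom, "pos": pos1, "ref": spec["ref"],
                "alts": alts_payload, "an": an_total, "an_by_pop": an_by_pop,
                "qual": round(rng.uniform(50, 5000), 2),
                "filter": filter_status,
                "gq_hist": _hist_counts(site_gq_values),
                "dp_hist": _hist_counts(site_dp_values),
                "id": ".",
            })

        # ---- rsids (first two genes get one each) -------------------------
        if gi < 2:
            rs_counter += 1
            rsid = f"rs{rs_counter}"
            first_key = sorted(gene_variant_keys)[0]
            chrom, pos_s, ref_s, alt_s = first_key.split("-")
            dbsnp_rows.append(f"{rsid}\t{chrom}\t{pos_s}\t{ref_s}\t{alt_s}")
            truth["rsids"][rsid] = first_key

        # ---- coverage -----------------------------------------------------
        exon_union: set[int] = set()
        for tid in gene.transcripts:
            for (s, e) in gene.transcripts[tid]["exon"]:
                exon_union.update(range(s, e))
        for pos0 in sorted(exon_union):
            if rng.random() < 0.1:
                continue  # coverage gap
            mean = round(rng.uniform(15, 60), 1)
            median = round(max(0.0, mean + rng.uniform(-3, 3)), 1)
            fracs = [round(math.exp(-c / mean), 4) for c in COVERAGE_CUTOFFS]
            coverage_rows.append((gene.chrom, pos0 + 1, mean, median, fracs))

        # ---- CNV calls ----------------------------------------------------
        canon_exons = sorted(canon_feats["exon"])
        gene_cnvs: list[tuple[int, int, str, float]] = []
        for ci in range(6):
            start = o + rng.randint(-200, 500)
            end = start + rng.randint(50, 400)
            kind = rng.choice(["DEL", "DUP"])
            if ci == 0:
                sq = round(rng.uniform(40, 59), 1)
            elif ci == 1:
                sq = round(rng.uniform(61, 85), 1)
            elif not forced_sq_boundary_emitted:
                sq, forced_sq_boundary_emitted = 60.0, True
            else:
                sq = round(rng.uniform(40, 85), 1)
            pop = rng.choice(pops)
            sample = f"CN{gi:02d}{ci}"
            cnv_rows.append(
                f"{gene.chrom}\t{start}\t{end}\t{kind}\t{sq}\t{pop}\t{sample}"
            )
            gene_cnvs.append((start, end, kind, sq))

        # brute-force exon CNV counts (strict SQ > 60, any overlap counts)
        exon_counts = {"DEL": [0] * len(canon_exons), "DUP": [0] * len(canon_exons)}
        for (cs, ce, kind, sq) in gene_cnvs:
            if not (sq > 60.0):
                continue
            for xi, (es, ee) in enumerate(canon_exons):
                if cs < ee and es < ce:
                    exon_counts[kind][xi] += 1

        truth["genes"][gene.gene_id] = {
            "symbol": gene.symbol,
            "chrom": gene.chrom,
            "strand": gene.strand,
            "canonical_transcript_id": gene.canonical,
            "variant_count": len(gene_variant_keys),
            "exon_cnv_counts": exon_counts,
        }

    # ---- low-AN truth (needs the dataset-wide AN maximum) ------------------
    an_max = max(v["an_total"] for v in truth["variants"].values())
    truth["an_max"] = an_max
    for key, v in truth["variants"].items():
        v["low_an"] = v["an_total"] < 0.8 * an_max

    # ---- MNV truth: naive codon walk over every transcript -----------------
    for gene in genes:
        for tid in sorted(gene.transcripts):
            cds = gene.transcripts[tid]["CDS"]
            snvs = []
            for key, v in truth["variants"].items():
                if v["gene"] != gene.gene_id:
                    continue
                chrom, pos_s, ref_s, alt_s = key.split("-")
                if len(ref_s) != 1 or len(alt_s) != 1:
                    continue
                if not gene.span_contains(tid, int(pos_s) - 1):
                    continue  # no annotation against this transcript
                codon = _codon_of(cds, gene.strand, int(pos_s) - 1)
                if codon is not None:
                    snvs.append((codon, int(pos_s), ref_s, alt_s, key))
            pairs = []
            snvs.sort(key=lambda t: (t[1], t[2], t[3]))
            for i in range(len(snvs)):
                for j in range(i + 1, len(snvs)):
                    if snvs[i][0] == snvs[j][0]:
                        pairs.append(sorted(
                            [snvs[i][4], snvs[j][4]],
                            key=lambda k: (
                                int(k.split("-")[1]), k.split("-")[2], k.split("-")[3]
                            ),
                        ))
            if pairs:
                truth["mnv_pairs"][tid] = sorted(
                    pairs,
                    key=lambda p: (int(p[0].split("-")[1]), p[0], p[1]),
                )

    _write_bundle(
        out, pops, gtf_lines, vcf_sites, coverage_rows, constraint_rows,
        cnv_rows, dbsnp_rows, alias_rows, carrier_rows, truth,
    )
    return truth


def _write_bundle(out, pops, gtf_lines, vcf_sites, coverage_rows,
                  constraint_rows, cnv_rows, dbsnp_rows, alias_rows,
                  carrier_rows, truth) -> None:
    (out / "genes.gtf").write_text("\n".join(gtf_lines) + "\n")

    header = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">',
        '##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">',
        '##INFO=<ID=Hom,Number=A,Type=Integer,Description="Homozygote count">',
    ]
    for p in pops:
        header += [
            f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="Allele count ({p})">',
            f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="Allele number ({p})">',
            f'##INFO=<ID=Hom_{p},Number=A,Type=Integer,Description="Homozygote count ({p})">',
        ]
    header += [
        '##INFO=<ID=GQ_HIST,Number=1,Type=String,Description="Genotype quality histogram, 20 bins of width 5 over [0,100]">',
        '##INFO=<ID=DP_HIST,Number=1,Type=String,Description="Depth histogram, 20 bins of width 5 over [0,100]">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: '
        + "|".join(CSQ_FORMAT) + '">',
        '##FILTER=<ID=RF,Description="Failed random-forest site filter">',
        "##contig=<ID=1>",
        "##contig=<ID=2>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = list(header)
    for site in sorted(vcf_sites, key=lambda s: (s["chrom"], s["pos"])):
        alts = ",".join(a["alt"] for a in site["alts"])
        info = [
            "AC=" + ",".join(str(a["ac"]) for a in site["alts"]),
            f"AN={site['an']}",
            "Hom=" + ",".join(str(a["hom"]) for a in site["alts"]),
        ]
        for p in pops:
            info.append(f"AC_{p}=" + ",".join(str(a["pop"][p]["ac"]) for a in site["alts"]))
            info.append(f"AN_{p}={site['an_by_pop'][p]}")
            info.append(f"Hom_{p}=" + ",".join(str(a["pop"][p]["hom"]) for a in site["alts"]))
        info.append("GQ_HIST=" + "|".join(str(c) for c in site["gq_hist"]))
        info.append("DP_HIST=" + "|".join(str(c) for c in site["dp_hist"]))
        info.append("CSQ=" + ",".join(e for a in site["alts"] for e in a["csq"]))
        lines.append("\t".join([
            site["chrom"], str(site["pos"]), site["id"], site["ref"], alts,
            str(site["qual"]), site["filter"], ";".join(info),
        ]))
    (out / "sites.vcf").write_text("\n".join(lines) + "\n")

    cov_lines = ["#chrom\tpos\tmean\tmedian\t" + "\t".join(str(c) for c in COVERAGE_CUTOFFS)]
    for (chrom, pos, mean, median, fracs) in sorted(coverage_rows, key=lambda r: (r[0], r[1])):
        cov_lines.append(
            f"{chrom}\t{pos}\t{mean}\t{median}\t" + "\t".join(f"{f}" for f in fracs)
        )
    (out / "coverage.tsv").write_text("\n".join(cov_lines) + "\n")

    (out / "constraint.tsv").write_text(
        "transcript_id\texp_syn\tobs_syn\tsyn_z\texp_mis\tobs_mis\tmis_z\t"
        "exp_lof\tobs_lof\tlof_z\tpli\n" + "\n".join(constraint_rows) + "\n"
    )
    (out / "cnv.tsv").write_text(
        "chrom\tstart\tend\tkind\tsq\tpopulation\tsample_id\n"
        + "\n".join(cnv_rows) + "\n"
    )
    (out / "dbsnp.tsv").write_text(
        "rsid\tchrom\tpos\tref\talt\n"
        + ("\n".join(dbsnp_rows) + "\n" if dbsnp_rows else "")
    )
    (out / "aliases.tsv").write_text("\n".join(alias_rows) + "\n")
    (out / "carriers.tsv").write_text(
        "variant_key\tsample_id\tgenotype_class\tgq\tdp\n"
        + "\n".join(carrier_rows) + "\n"
    )
    (out / "truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )


def bundle_paths(out_dir: str | Path) -> dict[str, Path]:
    """Canonical file locations of a generated bundle."""
    out = Path(out_dir)
    return {
        "gtf": out / "genes.gtf",
        "vcf": out / "sites.vcf",
        "coverage": out / "coverage.tsv",
        "constraint": out / "constraint.tsv",
        "cnv": out / "cnv.tsv",
        "dbsnp": out / "dbsnp.tsv",
        "aliases": out / "aliases.tsv",
        "carriers": out / "carriers.tsv",
        "truth": out / "truth.json",
    }
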