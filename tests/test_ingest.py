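"""Input-format readers: VCF, GTF, coverage and side tables."""

import textwrap

import pytest

from varbrowse import ingest
from varbrowse.ingest import IngestError


VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
    ##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
    ##INFO=<ID=Hom,Number=A,Type=Integer,Description="Homozygote count">
    ##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations from Ensembl VEP. Format: Allele|Consequence|Gene|Feature|CANONICAL|PolyPhen|SIFT|LoF">
    ##contig=<ID=1>
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
    """)


def _write_vcf(tmp_path, body_lines):
    path = tmp_path / "test.vcf"
    path.write_text(VCF_HEADER + "".join(line + "\n" for line in body_lines))
    return path


def test_csq_format_read_from_header_and_multi_alt_kept_intact(tmp_path):
    path = _write_vcf(tmp_path, [
        "1\t1000\trs1\tA\tC,G\t500\tPASS\t"
        "AC=5,2;AN=1000;Hom=1,0;CSQ="
        "C|missense_variant&splice_region_variant|ENSG01|ENST01|YES|probably_damaging(0.98)|deleterious(0.01)|,"
        "G|synonymous_variant|ENSG01|ENST01|YES|||",
    ])
    reader = ingest.read_sites_vcf(path)
    assert reader.csq_format == [
        "Allele", "Consequence", "Gene", "Feature", "CANONICAL",
        "PolyPhen", "SIFT", "LoF",
    ]
    records = list(reader)
    assert len(records) == 1
    rec = records[0]
    assert rec.alts == ["C", "G"]
    assert rec.ac == [5, 2]
    assert rec.an == 1000
    assert rec.rsid == "rs1"

    cons = ingest.parse_consequences(rec, alt="C")
    assert len(cons) == 1
    assert cons[0].consequence_terms == ["missense_variant", "splice_region_variant"]
    assert cons[0].is_canonical
    assert cons[0].polyphen == ("probably_damaging", 0.98)
    assert cons[0].sift == ("deleterious", 0.01)
    assert cons[0].lof is None


def test_empty_vcf_yields_empty_stream_with_header_parsed(tmp_path):
    reader = ingest.read_sites_vcf(_write_vcf(tmp_path, []))
    assert reader.csq_format[0] == "Allele"
    assert list(reader) == []


def test_missing_csq_header_is_fatal_and_names_the_key(tmp_path):
    path = tmp_path / "nocsq.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##INFO=<ID=AC,Number=A,Type=Integer,Description="x">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
    )
    with pytest.raises(IngestError, match="CSQ"):
        ingest.read_sites_vcf(path)


def test_fixture_vcf_streams_one_record_per_data_line(bundle_files):
    with open(bundle_files["vcf"]) as fh:
        expected = sum(1 for line in fh if not line.startswith("#"))
    records = list(ingest.read_sites_vcf(bundle_files["vcf"]))
    assert len(records) == expected
    # re-reading yields identical structures
    again = list(ingest.read_sites_vcf(bundle_files["vcf"]))
    assert [(r.chrom, r.pos, r.ref, tuple(r.alts), tuple(r.ac)) for r in records] == \
           [(r.chrom, r.pos, r.ref, tuple(r.alts), tuple(r.ac)) for r in again]


def test_short_consequence_entry_rejected_but_parsing_continues(tmp_path, caplog):
    import logging
    path = _write_vcf(tmp_path, [
        "1\t2000\t.\tA\tG\t10\tPASS\tAC=1;AN=10;Hom=0;CSQ="
        "G|missense_variant|ENSG01,"  # truncated entry
        "G|synonymous_variant|ENSG01|ENST02||||",
    ])
    rec = next(iter(ingest.read_sites_vcf(path)))
    with caplog.at_level(logging.WARNING):
        cons = ingest.parse_consequences(rec, alt="G")
    assert [c.consequence_terms for c in cons] == [["synonymous_variant"]]
    assert any("rejecting" in r.message for r in caplog.records)


def test_allele_subfield_partitions_entries_between_alts(tmp_path):
    path = _write_vcf(tmp_path, [
        "1\t3000\t.\tA\tC,T\t10\tPASS\tAC=1,1;AN=10;Hom=0,0;CSQ="
        "C|missense_variant|G1|T1||||,T|stop_gained|G1|T1||||",
    ])
    rec = next(iter(ingest.read_sites_vcf(path)))
    for alt, term in (("C", "missense_variant"), ("T", "stop_gained")):
        cons = ingest.parse_consequences(rec, alt=alt)
        assert [c.consequence_terms for c in cons] == [[term]]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

GTF = textwrap.dedent("""\
    chr1\tt\tgene\t101\t700\t.\t+\t.\tgene_id "G1"; gene_name "ALPHA";
    chr1\tt\ttranscript\t101\t700\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
    chr1\tt\tCDS\t101\t200\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
    chr1\tt\ttranscript\t101\t700\t.\t+\t.\tgene_id "G1"; transcript_id "T0";
    chr1\tt\texon\t101\t300\t.\t+\t.\tgene_id "G1"; transcript_id "T0";
    chr1\tt\tCDS\t101\t200\t.\t+\t0\tgene_id "G1"; transcript_id "T0";
    """)


def test_gtf_coordinates_become_zero_based_half_open(tmp_path):
    path = tmp_path / "g.gtf"
    path.write_text(GTF)
    genes, transcripts = ingest.read_gene_models(path)
    assert transcripts["T1"].exon_intervals() == [(100, 200)]
    assert genes["G1"].chrom == "1"  # chr prefix stripped
    assert genes["G1"].start == 100 and genes["G1"].end == 700


def test_canonical_resolution_ties_break_lexicographically(tmp_path):
    # T0 and T1 have identical CDS length; T0 wins the tie in either file order
    path = tmp_path / "g.gtf"
    path.write_text(GTF)
    genes, _ = ingest.read_gene_models(path)
    assert genes["G1"].canonical_transcript_id == "T0"
    swapped = "\n".join(reversed(GTF.strip().split("\n"))) + "\n"
    path2 = tmp_path / "g2.gtf"
    path2.write_text(swapped)
    genes2, _ = ingest.read_gene_models(path2)
    assert genes2["G1"].canonical_transcript_id == "T0"


def test_minus_strand_exons_stored_in_genomic_order(bundle_files, truth):
    genes, transcripts = ingest.read_gene_models(bundle_files["gtf"])
    minus = [g for g in genes.values() if g.strand == "-"]
    assert minus, "bundle must contain negative-strand genes"
    for g in minus:
        for tid in g.transcript_ids:
            ivs = transcripts[tid].exon_intervals()
            assert ivs == sorted(ivs)


def test_exon_referencing_unknown_transcript_is_fatal(tmp_path):
    path = tmp_path / "bad.gtf"
    path.write_text(
        'chr1\tt\tgene\t101\t700\t.\t+\t.\tgene_id "G1";\n'
        'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "TX";\n'
    )
    with pytest.raises(IngestError, match="TX"):
        ingest.read_gene_models(path)


def test_aliases_attached_from_alias_table(bundle_files, built_store):
    for gene in built_store.genes.values():
        assert f"{gene.symbol}X" in gene.aliases


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def test_coverage_header_declares_cutoffs(tmp_path):
    path = tmp_path / "cov.tsv"
    path.write_text(
        "#chrom\tpos\tmean\tmedian\t1\t5\t10\n"
        "1\t1000\t34.2\t33\t1.0\t0.99\t0.97\n"
    )
    rows = list(ingest.read_coverage(path))
    assert len(rows) == 1
    assert rows[0].frac_over == {1: 1.0, 5: 0.99, 10: 0.97}
    assert rows[0].mean_depth == 34.2


def test_coverage_fraction_out_of_range_is_fatal_with_position(tmp_path):
    path = tmp_path / "cov.tsv"
    path.write_text("#chrom\tpos\tmean\tmedian\t10\n1\t555\t30\t30\t1.2\n")
    with pytest.raises(IngestError, match="555"):
        list(ingest.read_coverage(path))


def test_coverage_streams_every_line(bundle_files):
    with open(bundle_files["coverage"]) as fh:
        expected = sum(1 for line in fh if not line.startswith("#"))
    assert sum(1 for _ in ingest.read_coverage(bundle_files["coverage"])) == expected


def test_gzipped_coverage_detected_by_extension(tmp_path):
    import gzip
    path = tmp_path / "cov.tsv.gz"
    with gzip.open(path, "wt") as fh:
        fh.write("#chrom\tpos\tmean\tmedian\t10\n1\t7\t30\t30\t0.5\n")
    rows = list(ingest.read_coverage(path))
    assert rows[0].pos == 7


# ---------------------------------------------------------------------------
# side tables
# ---------------------------------------------------------------------------

def test_constraint_rows_keyed_by_transcript(bundle_files, truth):
    constraint = ingest.read_constraint(bundle_files["constraint"])
    for gid, g in truth["genes"].items():
        rec = constraint[g["canonical_transcript_id"]]
        assert 0.0 <= rec.pli <= 1.0


def test_empty_cnv_file_yields_empty_list(tmp_path):
    path = tmp_path / "cnv.tsv"
    path.write_text("chrom\tstart\tend\tkind\tsq\tpopulation\tsample_id\n")
    assert ingest.read_cnv_calls(path) == []


def test_unparsable_constraint_field_is_fatal_with_row(tmp_path):
    path = tmp_path / "c.tsv"
    path.write_text(
        "transcript_id\texp_syn\tobs_syn\tsyn_z\texp_mis\tobs_mis\tmis_z\t"
        "exp_lof\tobs_lof\tlof_z\tpli\n"
        "T1\tten\t4\t-2.1\t1\t1\t0\t1\t1\t0\t0.5\n"
    )
    with pytest.raises(IngestError, match="row 2"):
        ingest.read_constraint(path)


def test_dbsnp_duplicate_rows_last_wins_with_warning(tmp_path, caplog):
    import logging
    path = tmp_path / "db.tsv"
    path.write_text(
        "rsid\tchrom\tpos\tref\talt\n"
        "rs1\t1\t100\tA\tG\n"
        "rs1\t1\t100\tA\tG\n"
    )
    with caplog.at_level(logging.WARNING):
        db = ingest.read_dbsnp(path)
    assert db["rs1"] == [("1", 100, "A", "G")]
    assert any("duplicate" in r.message for r in caplog.records)
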