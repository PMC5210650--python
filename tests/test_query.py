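"""Search resolution, page assembly, region limits and CSV export."""

import csv
import io
import random

import pytest

from varbrowse import query
from varbrowse.model import GenomeInterval, ModelError
from varbrowse.variants import worst_consequence


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------

def test_rsid_query_resolves_to_variant(built_store, truth):
    for rsid, key in truth["rsids"].items():
        result = query.resolve_search(rsid, built_store)
        assert result.kind == "variant"
        assert result.target == key


def test_symbol_query_resolves_to_gene_case_insensitively(built_store, truth):
    for gid, g in truth["genes"].items():
        assert query.resolve_search(g["symbol"].lower(), built_store).target == gid


def test_exact_symbol_wins_over_alias_collision(built_store, truth):
    # the bundle gives gene 1 an alias equal to gene 0's symbol
    gids = sorted(truth["genes"])
    symbol0 = truth["genes"][gids[0]]["symbol"]
    result = query.resolve_search(symbol0, built_store)
    assert result.kind == "gene"
    assert result.target == gids[0]
    # but the alias is still reachable when it does not collide
    assert query.resolve_search(f"{symbol0}X", built_store).target == gids[0]


def test_variant_key_and_region_query_forms(built_store, truth):
    key = sorted(truth["variants"])[0]
    assert query.resolve_search(key, built_store).kind == "variant"
    chrom, pos = key.split("-")[0], key.split("-")[1]
    r = query.resolve_search(f"{chrom}:100000-101000", built_store)
    assert r.kind == "region"


def test_ensembl_identifiers_resolve(built_store, truth):
    gid = sorted(truth["genes"])[0]
    tid = truth["genes"][gid]["canonical_transcript_id"]
    assert query.resolve_search(gid, built_store).kind == "gene"
    assert query.resolve_search(tid, built_store).kind == "transcript"


def test_unknown_query_is_not_found_with_suggestions(built_store):
    result = query.resolve_search("GNX_UNKNOWN", built_store)
    assert result.kind == "not_found"
    assert result.target == ""


def test_autocomplete_ranks_symbols_before_aliases(built_store, truth):
    symbols = sorted(g["symbol"] for g in truth["genes"].values())
    got = query.autocomplete("GN", built_store)
    assert got[:len(symbols)] == symbols
    assert all(s in got for s in symbols)
    assert query.autocomplete("ZZZ", built_store) == []
    assert query.autocomplete("GN", built_store, limit=1) == [symbols[0]]


# ---------------------------------------------------------------------------
# pages
# ---------------------------------------------------------------------------

def test_gene_page_reproduces_truth_counts_and_worst_consequences(built_store, truth):
    for gid, g in truth["genes"].items():
        payload = query.gene_page(gid, built_store)
        assert payload.page_kind == "gene"
        assert len(payload.variant_table) == g["variant_count"]
        positions = [row["pos"] for row in payload.variant_table]
        assert positions == sorted(positions)
        for row in payload.variant_table:
            expected = truth["variants"][row["variant_key"]]["worst_consequence"]
            assert row["consequence"] == expected
            v = built_store.variant_by_key(row["variant_key"])
            assert row["consequence"] == worst_consequence(
                v.consequences, built_store.severity
            )


def test_gene_page_constraint_and_metadata_present(built_store, truth):
    gid = sorted(truth["genes"])[0]
    payload = query.gene_page(gid, built_store)
    assert payload.metadata["gene"]["constraint"] is not None
    assert 0.0 <= payload.metadata["gene"]["constraint"]["pli"] <= 1.0
    assert payload.metadata["coverage_summary"], "canonical exon coverage expected"


def test_unknown_gene_yields_not_found_payload(built_store):
    payload = query.gene_page("ENSG_NOPE", built_store)
    assert payload.page_kind == "not_found"


def test_transcript_page_filters_to_its_own_annotations(built_store, truth):
    gid = sorted(truth["genes"])[0]
    g = truth["genes"][gid]
    canonical = g["canonical_transcript_id"]
    other = canonical[:-1] + "B"
    gene_keys = {r["variant_key"] for r in query.gene_page(gid, built_store).variant_table}
    t_payload = query.transcript_page(canonical, built_store)
    t_keys = {r["variant_key"] for r in t_payload.variant_table}
    assert t_keys <= gene_keys
    for row in t_payload.variant_table:
        v = built_store.variant_by_key(row["variant_key"])
        assert any(c.transcript_id == canonical for c in v.consequences)
    # a variant annotated only against transcript B is absent from A's page
    b_only = {
        v.key for v in built_store.variants.values()
        if truth["variants"][v.key]["gene"] == gid
        and {c.transcript_id for c in v.consequences} == {other}
    }
    assert b_only.isdisjoint(t_keys)
    # coverage intervals equal this transcript's exons
    t = built_store.transcript_by_id(canonical)
    assert [(e["start"], e["end"]) for e in t_payload.metadata["coverage_summary"]] == \
        t.exon_intervals()


def test_variant_page_population_table_and_groups(built_store, truth):
    key = sorted(truth["variants"])[0]
    payload = query.variant_page(key, built_store)
    assert payload.page_kind == "variant"
    assert len(payload.metadata["population_table"]) == 8
    groups = payload.metadata["consequence_groups"]
    n_annotations = sum(len(g["annotations"]) for g in groups)
    v = built_store.variant_by_key(key)
    assert n_annotations == len(v.consequences)
    # transcripts sharing one annotation collapse into one group
    terms = [g["consequence"] for g in groups]
    assert len(terms) == len(set(terms))


def test_absent_variant_shows_regional_coverage(built_store):
    payload = query.variant_page("1-100200-A-C", built_store)
    assert payload.page_kind == "not_found"
    assert payload.coverage_series, "coverage context must be shown"


def test_malformed_variant_key_names_expected_format(built_store):
    with pytest.raises(ModelError, match="chrom-pos-ref-alt"):
        query.variant_page("oops", built_store)


def test_region_limit_boundary_exact(built_store):
    served = query.region_page("1", 1, 100_001, built_store)  # span 100000
    assert served.metadata["rejected"] is False
    rejected = query.region_page("1", 1, 100_002, built_store)  # span 100001
    assert rejected.metadata["rejected"] is True
    assert "100000" in rejected.warnings[0]
    with pytest.raises(ValueError, match="inverted"):
        query.region_page("1", 10, 5, built_store)


def test_region_variants_equal_brute_force_scan(built_store):
    rng = random.Random(23)
    for _ in range(20):
        start = rng.randint(95_000, 300_000)
        stop = start + rng.randint(100, 90_000)
        payload = query.region_page("1", start, stop, built_store)
        expected = built_store.variants_in(GenomeInterval("1", start - 1, stop))
        assert [r["variant_key"] for r in payload.variant_table] == \
            [v.key for v in expected]


def test_gene_without_variants_still_shows_coverage(bundle_files, built_store):
    # region of gene 0 with the variants filtered out by span choice:
    # use a sub-exon window with no variant but coverage present
    gene = next(iter(built_store.genes.values()))
    window_start = gene.start + 1  # 5' UTR region: no variants generated there
    payload = query.region_page(gene.chrom, window_start, window_start + 30, built_store)
    assert payload.coverage_series


# ---------------------------------------------------------------------------
# CSV export
# ---------------------------------------------------------------------------

def test_csv_export_row_count_and_round_trip(built_store, truth):
    gid = sorted(truth["genes"])[0]
    payload = query.gene_page(gid, built_store)
    text = query.export_variant_table_csv(
        payload, populations=built_store.config.populations
    )
    lines = text.strip().split("\r\n")
    assert len(lines) == len(payload.variant_table) + 1
    parsed = list(csv.DictReader(io.StringIO(text)))
    for row, original in zip(parsed, payload.variant_table):
        assert row["chrom"] == original["chrom"]
        assert int(row["pos"]) == original["pos"]
        assert row["ref"] == original["ref"]
        assert row["alt"] == original["alt"]
        assert row["consequence"] == original["consequence"]
        assert int(row["ac"]) == original["ac"]
        assert int(row["an"]) == original["an"]
        assert int(row["hom"]) == original["hom"]
        assert row["af"] == query.format_af(original["af"])
        for pop in built_store.config.populations:
            assert int(row[f"ac_{pop}"]) == original["populations"][pop]["ac"]


def test_csv_export_empty_table_is_header_only(built_store):
    from varbrowse.model import PagePayload
    text = query.export_variant_table_csv(PagePayload(page_kind="gene"))
    assert text.strip().count("\r\n") == 0
    assert text.startswith("chrom,pos,rsid")


def test_af_formatting_six_significant_digits_scientific_below_1e4():
    assert query.format_af(0.00333333333) == "0.00333333"
    assert query.format_af(0.5) == "0.5"
    assert query.format_af(3e-05) == "3e-05"
    assert query.format_af(0.000123456789) == "0.000123457"


def test_payloads_stable_across_repeated_calls(built_store, truth):
    gid = sorted(truth["genes"])[0]
    assert query.gene_page(gid, built_store).to_json() == \
        query.gene_page(gid, built_store).to_json()
    key = sorted(truth["variants"])[0]
    assert query.variant_page(key, built_store).to_json() == \
        query.variant_page(key, built_store).to_json()
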