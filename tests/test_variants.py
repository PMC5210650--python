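"""Normalization, severity ranking, codon arithmetic and MNV detection."""

import random
from itertools import combinations

import pytest
from hypothesis import given, strategies as st

from varbrowse.ingest import SiteRecord, PopulationSiteCounts
from varbrowse.model import ExonFeature, TranscriptModel, Variant
from varbrowse.variants import (
    SeverityTable,
    UnknownConsequenceError,
    codon_index,
    detect_mnv_candidates,
    flag_low_an,
    minimal_representation,
    split_multiallelic,
    worst_consequence,
)
from varbrowse.model import TranscriptConsequence

# ---------------------------------------------------------------------------
# minimal representation
# ---------------------------------------------------------------------------

def naive_walk_codon(cds, strand, pos1):
    """Per-base walk oracle: codon/offset of a 1-based position, or None."""
    bases = [p for (s, e) in sorted(cds) for p in range(s, e)]
    if strand == "-":
        bases.reverse()
    pos0 = pos1 - 1
    if pos0 not in bases:
        return None
    i = bases.index(pos0)
    return i // 3, i % 3


def random_minimal_variant(rng):
    """A minimal (pos, ref, alt) whose fixed point is padding-invariant:
    SNVs or anchored indels whose trailing bases differ between alleles."""
    pos = rng.randint(1, 10**6)
    kind = rng.choice(["snv", "del", "ins"])
    bases = "ACGT"
    if kind == "snv":
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
        return pos, ref, alt
    anchor = rng.choice(bases)
    tail = "".join(rng.choice(bases) for _ in range(rng.randint(1, 3)))
    while tail[-1] == anchor:
        tail = tail[:-1] + rng.choice([b for b in bases if b != anchor])
    long_allele = anchor + tail
    if kind == "del":
        return pos, long_allele, anchor
    return pos, anchor, long_allele


@pytest.mark.parametrize("given_form, expected", [
    ((1001, "CTCC", "CCC"), (1001, "CT", "C")),
    ((500, "A", "G"), (500, "A", "G")),
    # suffix trim fires once; prefix trim is blocked by the both-lengths>1 rule
    ((100, "TAA", "TA"), (100, "TA", "T")),
    ((1000, "GCACA", "GCA"), (1000, "GCA", "G")),
])
def test_minimal_representation_examples(given_form, expected):
    assert minimal_representation(*given_form) == expected


def test_minimal_representation_rejects_non_variant():
    with pytest.raises(ValueError, match="identical"):
        minimal_representation(10, "ACG", "ACG")


def test_padded_forms_reach_a_unique_fixed_point():
    """All prefix/suffix paddings (length <= 3) of 500 random minimal
    variants normalize back to the same (pos, ref, alt)."""
    rng = random.Random(20_240_901)
    pads = [""] + ["".join(p) for n in (1, 2, 3)
                   for p in __import__("itertools").product("ACGT", repeat=n)]
    for _ in range(500):
        pos, ref, alt = random_minimal_variant(rng)
        assert minimal_representation(pos, ref, alt) == (pos, ref, alt)
        prefix = rng.choice(pads)
        for suffix in rng.sample(pads, 8):
            padded = (pos - len(prefix), prefix + ref + suffix, prefix + alt + suffix)
            assert minimal_representation(*padded) == (pos, ref, alt)


@given(
    st.integers(min_value=1, max_value=10**6),
    st.text(alphabet="ACGT", min_size=1, max_size=6),
    st.text(alphabet="ACGT", min_size=1, max_size=6),
)
def test_minimal_representation_idempotent_and_monotone(pos, ref, alt):
    if ref == alt:
        alt = alt + "C"
    out = minimal_representation(pos, ref, alt)
    assert minimal_representation(*out) == out
    assert out[0] >= pos


# ---------------------------------------------------------------------------
# severity / worst consequence
# ---------------------------------------------------------------------------

def _cons(*term_groups):
    return [
        TranscriptConsequence(
            transcript_id=f"T{i}", gene_id="G", consequence_terms=list(terms)
        )
        for i, terms in enumerate(term_groups)
    ]


def test_worst_consequence_prefers_most_severe_term():
    table = SeverityTable.default()
    cons = _cons(["synonymous_variant"], ["missense_variant"], ["stop_gained"])
    assert worst_consequence(cons, table) == "stop_gained"
    assert worst_consequence(_cons(["intron_variant"]), table) == "intron_variant"


def test_worst_consequence_unknown_term_is_named():
    table = SeverityTable.default()
    with pytest.raises(UnknownConsequenceError, match="made_up_term"):
        worst_consequence(_cons(["made_up_term"]), table)


def test_worst_consequence_matches_brute_force_and_is_order_invariant():
    table = SeverityTable.default()
    rng = random.Random(11)
    pool = list(table.terms)
    for _ in range(100):
        groups = [
            rng.sample(pool, rng.randint(1, 3))
            for _ in range(rng.randint(1, 5))
        ]
        cons = _cons(*groups)
        expected_rank = min(table.rank(t) for g in groups for t in g)
        got = worst_consequence(cons, table)
        assert table.rank(got) == expected_rank
        shuffled = cons[:]
        rng.shuffle(shuffled)
        assert worst_consequence(shuffled, table) == got


def test_severity_table_rejects_duplicates():
    with pytest.raises(ValueError):
        SeverityTable(["a", "b", "a"])


# ---------------------------------------------------------------------------
# codon arithmetic
# ---------------------------------------------------------------------------

def _transcript(strand, cds_intervals, tid="T1"):
    feats = [ExonFeature(s, e, "CDS") for s, e in cds_intervals]
    feats += [ExonFeature(s, e, "exon") for s, e in cds_intervals]
    return TranscriptModel(
        transcript_id=tid, gene_id="G1", chrom="1", strand=strand, exons=feats
    )


def test_codon_index_plus_strand_single_cds():
    t = _transcript("+", [(100, 130)])
    assert codon_index(t, 104) == (1, 0)  # 3 coding bases 5' of it
    assert codon_index(t, 101) == (0, 0)
    assert codon_index(t, 130) == (9, 2)
    assert codon_index(t, 131) is None  # past the CDS


def test_codon_index_minus_strand_counts_from_high_coordinate():
    t = _transcript("-", [(100, 200)])
    assert codon_index(t, 200) == (0, 0)
    assert codon_index(t, 198) == (0, 2)
    assert codon_index(t, 101) == (33, 0)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_codon_index_matches_naive_walk_across_split_cds(strand):
    cds = [(100, 130), (150, 171), (300, 312)]
    t = _transcript(strand, cds)
    for pos1 in range(95, 320):
        assert codon_index(t, pos1) == naive_walk_codon(cds, strand, pos1), pos1


def test_codon_index_outside_cds_is_none():
    t = TranscriptModel(
        transcript_id="T1", gene_id="G1", chrom="1", strand="+",
        exons=[ExonFeature(100, 200, "exon"), ExonFeature(120, 180, "CDS"),
               ExonFeature(100, 120, "UTR")],
    )
    assert codon_index(t, 110) is None  # UTR


# ---------------------------------------------------------------------------
# MNV candidates
# ---------------------------------------------------------------------------

def _snv(pos, ref="A", alt="G", chrom="1"):
    return Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, ac_total=1, an_total=10)


def test_same_codon_snvs_pair_and_gain_flag():
    t = _transcript("+", [(100, 130)])
    a, b = _snv(101), _snv(103, ref="C", alt="T")
    pairs = detect_mnv_candidates([a, b], t)
    assert pairs == [(a.key, b.key)]
    assert "mnv_candidate" in a.flags and "mnv_candidate" in b.flags


def test_adjacent_snvs_straddling_codon_boundary_do_not_pair():
    t = _transcript("+", [(100, 130)])
    a, b = _snv(103), _snv(104, ref="C", alt="T")  # offsets 2 and 0
    assert detect_mnv_candidates([a, b], t) == []
    assert "mnv_candidate" not in a.flags


def test_n_snvs_in_one_codon_give_all_pairs():
    t = _transcript("+", [(100, 130)])
    vs = [_snv(101, alt=a) for a in "CGT"]
    pairs = detect_mnv_candidates(vs, t)
    assert len(pairs) == 3  # C(3,2)


def test_mnv_detection_symmetric_and_equals_brute_force():
    rng = random.Random(5)
    for strand in ("+", "-"):
        cds = [(1000, 1060), (1100, 1141)]
        t = _transcript(strand, cds)
        for _ in range(50):
            vs = []
            for pos in rng.sample(range(995, 1150), rng.randint(2, 12)):
                ref = rng.choice("ACGT")
                alt = rng.choice([b for b in "ACGT" if b != ref])
                if rng.random() < 0.1:
                    ref, alt = ref + "T", ref  # non-SNV: must be ignored
                vs.append(_snv(pos, ref=ref, alt=alt))
            got = detect_mnv_candidates(vs, t)
            expected = set()
            for a, b in combinations(vs, 2):
                if not (a.is_snv and b.is_snv):
                    continue
                ca = naive_walk_codon(cds, strand, a.pos)
                cb = naive_walk_codon(cds, strand, b.pos)
                if ca is not None and cb is not None and ca[0] == cb[0]:
                    first, second = sorted([a, b], key=lambda v: (v.pos, v.ref, v.alt))
                    expected.add((first.key, second.key))
            assert set(got) == expected
            shuffled = vs[:]
            rng.shuffle(shuffled)
            assert detect_mnv_candidates(shuffled, t) == got


def test_mnv_cooccurrence_table_restricts_pairs():
    t = _transcript("+", [(100, 130)])
    a, b, c = _snv(101), _snv(102, ref="C", alt="T"), _snv(103, ref="G", alt="C")
    allowed = {frozenset((a.key, b.key))}
    pairs = detect_mnv_candidates([a, b, c], t, cooccurrence=allowed)
    assert pairs == [(a.key, b.key)]


# ---------------------------------------------------------------------------
# multi-allelic splitting and low-AN flag
# ---------------------------------------------------------------------------

def _record(alts, ac, hom, csq_entries=(), an=1000):
    return SiteRecord(
        chrom="1", pos=500, rsid=None, ref="A", alts=list(alts),
        site_quality=99.0, filter_status="PASS", an=an, ac=list(ac),
        hom=list(hom),
        pop={"NFE": PopulationSiteCounts(an=an, ac=list(ac), hom=list(hom))},
        csq_entries=list(csq_entries),
        csq_format=["Allele", "Consequence", "Gene", "Feature", "CANONICAL",
                    "PolyPhen", "SIFT", "LoF"],
    )


def test_single_alt_site_is_not_flagged_multiallelic():
    out = split_multiallelic(_record(["G"], [5], [1]))
    assert len(out) == 1
    assert out[0].flags == set()
    assert out[0].ac_total == 5


def test_three_alt_site_splits_with_per_alt_counts_all_flagged():
    out = split_multiallelic(_record(["G", "C", "T"], [5, 2, 1], [2, 0, 0]))
    assert [v.ac_total for v in out] == [5, 2, 1]
    assert all("multiallelic" in v.flags for v in out)
    assert all(v.an_total == 1000 for v in out)


def test_star_allele_dropped_with_shared_an_unchanged(caplog):
    import logging
    with caplog.at_level(logging.WARNING):
        out = split_multiallelic(_record(["G", "*"], [5, 3], [0, 0]))
    assert [v.alt for v in out] == ["G"]
    assert out[0].an_total == 1000
    assert "multiallelic" in out[0].flags  # the site had two ALT entries
    assert any("*" in rec.message for rec in caplog.records)


def test_split_partitions_consequences_by_allele():
    entries = [
        "G|missense_variant|ENSG1|ENST1|YES|||",
        "C|stop_gained|ENSG1|ENST1|YES|||",
        "G|intron_variant|ENSG1|ENST2||||",
    ]
    out = split_multiallelic(_record(["G", "C"], [5, 2], [0, 0], entries))
    by_alt = {v.alt: v for v in out}
    assert {c.consequence_terms[0] for c in by_alt["G"].consequences} == {
        "missense_variant", "intron_variant"
    }
    assert [c.consequence_terms for c in by_alt["C"].consequences] == [["stop_gained"]]


def test_split_rejects_mismatched_ac_length():
    with pytest.raises(ValueError, match="length"):
        split_multiallelic(_record(["G", "C"], [5], [0]))


@pytest.mark.parametrize("an_total, expect_flag", [
    (1000, False),          # equals an_max
    (500, True),            # half of max
    (800, False),           # exactly the 0.8 boundary: strict <, unflagged
    (799, True),
])
def test_low_an_flag_boundary(an_total, expect_flag):
    v = Variant(chrom="1", pos=1, ref="A", alt="G", ac_total=0, an_total=an_total)
    flag_low_an(v, an_max=1000)
    assert ("low_an" in v.flags) is expect_flag
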