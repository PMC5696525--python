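import numpy as np
import pytest
from hypothesis import given, strategies as st

from kstab.digestion import (
    CleavageRule,
    builtin_rules,
    digest,
    digestibility_table,
    find_cut_sites,
    load_rules,
    normalized_site_count,
    save_rules,
)
from kstab.sequence_io import SubunitRecord, theoretical_mass

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_text = st.text(alphabet=AA, min_size=1, max_size=60)

WATER = 18.0153


# ---------------------------------------------------------------- rule tables

def test_trypsin_rule_definition():
    rule = builtin_rules()["trypsin"]
    assert rule.p1_residues == frozenset("KR")
    assert rule.p1prime_blockers == frozenset("P")


def test_unknown_protease_and_dialect():
    with pytest.raises(KeyError):
        builtin_rules()["unknownase"]
    with pytest.raises(KeyError):
        builtin_rules("webtoolx")


@pytest.mark.parametrize("dialect", ["peptidecutter", "msdigest"])
def test_rules_yaml_round_trip(tmp_path, dialect):
    rules = builtin_rules(dialect)
    p = tmp_path / "rules.yaml"
    save_rules(rules, p)
    assert load_rules(p) == rules


def test_empty_p1_set_rejected():
    with pytest.raises(ValueError):
        CleavageRule("null", frozenset())


# ------------------------------------------------------------------ cut sites

TRYPSIN = builtin_rules()["trypsin"]


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AKAA", [1]),        # single K
        ("AKPA", []),         # proline block
        ("AWKPA", [2]),       # Keil exception: WKP cleaves despite proline
        ("AMRPA", [2]),       # Keil exception: MRP cleaves despite proline
        ("ACKDA", []),        # Keil veto: CKD
        ("ARRRA", [1, 3]),    # RRR vetoes the middle R; flanking Rs cleave
        ("AAAK", []),         # C-terminal residue never a site
    ],
)
def test_trypsin_sites(seq, expected):
    assert find_cut_sites(seq, TRYPSIN) == expected


def _oracle_trypsin_sites(seq):
    """Independent literal-rule scan for PeptideCutter-style trypsin."""
    allow = {("W", "K", "P"), ("M", "R", "P")}
    veto = {("C", "K", "D"), ("D", "K", "D"), ("C", "K", "H"),
            ("C", "K", "Y"), ("K", "K", "R"), ("C", "R", "K"),
            ("R", "R", "H"), ("R", "R", "R")}
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] not in "KR":
            continue
        p2 = seq[i - 1] if i > 0 else ""
        trip = (p2, seq[i], seq[i + 1])
        if trip in allow:
            sites.append(i)
        elif seq[i + 1] == "P" or trip in veto:
            continue
        else:
            sites.append(i)
    return sites


def _oracle_simple_sites(seq, p1, blockers):
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i] in p1 and seq[i + 1] not in blockers
    ]


def test_rule_engine_matches_independent_oracle(rng):
    """Every built-in rule equals a literal per-enzyme scan on random 200-mers."""
    simple = {
        ("msdigest", "trypsin"): ("KR", "P"),
        ("msdigest", "chymotrypsin-high"): ("FYW", "P"),
        ("msdigest", "chymotrypsin-low"): ("FYWLM", "P"),
        ("msdigest", "pepsin-ph1.3"): ("FL", ""),
        ("msdigest", "pepsin-ph2"): ("FLWY", ""),
        ("msdigest", "elastase"): ("AVLIGS", "P"),
        ("msdigest", "proteinase-k"): ("AFILTVWY", ""),
        ("peptidecutter", "elastase"): ("AVLIGS", "P"),
        ("peptidecutter", "proteinase-k"): ("AFILTVWY", ""),
    }
    for _ in range(50):
        seq = "".join(rng.choice(list(AA), size=200))
        for (dialect, name), (p1, blockers) in simple.items():
            rule = builtin_rules(dialect)[name]
            assert find_cut_sites(seq, rule) == _oracle_simple_sites(
                seq, p1, blockers
            ), (dialect, name)
        assert find_cut_sites(seq, TRYPSIN) == _oracle_trypsin_sites(seq)


# --------------------------------------------------------------------- digest

def test_digest_single_cut():
    res = digest("AKAA", TRYPSIN, 0)
    assert [p.sequence for p in res.peptides] == ["AK", "AA"]
    assert res.cut_sites == [1]


def test_digest_no_sites_returns_whole_chain():
    res = digest("AAAA", TRYPSIN, 0)
    assert [p.sequence for p in res.peptides] == ["AAAA"]
    assert res.cut_sites == []


def test_digest_missed_cleavages_enumeration():
    # bounds 0|2|4|5 -> fragments spanning <=1 internal site
    res = digest("AKAKA", TRYPSIN, 1)
    got = {p.sequence for p in res.peptides}
    assert got == {"AK", "AK", "A", "AKAK", "AKA"}
    assert len(res.peptides) == 5  # 3 tiles + 2 one-missed spans


def test_digest_rejects_negative_missed():
    with pytest.raises(ValueError):
        digest("AKAA", TRYPSIN, -1)


@given(st.text(alphabet=AA, min_size=1, max_size=80))
def test_digest_tiles_sequence_exactly(seq):
    res = digest(seq, TRYPSIN, 0)
    assert res.peptides[0].start == 0
    assert res.peptides[-1].end == len(seq)
    for left, right in zip(res.peptides, res.peptides[1:]):
        assert left.end == right.start
    assert "".join(p.sequence for p in res.peptides) == seq
    assert len(res.peptides) == len(res.cut_sites) + 1


@given(st.text(alphabet=AA, min_size=1, max_size=80))
def test_peptide_masses_sum_to_chain_mass_plus_waters(seq):
    res = digest(seq, TRYPSIN, 0)
    total = sum(p.average_mass for p in res.peptides)
    expected = theoretical_mass(seq).average_mass + (len(res.peptides) - 1) * WATER
    assert total == pytest.approx(expected, abs=1e-6)


@given(st.text(alphabet=AA, min_size=2, max_size=40),
       st.text(alphabet=AA, min_size=2, max_size=40))
def test_concatenation_preserves_internal_sites(a, b):
    """Sites of A++B away from the junction contain all internal sites."""
    joint = set(find_cut_sites(a + b, TRYPSIN))
    # internal sites of a (exclude the last two positions: junction context)
    for i in find_cut_sites(a, TRYPSIN):
        if i < len(a) - 2:
            assert i in joint
    for i in find_cut_sites(b, TRYPSIN):
        if i >= 2:
            assert i + len(a) in joint


# -------------------------------------------------------------- digestibility

def test_normalized_site_count():
    assert normalized_site_count(10, 20000) == 10.0
    assert normalized_site_count(10, 40000) == 5.0
    assert normalized_site_count(0, 66000) == 0.0
    with pytest.raises(ValueError):
        normalized_site_count(1, 0)


def test_digestibility_table_single_record():
    tbl = digestibility_table([SubunitRecord("r", "AKAA")], ["trypsin"])
    assert tbl.per_record.loc[0, "n_sites"] == 1
    assert tbl.totals.loc[0, "total_sites"] == 1


def test_digestibility_table_empty_protease_list():
    tbl = digestibility_table([SubunitRecord("r", "AKAA")], [])
    assert tbl.per_record.empty
    assert tbl.totals.empty


def test_digestibility_table_errors():
    with pytest.raises(ValueError):
        digestibility_table([], ["trypsin"])
    with pytest.raises(KeyError):
        digestibility_table([SubunitRecord("r", "AKAA")], ["unknownase"])


def test_digestibility_uses_mature_sequence():
    rec = SubunitRecord("r", "KKKAKAA", signal_peptide_length=3)
    tbl = digestibility_table([rec], ["trypsin"])
    assert tbl.per_record.loc[0, "n_sites"] == 1  # only the mature K counts
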