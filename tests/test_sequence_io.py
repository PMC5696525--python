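import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight
from hypothesis import given, strategies as st

from kstab.sequence_io import (
    MassResult,
    SubunitRecord,
    mass_table,
    mature_sequence,
    pairwise_identity,
    pairwise_similarity,
    read_fasta,
    read_genbank,
    theoretical_mass,
    write_fasta,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_text = st.text(alphabet=AA, min_size=1, max_size=30)


# ---------------------------------------------------------------------- FASTA

def test_read_fasta_basic(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">s1\nMKT\n")
    recs = read_fasta(p)
    assert len(recs) == 1
    assert recs[0].id == "s1"
    assert recs[0].sequence == "MKT"
    assert recs[0].signal_peptide_length == 0


def test_read_fasta_signal_peptide_token(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">s1 sp=2\nMKTAA\n")
    rec = read_fasta(p)[0]
    assert rec.signal_peptide_length == 2
    assert mature_sequence(rec) == "TAA"


def test_read_fasta_illegal_residue_reports_position(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">s1\nMK1\n")
    with pytest.raises(ValueError, match="position 3"):
        read_fasta(p)


def test_read_fasta_empty_file_errors(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text("")
    with pytest.raises(ValueError):
        read_fasta(p)


def test_fasta_round_trip(tmp_path):
    recs = [SubunitRecord("x1", "MKTAA", 2), SubunitRecord("x2", "GGG")]
    p = tmp_path / "out.fasta"
    write_fasta(recs, p)
    back = read_fasta(p)
    assert [(r.id, r.sequence, r.signal_peptide_length) for r in back] == [
        ("x1", "MKTAA", 2),
        ("x2", "GGG", 0),
    ]


# -------------------------------------------------------------------- GenBank

def _write_genbank(path, rec):
    SeqIO.write([rec], str(path), "genbank")


def test_read_genbank_cds_translation(tmp_path):
    rec = SeqRecord(Seq("ATGAAAACCTAA"), id="T1", name="T1",
                    annotations={"molecule_type": "DNA"})
    rec.features = [
        SeqFeature(SimpleLocation(0, 12), type="CDS",
                   qualifiers={"translation": ["MKT"]})
    ]
    p = tmp_path / "t.gb"
    _write_genbank(p, rec)
    out = read_genbank(p)[0]
    assert out.sequence == "MKT"
    assert out.signal_peptide_length == 0


def test_read_genbank_sig_peptide_on_protein_record(tmp_path):
    seq = "M" + "A" * 30
    rec = SeqRecord(Seq(seq), id="P1", name="P1",
                    annotations={"molecule_type": "protein"})
    rec.features = [SeqFeature(SimpleLocation(0, 18), type="sig_peptide")]
    p = tmp_path / "p.gb"
    _write_genbank(p, rec)
    out = read_genbank(p)[0]
    assert out.signal_peptide_length == 18
    assert len(mature_sequence(out)) == len(seq) - 18


def test_read_genbank_sig_peptide_in_codons(tmp_path):
    rec = SeqRecord(Seq("ATG" * 10), id="T2", name="T2",
                    annotations={"molecule_type": "DNA"})
    rec.features = [
        SeqFeature(SimpleLocation(0, 30), type="CDS",
                   qualifiers={"translation": ["MMMMMMMMMM"]}),
        SeqFeature(SimpleLocation(0, 6), type="sig_peptide"),
    ]
    p = tmp_path / "t.gb"
    _write_genbank(p, rec)
    assert read_genbank(p)[0].signal_peptide_length == 2


def test_read_genbank_no_cds_errors(tmp_path):
    rec = SeqRecord(Seq("ATGATG"), id="T3", name="T3",
                    annotations={"molecule_type": "DNA"})
    p = tmp_path / "t.gb"
    _write_genbank(p, rec)
    with pytest.raises(ValueError, match="translatable"):
        read_genbank(p)


# --------------------------------------------------------------------- record

def test_record_invariants():
    with pytest.raises(ValueError):
        SubunitRecord("r", "")
    with pytest.raises(ValueError):
        SubunitRecord("r", "MKT", signal_peptide_length=3)
    rec = SubunitRecord("r", "mkt")
    assert rec.sequence == "MKT"  # uppercased


@pytest.mark.parametrize(
    "seq,sp,expected",
    [("MKTAA", 2, "TAA"), ("MKTAA", 0, "MKTAA"), ("M", 0, "M")],
)
def test_mature_sequence(seq, sp, expected):
    assert mature_sequence(SubunitRecord("r", seq, sp)) == expected


@given(st.text(alphabet=AA, min_size=2, max_size=40), st.integers(0, 39))
def test_mature_plus_signal_lengths_sum_to_precursor(seq, sp):
    sp = min(sp, len(seq) - 1)
    rec = SubunitRecord("r", seq, sp)
    assert len(mature_sequence(rec)) + sp == len(seq)


# --------------------------------------------------------------------- masses

def test_theoretical_mass_glycine():
    m = theoretical_mass("G")
    assert m.average_mass == pytest.approx(75.0672, abs=1e-3)
    assert m.monoisotopic_mass < m.average_mass


def test_theoretical_mass_dipeptide():
    assert theoretical_mass("AG").average_mass == pytest.approx(146.146, abs=1e-3)


def test_theoretical_mass_rejects_x():
    with pytest.raises(ValueError, match="position 2"):
        theoretical_mass("AXG")
    with pytest.raises(ValueError):
        theoretical_mass("")


def test_theoretical_mass_matches_biopython(rng):
    # independent oracle: Biopython's own residue tables
    seq = "".join(rng.choice(list(AA), size=50))
    m = theoretical_mass(seq)
    assert m.average_mass == pytest.approx(
        molecular_weight(seq, "protein"), abs=0.5
    )
    assert m.monoisotopic_mass == pytest.approx(
        molecular_weight(seq, "protein", monoisotopic=True), abs=0.05
    )


@given(aa_text, aa_text)
def test_mass_additivity(a, b):
    water = 18.0153
    whole = theoretical_mass(a + b).average_mass
    parts = theoretical_mass(a).average_mass + theoretical_mass(b).average_mass
    assert whole == pytest.approx(parts - water, abs=1e-6)


def test_mass_table_columns():
    df = mass_table([SubunitRecord("r1", "MKTAA", 2)])
    assert df.loc[0, "mature_length"] == 3
    assert df.loc[0, "precursor_average_da"] > df.loc[0, "mature_average_da"]


# ------------------------------------------------------------------- identity

def _nw_score(a, b, match=1.0, mismatch=0.0, gap=-1.0):
    """Independent Needleman-Wunsch score by explicit DP."""
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0.0] * m
        for j in range(1, m + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
        prev = cur
    return prev[m]


def test_identity_trivial_cases():
    assert pairwise_identity("MKT", "MKT") == 100.0
    assert pairwise_identity("AAAA", "CCCC") == 0.0


def test_identity_alignment_score_matches_dp_oracle(rng):
    for _ in range(10):
        a = "".join(rng.choice(list(AA), size=30))
        b = "".join(rng.choice(list(AA), size=30))
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1.0
        aligner.mismatch_score = 0.0
        aligner.open_gap_score = -1.0
        aligner.extend_gap_score = -1.0
        assert aligner.score(a, b) == pytest.approx(_nw_score(a, b))
        # identity is bounded by the fraction of matches any alignment can have
        ident = pairwise_identity(a, b)
        assert 0.0 <= ident <= 100.0


@given(aa_text, aa_text)
def test_identity_symmetric(a, b):
    assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


@given(aa_text)
def test_identity_100_iff_identical(seq):
    assert pairwise_identity(seq, seq) == 100.0


def test_similarity_counts_conservative_pairs():
    # I/L score positively in BLOSUM62, so the pair is similar but not identical
    assert pairwise_identity("ILIL", "LILI") < 100.0
    assert pairwise_similarity("ILIL", "LILI") == 100.0
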