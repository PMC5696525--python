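"""Protein sequence I/O, mature-chain derivation, masses and pairwise identity.

Subunit precursors carry an N-terminal secretory signal peptide that is absent
from the mature, secreted chain; the mature sequence is what matters for
theoretical masses and digestibility. Signal peptides are taken from
annotation (GenBank ``sig_peptide`` feature) or from a ``sp=N`` token in a
FASTA header — they are never predicted here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from . import _masses

#: Residues accepted in a :class:`SubunitRecord` (20 canonical + X).
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_SP_TOKEN = re.compile(r"\bsp=(\d+)\b")


@dataclass
class SubunitRecord:
    """A protein sequence with an optional signal-peptide annotation.

    Parameters
    ----------
    id : str
        Accession or free name.
    sequence : str
        Uppercase amino-acid string over the 20 canonical letters plus ``X``.
    signal_peptide_length : int
        Number of N-terminal residues annotated as signal peptide; 0 means
        none annotated.
    description : str
        Free text carried over from the source record.
    """

    id: str
    sequence: str
    signal_peptide_length: int = 0
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {pos}"
                )
        if not 0 <= self.signal_peptide_length < len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: signal peptide length "
                f"{self.signal_peptide_length} not in [0, {len(self.sequence) - 1}]"
            )


@dataclass(frozen=True)
class MassResult:
    """Theoretical chain masses in daltons."""

    average_mass: float
    monoisotopic_mass: float


def read_fasta(path: str | Path) -> list[SubunitRecord]:
    """Read protein records from a FASTA file.

    A header token ``sp=N`` (convention documented here, since FASTA has no
    feature table) sets the signal-peptide length of that record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _SP_TOKEN.search(rec.description)
        sp = int(m.group(1)) if m else 0
        records.append(
            SubunitRecord(
                id=rec.id,
                sequence=str(rec.seq),
                signal_peptide_length=sp,
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_genbank(path: str | Path) -> list[SubunitRecord]:
    """Read protein sequences from a GenBank flat file.

    For nucleotide records the first CDS ``/translation`` is used; protein
    records use the record sequence itself. A ``sig_peptide`` feature starting
    at the N-terminus sets ``signal_peptide_length`` (in residues).
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        molecule = rec.annotations.get("molecule_type", "")
        translation = None
        if "protein" in molecule.lower():
            translation = str(rec.seq)
        else:
            for feat in rec.features:
                if feat.type == "CDS" and "translation" in feat.qualifiers:
                    translation = feat.qualifiers["translation"][0]
                    break
        if not translation:
            raise ValueError(f"record {rec.id!r}: no translatable feature")

        sp = 0
        for feat in rec.features:
            if feat.type == "sig_peptide" and int(feat.location.start) == 0:
                span = int(feat.location.end) - int(feat.location.start)
                # on a nucleotide record the feature spans codons
                sp = span // 3 if "protein" not in molecule.lower() else span
                break
        records.append(
            SubunitRecord(
                id=rec.id,
                sequence=translation,
                signal_peptide_length=sp,
                description=rec.description,
            )
        )
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    return records


def write_fasta(records: Iterable[SubunitRecord], path: str | Path) -> None:
    """Write records as FASTA, encoding signal peptides as ``sp=N`` tokens."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.signal_peptide_length:
                header += f" sp={rec.signal_peptide_length}"
            fh.write(f">{header}\n{rec.sequence}\n")


def mature_sequence(rec: SubunitRecord) -> str:
    """Sequence with the annotated signal peptide removed."""
    return rec.sequence[rec.signal_peptide_length:]


def theoretical_mass(seq: str) -> MassResult:
    """Theoretical average and monoisotopic mass of a peptide chain.

    Sum of residue masses plus one water; residues must be canonical
    (``X`` is rejected rather than imputed).
    """
    if not seq:
        raise ValueError("empty sequence")
    avg = _masses.WATER_AVERAGE
    mono = _masses.WATER_MONOISOTOPIC
    for pos, ch in enumerate(seq.upper(), start=1):
        if ch not in _masses.AVERAGE:
            raise ValueError(f"cannot compute mass: residue {ch!r} at position {pos}")
        avg += _masses.AVERAGE[ch]
        mono += _masses.MONOISOTOPIC[ch]
    return MassResult(average_mass=avg, monoisotopic_mass=mono)


def mass_table(records: Iterable[SubunitRecord]) -> pd.DataFrame:
    """Per-record precursor and mature masses, TSV-exportable via ``to_csv``."""
    rows = []
    for rec in records:
        mat = mature_sequence(rec)
        pre = theoretical_mass(rec.sequence)
        post = theoretical_mass(mat)
        rows.append(
            {
                "id": rec.id,
                "precursor_length": len(rec.sequence),
                "mature_length": len(mat),
                "precursor_average_da": pre.average_mass,
                "mature_average_da": post.average_mass,
                "mature_monoisotopic_da": post.monoisotopic_mass,
            }
        )
    return pd.DataFrame(rows)


def _global_aligner(match: float, mismatch: float, gap: float,
                    matrix: str | None) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def pairwise_identity(a: str, b: str, *, match: float = 1.0,
                      mismatch: float = 0.0, gap: float = -1.0) -> float:
    """Percent identity from a global alignment.

    Needleman–Wunsch with linear gaps (defaults: match +1, mismatch 0,
    gap −1); identity = identical columns / alignment length × 100.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _global_aligner(match, mismatch, gap, None)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / length


def pairwise_similarity(a: str, b: str, *, matrix: str = "BLOSUM62",
                        gap: float = -8.0) -> float:
    """Percent similarity under a substitution matrix.

    Columns whose substitution score is positive (conservative replacements
    included) count as similar; gap columns never do.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _global_aligner(0, 0, gap, matrix)
    subs = aligner.substitution_matrix
    aln = aligner.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    similar = sum(
        1
        for x, y in zip(sa, sb)
        if x != "-" and y != "-" and subs[x, y] > 0
    )
    return 100.0 * similar / len(sa)
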