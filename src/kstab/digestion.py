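"""In-silico proteolysis: cleavage specificity rules, peptide enumeration and
normalized digestibility counts.

A protease is modelled by the residue it cuts after (P1), residues that block
cleavage when immediately C-terminal (P1′, classically proline), and optional
context exceptions expressed as position patterns around the scissile bond.
Site indices are 0-based and denote cleavage *after* index ``i`` (between
``i`` and ``i+1``).

Two named rule dialects ship with the package, because the common web
calculators do not agree on pepsin/elastase context rules: ``"peptidecutter"``
(with Keil-rule trypsin exceptions and simplified pepsin context rules) and
``"msdigest"`` (plain P1/P1′ rules, no context exceptions). Every output
records which dialect produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

from .sequence_io import SubunitRecord, mature_sequence, theoretical_mass

#: A context pattern: relative offset from the P1 index -> allowed residue set.
#: The pattern matches a candidate site ``i`` when, for every (offset, residues)
#: pair, position ``i + offset`` exists and holds one of the residues.
Pattern = Mapping[int, str]


@dataclass(frozen=True)
class CleavageRule:
    """Specificity definition for one protease.

    ``allow_patterns`` override P1′ blockers (e.g. trypsin cleaves K-P when W
    occupies P2); ``block_patterns`` add contextual vetoes beyond the plain
    P1′ blocker set.
    """

    name: str
    p1_residues: frozenset
    p1prime_blockers: frozenset = frozenset()
    allow_patterns: tuple = ()
    block_patterns: tuple = ()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise ValueError(f"rule {self.name!r}: empty P1 residue set")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "p1_residues": "".join(sorted(self.p1_residues)),
            "p1prime_blockers": "".join(sorted(self.p1prime_blockers)),
            "allow_patterns": [
                {int(k): v for k, v in pat.items()} for pat in self.allow_patterns
            ],
            "block_patterns": [
                {int(k): v for k, v in pat.items()} for pat in self.block_patterns
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CleavageRule":
        return cls(
            name=d["name"],
            p1_residues=frozenset(d["p1_residues"]),
            p1prime_blockers=frozenset(d.get("p1prime_blockers", "")),
            allow_patterns=tuple(
                {int(k): str(v) for k, v in pat.items()}
                for pat in d.get("allow_patterns", [])
            ),
            block_patterns=tuple(
                {int(k): str(v) for k, v in pat.items()}
                for pat in d.get("block_patterns", [])
            ),
        )


def save_rules(rules: Mapping[str, CleavageRule], path: str | Path) -> None:
    """Serialize a rule set to a YAML config file."""
    payload = {name: rule.to_dict() for name, rule in rules.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_rules(path: str | Path) -> dict:
    """Load a rule set previously written by :func:`save_rules`."""
    payload = yaml.safe_load(Path(path).read_text())
    return {name: CleavageRule.from_dict(d) for name, d in payload.items()}


# Keil-rule trypsin exceptions as tabulated by the common cleavage calculators:
# triplets (P2, P1, P1') that veto an otherwise valid K/R site, and the two
# contexts that rescue cleavage before proline.
_TRYPSIN_ALLOW = (
    {-1: "W", 0: "K", 1: "P"},  # WKP cleaves despite proline
    {-1: "M", 0: "R", 1: "P"},  # MRP cleaves despite proline
)
_TRYPSIN_BLOCK = (
    {-1: "C", 0: "K", 1: "D"},
    {-1: "D", 0: "K", 1: "D"},
    {-1: "C", 0: "K", 1: "H"},
    {-1: "C", 0: "K", 1: "Y"},
    {-1: "K", 0: "K", 1: "R"},
    {-1: "C", 0: "R", 1: "K"},
    {-1: "R", 0: "R", 1: "H"},
    {-1: "R", 0: "R", 1: "R"},
)

# Simplified pepsin context: cleavage after hydrophobic P1 is vetoed by
# proline on either flank and by a basic residue at P1'.
_PEPSIN_BLOCK = (
    {-1: "P"},
    {1: "HKR"},
)


def _dialect_rules(dialect: str) -> dict:
    if dialect == "peptidecutter":
        return {
            "trypsin": CleavageRule(
                "trypsin", frozenset("KR"), frozenset("P"),
                allow_patterns=_TRYPSIN_ALLOW, block_patterns=_TRYPSIN_BLOCK,
            ),
            "chymotrypsin-high": CleavageRule(
                "chymotrypsin-high", frozenset("FYW"), frozenset("P"),
                block_patterns=({0: "W", 1: "M"},),
            ),
            "chymotrypsin-low": CleavageRule(
                "chymotrypsin-low", frozenset("FYWLM"), frozenset("P"),
                block_patterns=({0: "W", 1: "M"}, {0: "M", 1: "Y"}),
            ),
            "pepsin-ph1.3": CleavageRule(
                "pepsin-ph1.3", frozenset("FL"), frozenset("P"),
                block_patterns=_PEPSIN_BLOCK,
            ),
            "pepsin-ph2": CleavageRule(
                "pepsin-ph2", frozenset("FLWY"), frozenset("P"),
                block_patterns=_PEPSIN_BLOCK,
            ),
            "elastase": CleavageRule(
                "elastase", frozenset("AVLIGS"), frozenset("P"),
            ),
            "proteinase-k": CleavageRule(
                "proteinase-k", frozenset("AFILTVWY"), frozenset(),
            ),
        }
    if dialect == "msdigest":
        return {
            "trypsin": CleavageRule("trypsin", frozenset("KR"), frozenset("P")),
            "chymotrypsin-high": CleavageRule(
                "chymotrypsin-high", frozenset("FYW"), frozenset("P")
            ),
            "chymotrypsin-low": CleavageRule(
                "chymotrypsin-low", frozenset("FYWLM"), frozenset("P")
            ),
            "pepsin-ph1.3": CleavageRule("pepsin-ph1.3", frozenset("FL"), frozenset()),
            "pepsin-ph2": CleavageRule("pepsin-ph2", frozenset("FLWY"), frozenset()),
            "elastase": CleavageRule("elastase", frozenset("AVLIGS"), frozenset("P")),
            "proteinase-k": CleavageRule(
                "proteinase-k", frozenset("AFILTVWY"), frozenset()
            ),
        }
    raise KeyError(f"unknown rules dialect {dialect!r}")


def builtin_rules(dialect: str = "peptidecutter") -> dict:
    """Built-in protease rule set for one dialect (name -> CleavageRule)."""
    return _dialect_rules(dialect)


def _matches(seq: str, i: int, pattern: Pattern) -> bool:
    for off, residues in pattern.items():
        j = i + off
        if j < 0 or j >= len(seq) or seq[j] not in residues:
            return False
    return True


def find_cut_sites(seq: str, rule: CleavageRule) -> list:
    """0-based indices ``i`` where ``rule`` cleaves between ``i`` and ``i+1``."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    sites = []
    for i in range(len(seq) - 1):
        if seq[i] not in rule.p1_residues:
            continue
        if any(_matches(seq, i, pat) for pat in rule.allow_patterns):
            sites.append(i)
            continue
        if seq[i + 1] in rule.p1prime_blockers:
            continue
        if any(_matches(seq, i, pat) for pat in rule.block_patterns):
            continue
        sites.append(i)
    return sites


class Peptide(NamedTuple):
    start: int
    end: int  # exclusive
    sequence: str
    average_mass: float
    monoisotopic_mass: float


@dataclass
class DigestResult:
    """Cut sites and peptides for one sequence under one protease."""

    sequence_id: str
    protease: str
    cut_sites: list
    peptides: list
    missed_cleavages: int


def digest(seq: str, rule: CleavageRule, missed_cleavages: int = 0,
           sequence_id: str = "") -> DigestResult:
    """Enumerate peptides with up to ``missed_cleavages`` internal cut sites.

    With ``missed_cleavages=0`` the peptides tile the sequence exactly once.
    """
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = seq.upper()
    sites = find_cut_sites(seq, rule)
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(bounds))):
            start, end = bounds[a], bounds[b]
            frag = seq[start:end]
            m = theoretical_mass(frag)
            peptides.append(
                Peptide(start, end, frag, m.average_mass, m.monoisotopic_mass)
            )
    return DigestResult(
        sequence_id=sequence_id,
        protease=rule.name,
        cut_sites=sites,
        peptides=peptides,
        missed_cleavages=missed_cleavages,
    )


def normalized_site_count(n_sites: int, mass_da: float) -> float:
    """Cut sites rescaled to a 20 kDa chain: ``n_sites * 20000 / mass``."""
    if mass_da <= 0:
        raise ValueError("mass must be > 0")
    return n_sites * 20000.0 / mass_da


class DigestibilityTable(NamedTuple):
    """Per-(record, protease) site counts plus per-protease totals."""

    per_record: pd.DataFrame
    totals: pd.DataFrame


def digestibility_table(records: Sequence[SubunitRecord],
                        proteases: Iterable[str],
                        dialect: str = "peptidecutter",
                        use_mature: bool = True) -> DigestibilityTable:
    """Raw and 20 kDa-normalized cleavage-site counts for each record/protease.

    Normalization uses the (mature, by default) average mass. The totals table
    aggregates each protease over all records, both raw and normalized.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rules = builtin_rules(dialect)
    proteases = list(proteases)
    for name in proteases:
        if name not in rules:
            raise KeyError(f"unknown protease {name!r} in dialect {dialect!r}")
    rows = []
    for rec in records:
        seq = mature_sequence(rec) if use_mature else rec.sequence
        mass = theoretical_mass(seq).average_mass
        for name in proteases:
            n = len(find_cut_sites(seq, rules[name]))
            rows.append(
                {
                    "id": rec.id,
                    "protease": name,
                    "dialect": dialect,
                    "n_sites": n,
                    "mature_average_da": mass,
                    "sites_per_20kda": normalized_site_count(n, mass),
                }
            )
    per_record = pd.DataFrame(
        rows,
        columns=["id", "protease", "dialect", "n_sites",
                 "mature_average_da", "sites_per_20kda"],
    )
    if per_record.empty:
        totals = pd.DataFrame(
            columns=["protease", "total_sites", "total_sites_per_20kda"]
        )
    else:
        totals = (
            per_record.groupby("protease", sort=False)
            .agg(total_sites=("n_sites", "sum"),
                 total_sites_per_20kda=("sites_per_20kda", "sum"))
            .reset_index()
        )
    return DigestibilityTable(per_record=per_record, totals=totals)
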