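"""Mass-spectrometry verification artifacts.

In-silico tryptic digestion of predicted circ-peptides, selection of
fragments that overlap junction-unique residues, neutral peptide mass
computation, and export of a protein-FASTA search database for downstream
MS search engines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from circscan.uniqueness import UniquenessReport

# Standard amino-acid residue masses (Da): monoisotopic and average,
# unmodified residues (Unimod/ExPASy reference values).
MONO_RESIDUE_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
AVG_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MONO = 18.0105646863
WATER_AVG = 18.01528


@dataclass(frozen=True)
class DigestParams:
    max_missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 35
    #: cleave after K/R but not before P; set False for strict K/R cleavage
    proline_rule: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_missed_cleavages <= 5):
            raise ValueError("max_missed_cleavages must be in 0..5")
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")


@dataclass
class EvidencePeptide:
    """A tryptic fragment of a circ-peptide, with half-open coordinates on
    the parent peptide and neutral masses once filled."""

    circ_id: str
    fragment: str
    start: int
    end: int
    missed_cleavages: int
    covers_unique: bool = False
    unique_aa_overlap: int = 0
    mono_mass_da: Optional[float] = None
    avg_mass_da: Optional[float] = None


def cleavage_sites(peptide: str, proline_rule: bool = True) -> list[int]:
    """Positions after which trypsin cleaves (indices of the K/R residue +1)."""
    sites = []
    for i, aa in enumerate(peptide[:-1]):
        if aa in "KR" and not (proline_rule and peptide[i + 1] == "P"):
            sites.append(i + 1)
    return sites


def tryptic_digest(
    peptide: str,
    params: Optional[DigestParams] = None,
    circ_id: str = "",
) -> list[EvidencePeptide]:
    """Digest with trypsin (cleave C-terminal to K/R, not before P).

    Emits every fragment with 0..max_missed_cleavages missed cleavages that
    satisfies the length bounds, ordered by start then missed-cleavage
    count. Masses are left unfilled.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    params = params or DigestParams()
    bounds = [0] + cleavage_sites(peptide, params.proline_rule) + [len(peptide)]
    fragments: list[EvidencePeptide] = []
    n = len(bounds) - 1  # number of 0-missed fragments
    for i in range(n):
        for missed in range(params.max_missed_cleavages + 1):
            j = i + missed + 1
            if j > n:
                break
            start, end = bounds[i], bounds[j]
            if params.min_len <= end - start <= params.max_len:
                fragments.append(
                    EvidencePeptide(
                        circ_id=circ_id,
                        fragment=peptide[start:end],
                        start=start,
                        end=end,
                        missed_cleavages=missed,
                    )
                )
    fragments.sort(key=lambda f: (f.start, f.missed_cleavages))
    return fragments


def peptide_mass(fragment: str, kind: str = "mono") -> float:
    """Neutral peptide mass in Da: sum of residue masses plus one water."""
    if not fragment:
        raise ValueError("empty fragment")
    if kind == "mono":
        table, water = MONO_RESIDUE_MASS, WATER_MONO
    elif kind == "avg":
        table, water = AVG_RESIDUE_MASS, WATER_AVG
    else:
        raise ValueError(f"unknown mass kind {kind!r}")
    total = water
    for aa in fragment:
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"non-standard residue {aa!r}") from None
    return total


def select_evidence_peptides(
    digest: Sequence[EvidencePeptide],
    report: UniquenessReport,
    params: Optional[DigestParams] = None,
) -> list[EvidencePeptide]:
    """Keep fragments overlapping at least one unique (uncovered) residue.

    Fills masses and sorts by descending unique-residue overlap, then
    ascending start coordinate.
    """
    selected = []
    mask = report.covered_mask
    for frag in digest:
        overlap = sum(1 for p in range(frag.start, frag.end) if not mask[p])
        if overlap >= 1:
            frag.covers_unique = True
            frag.unique_aa_overlap = overlap
            frag.mono_mass_da = peptide_mass(frag.fragment, "mono")
            frag.avg_mass_da = peptide_mass(frag.fragment, "avg")
            selected.append(frag)
    selected.sort(key=lambda f: (-f.unique_aa_overlap, f.start))
    return selected


def export_search_db(candidates: Iterable[tuple], path: Union[str, Path]) -> None:
    """Write an MS search database as protein FASTA.

    ``candidates`` yields ``(candidate_row, peptide)`` pairs; headers are
    ``>circ_id|orf_start|pep_len``. Duplicate peptides from different
    circRNAs are all kept (distinct headers). Output is deterministic.
    """
    entries = []
    for row, peptide in candidates:
        if not peptide:
            raise ValueError(f"{row.circ_id}: empty peptide")
        start = row.best_orf.start_nt if getattr(row, "best_orf", None) else 0
        entries.append((f"{row.circ_id}|{start}|{len(peptide)}", peptide))
    entries.sort()
    with open(path, "w") as handle:
        for header, peptide in entries:
            handle.write(f">{header}\n")
            for i in range(0, len(peptide), 60):
                handle.write(peptide[i : i + 60] + "\n")


EVIDENCE_COLUMNS = [
    "circ_id",
    "fragment",
    "start",
    "end",
    "missed",
    "covers_unique",
    "unique_aa_overlap",
    "mono_mass_da",
    "avg_mass_da",
]


def write_evidence_table(peptides: Iterable[EvidencePeptide], path: Union[str, Path]) -> None:
    import csv

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(EVIDENCE_COLUMNS)
        for p in peptides:
            writer.writerow(
                [
                    p.circ_id,
                    p.fragment,
                    p.start,
                    p.end,
                    p.missed_cleavages,
                    str(p.covers_unique).lower(),
                    p.unique_aa_overlap,
                    "" if p.mono_mass_da is None else f"{p.mono_mass_da:.5f}",
                    "" if p.avg_mass_da is None else f"{p.avg_mass_da:.4f}",
                ]
            )
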