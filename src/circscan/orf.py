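"""Open reading frames on circular nucleotide sequences.

A circular transcript has no natural end: a ribosome entering at a start
codon may read across the junction between the supplied rotation's last and
first base, and — when the circle length is not a multiple of 3 — keep
shifting frame on every lap (rolling-circle reading). After at most three
laps the reader returns to its starting state, so an ORF that has not met an
in-frame stop within ``max_cycles = 3`` laps never terminates and is flagged
infinite.

Coordinates are 0-based internally. The back-splice junction sits between
index L-1 and index 0 of the supplied rotation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# NCBI translation table 1 (standard code)
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class CircularORF:
    """One ORF on a circle, start codon through stop codon inclusive.

    ``overlay_bp`` counts circle bases read more than once (rolling-circle
    reuse); ``spans_junction`` is true when the reading crosses the
    back-splice junction of the supplied rotation.
    """

    circ_id: str
    start_nt: int
    orf_len_nt: int
    peptide: str
    circle_len: int
    is_complete: bool
    is_infinite: bool = False

    @property
    def frame(self) -> int:
        return self.start_nt % 3

    @property
    def pep_len_aa(self) -> int:
        return len(self.peptide)

    @property
    def spans_junction(self) -> bool:
        return self.start_nt + self.orf_len_nt > self.circle_len

    @property
    def overlay_bp(self) -> int:
        return max(0, self.orf_len_nt - self.circle_len)


@dataclass(frozen=True)
class OrfParams:
    """Candidate-filter thresholds.

    Defaults encode the strategy's strict rules: peptides of more than 50
    amino acids (``min_pep_aa = 51``), base reuse of fewer than 50 bp
    (``max_overlay_bp = 49``), and junction spanning required.
    """

    min_pep_aa: int = 51
    max_overlay_bp: int = 49
    max_cycles: int = 3
    require_junction: bool = True
    start_codons: frozenset = frozenset({"ATG"})

    def __post_init__(self) -> None:
        if self.min_pep_aa < 1:
            raise ValueError("min_pep_aa must be >= 1")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


def translate(codon_string: str, table: int = 1) -> str:
    """Translate a nucleotide string whose length is a multiple of 3.

    Codons containing N (or any non-ACGT character) yield X; stop codons
    yield '*'. The caller decides what to do with stops.
    """
    if table != 1:
        raise ValueError("only the standard genetic code (table 1) is supported")
    if len(codon_string) % 3 != 0:
        raise ValueError(f"length {len(codon_string)} is not a multiple of 3")
    seq = codon_string.upper()
    return "".join(CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq), 3))


def find_circular_orfs(
    rec,
    params: Optional[OrfParams] = None,
    include_infinite: bool = False,
) -> list[CircularORF]:
    """Enumerate ORFs starting at every start-codon occurrence on the circle.

    From each start position the reader walks codons with wraparound (index
    ``(s + i) mod L``) until the first in-frame stop, up to
    ``params.max_cycles * L`` nucleotides. Starts with no stop within that
    bound are infinite ORFs; they are excluded from the returned list unless
    ``include_infinite`` is set. Complete ORFs are sorted by descending
    peptide length, then ascending start position.
    """
    params = params or OrfParams()
    seq = rec.sequence
    L = len(seq)
    if L < 3:
        raise ValueError(f"{rec.circ_id}: circle length {L} < 3")
    # extended buffer long enough for a max_cycles-lap walk from any start
    ext = seq * (params.max_cycles + 1)
    max_nt = params.max_cycles * L
    results: list[CircularORF] = []
    for s in range(L):
        codon0 = seq[s : s + 3] if s + 3 <= L else (seq[s:] + seq[: s + 3 - L])
        if codon0 not in params.start_codons:
            continue
        orf = _walk_from(rec.circ_id, ext, s, L, max_nt)
        if orf.is_infinite and not include_infinite:
            continue
        results.append(orf)
    results.sort(key=lambda o: (not o.is_complete, -o.pep_len_aa, o.start_nt))
    return results


def _walk_from(circ_id: str, ext: str, s: int, L: int, max_nt: int) -> CircularORF:
    residues: list[str] = []
    n_codons = max_nt // 3
    for i in range(n_codons):
        pos = s + 3 * i
        codon = ext[pos : pos + 3]
        if codon in STOP_CODONS:
            return CircularORF(
                circ_id=circ_id,
                start_nt=s,
                orf_len_nt=3 * (i + 1),
                peptide="".join(residues),
                circle_len=L,
                is_complete=True,
            )
        residues.append(CODON_TABLE.get(codon, "X"))
    return CircularORF(
        circ_id=circ_id,
        start_nt=s,
        orf_len_nt=3 * n_codons,
        peptide="".join(residues),
        circle_len=L,
        is_complete=False,
        is_infinite=True,
    )


#: rule identifiers used in rejection records and pipeline stage flags
RULE_JUNCTION = "orf_junction"
RULE_PEP_LEN = "pep_len"
RULE_OVERLAY = "overlay"


def filter_orfs(
    orfs: Iterable[CircularORF],
    params: Optional[OrfParams] = None,
    return_rejections: bool = False,
):
    """Apply the three candidate rules to complete ORFs.

    Keeps ORFs that (1) span the junction when required, (2) encode strictly
    more than ``min_pep_aa - 1`` amino acids, and (3) reuse strictly fewer
    than ``max_overlay_bp + 1`` bases. With ``return_rejections`` also
    returns ``(orf, rule)`` pairs naming the first rule that fired.
    """
    params = params or OrfParams()
    kept: list[CircularORF] = []
    rejected: list[tuple[CircularORF, str]] = []
    for orf in orfs:
        if params.require_junction and not orf.spans_junction:
            rejected.append((orf, RULE_JUNCTION))
        elif orf.pep_len_aa < params.min_pep_aa:
            rejected.append((orf, RULE_PEP_LEN))
        elif orf.overlay_bp > params.max_overlay_bp:
            rejected.append((orf, RULE_OVERLAY))
        else:
            kept.append(orf)
    if return_rejections:
        return kept, rejected
    return kept


def best_orf(orfs: Iterable[CircularORF]) -> Optional[CircularORF]:
    """Promote the headline ORF: longest peptide, ties to smallest start."""
    candidates = [o for o in orfs if o.is_complete]
    if not candidates:
        return None
    return min(candidates, key=lambda o: (-o.pep_len_aa, o.start_nt))


ORF_COLUMNS = [
    "circ_id",
    "start_nt",
    "frame",
    "orf_len_nt",
    "pep_len_aa",
    "spans_junction",
    "overlay_bp",
    "is_complete",
    "is_infinite",
    "peptide",
]


def write_orf_table(orfs: Iterable[CircularORF], path: Union[str, Path]) -> None:
    """Write per-ORF TSV with the canonical column order."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ORF_COLUMNS)
        for o in orfs:
            writer.writerow(
                [
                    o.circ_id,
                    o.start_nt,
                    o.frame,
                    o.orf_len_nt,
                    o.pep_len_aa,
                    str(o.spans_junction).lower(),
                    o.overlay_bp,
                    str(o.is_complete).lower(),
                    str(o.is_infinite).lower(),
                    o.peptide,
                ]
            )
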