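"""Junction-unique peptide analysis.

A circRNA-derived peptide is only verifiable by mass spectrometry if it
carries residues that cannot be explained by the host gene's linear protein.
This module measures the shared region (longest exact common substring),
marks every peptide position coverable by a host match of at least
``min_match`` residues, and applies the strict more-than-``threshold``
unique-residues rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class UniquenessParams:
    #: minimum exact-match length for a host substring to "cover" residues;
    #: 7 aa is the shortest peptide routinely accepted as MS evidence
    min_match: int = 7
    #: strict lower bound: pass requires unique_aa_count > threshold
    threshold: int = 2
    #: treat isoleucine and leucine as equivalent (MS cannot distinguish them)
    il_equivalence: bool = False

    def __post_init__(self) -> None:
        if self.min_match < 1:
            raise ValueError("min_match must be >= 1")


@dataclass
class UniquenessReport:
    circ_id: str
    host_ids: list
    common_area_aa: int
    covered_mask: list  # bool per circ-peptide position
    unique_segments: list  # (start, end) half-open intervals
    passes: bool

    @property
    def unique_aa_count(self) -> int:
        return sum(1 for c in self.covered_mask if not c)


def longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """Length and start positions of the longest exact common substring.

    Ties resolve to the smallest position in ``a``, then the smallest in
    ``b``. Raises ``ValueError`` on empty input.
    """
    if not a or not b:
        raise ValueError("longest_common_substring requires non-empty strings")
    best_len, best_a, best_b = 0, 0, 0
    # dp over common-suffix lengths, one row of |b| at a time
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                length = prev[j - 1] + 1
                cur[j] = length
                pos_a, pos_b = i - length, j - length
                if length > best_len or (
                    length == best_len
                    and best_len > 0
                    and (pos_a, pos_b) < (best_a, best_b)
                ):
                    best_len, best_a, best_b = length, pos_a, pos_b
        prev = cur
    return best_len, best_a, best_b


def _canon(seq: str, il_equivalence: bool) -> str:
    return seq.replace("I", "L") if il_equivalence else seq


def uniqueness_report(
    peptide: str,
    hosts: Sequence,
    params: Optional[UniquenessParams] = None,
    circ_id: str = "",
) -> UniquenessReport:
    """Compare a circ-peptide against host protein(s).

    A peptide position is covered when it lies inside an exact match of
    length >= ``params.min_match`` against any host. Unique segments are the
    maximal runs of uncovered positions; the report passes when the total
    uncovered count strictly exceeds ``params.threshold``. Empty ``hosts``
    means every residue is unique.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    params = params or UniquenessParams()
    n = len(peptide)
    pep = _canon(peptide, params.il_equivalence)
    covered = [False] * n
    common_area = 0
    k = params.min_match
    host_windows: set[str] = set()
    for host in hosts:
        hseq = _canon(host.sequence, params.il_equivalence)
        length, _, _ = longest_common_substring(pep, hseq)
        common_area = max(common_area, length)
        for j in range(len(hseq) - k + 1):
            host_windows.add(hseq[j : j + k])
    # a position is inside a match of length >= k iff it is inside a
    # matching window of length exactly k
    for i in range(n - k + 1):
        if pep[i : i + k] in host_windows:
            for p in range(i, i + k):
                covered[p] = True
    segments = _uncovered_runs(covered)
    unique_count = n - sum(covered)
    return UniquenessReport(
        circ_id=circ_id,
        host_ids=[h.protein_id for h in hosts],
        common_area_aa=common_area,
        covered_mask=covered,
        unique_segments=segments,
        passes=unique_count > params.threshold,
    )


def _uncovered_runs(covered: list) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(covered):
        if not c and start is None:
            start = i
        elif c and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(covered)))
    return runs


def passes_uniqueness(report: UniquenessReport, threshold: int = 2) -> bool:
    """Strict rule: more than ``threshold`` unique residues required."""
    return report.unique_aa_count > threshold
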