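"""Synthetic fixtures with known planted truth.

Generators produce circular sequences carrying exactly one planted ORF of
requested geometry, host proteins sharing a controlled prefix with a
circ-peptide, and two-group expression matrices with planted differential
rows. Backgrounds are built from an A/T-only stop-dense pattern so that a
reader in any frame dies within a few codons of leaving the planted region
— the long-peptide rule can only be met by planted ORFs — and every
generated circle is verified against the scanner before being returned.

All randomness flows from the stated seed via numpy's seed-sequence
spawning; the same seed always reproduces byte-identical fixtures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from circscan.de import ExpressionMatrix
from circscan.orf import (
    CODON_TABLE,
    STOP_CODONS,
    OrfParams,
    filter_orfs,
    find_circular_orfs,
    translate,
)
from circscan.seq_io import CircRNARecord, ProteinRecord

# background: period-8 A/T pattern; 3 steps mod 8 cycle through every phase,
# so a reader in any frame meets a TAA within at most 8 codons (24 nt)
_BACKGROUND = "TTAATTAA"

_ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
# codons allowed inside a planted ORF: no stops (would truncate it) and no
# ATG (would plant a second in-frame start)
_SAFE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS and c != "ATG"]

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


class InfeasibleGeometry(ValueError):
    """Requested planted geometry cannot be realised."""


@dataclass
class PlantedTruth:
    """Ground truth for one synthetic fixture."""

    circ_id: str
    start_nt: int = 0
    frame: int = 0
    orf_len_nt: int = 0
    peptide: str = ""
    spans_junction: bool = False
    overlay_bp: int = 0
    host_prefix_len: Optional[int] = None
    expected_unique_aa: Optional[int] = None
    de_direction: Optional[str] = None
    de_log2fc: Optional[float] = None


def make_circ_with_orf(
    L: int,
    orf_aa_len: int,
    start_nt: int,
    want_junction: bool,
    want_overlay_bp: int,
    seed: int,
    circ_id: str = "",
    max_attempts: int = 500,
) -> tuple[CircRNARecord, PlantedTruth]:
    """Build a circle of length ``L`` with exactly one planted ATG..stop ORF.

    ``orf_aa_len`` is the encoded peptide length, so the ORF occupies
    ``3 * (orf_aa_len + 1)`` nucleotides including its stop codon. The
    requested junction/overlay geometry is validated against ``L`` and
    ``start_nt`` before construction; inconsistent requests raise
    ``InfeasibleGeometry``. Every returned circle has been re-scanned: the
    planted ORF is found with its exact geometry and no other ORF passes
    the default candidate rules.
    """
    if L < 3:
        raise InfeasibleGeometry(f"circle length {L} < 3")
    if not (0 <= start_nt < L):
        raise InfeasibleGeometry(f"start_nt {start_nt} outside circle of length {L}")
    orf_nt = 3 * (orf_aa_len + 1)
    if max(0, orf_nt - L) != want_overlay_bp:
        raise InfeasibleGeometry(
            f"overlay {want_overlay_bp} inconsistent with orf_nt {orf_nt} on circle {L}"
        )
    if (start_nt + orf_nt > L) != want_junction:
        raise InfeasibleGeometry(
            f"junction={want_junction} inconsistent with start {start_nt} + orf {orf_nt} on circle {L}"
        )
    circ_id = circ_id or f"sim_circ_{seed:06d}"
    root = np.random.SeedSequence([int(seed), L, orf_aa_len, start_nt])
    for attempt_seq in root.spawn(max_attempts):
        rng = np.random.default_rng(attempt_seq)
        seq = _try_plant(L, orf_aa_len, start_nt, rng)
        if seq is None:
            continue
        rec = CircRNARecord(circ_id=circ_id, sequence=seq)
        truth = _verify_plant(rec, start_nt, orf_nt)
        if truth is not None:
            return rec, truth
    raise InfeasibleGeometry(
        f"could not realise ORF of {orf_nt} nt at {start_nt} on circle {L} "
        f"after {max_attempts} attempts"
    )


def _try_plant(L: int, orf_aa_len: int, start_nt: int, rng) -> Optional[str]:
    seq: list = [None] * L
    n_codons = orf_aa_len + 1
    for i in range(n_codons):
        positions = [(start_nt + 3 * i + k) % L for k in range(3)]
        current = [seq[p] for p in positions]
        if i == 0:
            wanted = ["ATG"]
        elif i == n_codons - 1:
            wanted = sorted(STOP_CODONS)
        else:
            wanted = _SAFE_CODONS
        options = [
            c for c in wanted
            if all(cur is None or cur == ch for cur, ch in zip(current, c))
        ]
        if not options:
            return None  # forced letters contradict the wanted codon class
        codon = options[rng.integers(len(options))] if len(options) > 1 else options[0]
        for p, ch in zip(positions, codon):
            seq[p] = ch
    for p in range(L):
        if seq[p] is None:
            seq[p] = _BACKGROUND[p % len(_BACKGROUND)]
    return "".join(seq)


def _verify_plant(rec: CircRNARecord, start_nt: int, orf_nt: int) -> Optional[PlantedTruth]:
    params = OrfParams()
    orfs = find_circular_orfs(rec, params)
    planted = [o for o in orfs if o.start_nt == start_nt]
    if len(planted) != 1 or planted[0].orf_len_nt != orf_nt:
        return None
    orf = planted[0]
    qualifying = filter_orfs(orfs, params)
    extra = [o for o in qualifying if o.start_nt != start_nt]
    if extra:
        return None  # an accidental ORF would pass the candidate rules
    return PlantedTruth(
        circ_id=rec.circ_id,
        start_nt=orf.start_nt,
        frame=orf.frame,
        orf_len_nt=orf.orf_len_nt,
        peptide=orf.peptide,
        spans_junction=orf.spans_junction,
        overlay_bp=orf.overlay_bp,
    )


def make_host_protein(
    circ_peptide: str,
    shared_prefix_len: int,
    total_len: int,
    seed: int,
    min_match: int = 7,
    protein_id: str = "",
    gene: str = "",
    max_attempts: int = 200,
) -> ProteinRecord:
    """Build a host protein sharing exactly the circ-peptide's first
    ``shared_prefix_len`` residues and no other match of ``min_match`` or
    longer, so the expected unique-residue count is known by construction."""
    from circscan.uniqueness import UniquenessParams, uniqueness_report

    k = shared_prefix_len
    if k > min(len(circ_peptide), total_len):
        raise ValueError("shared_prefix_len exceeds peptide or host length")
    if total_len < 1:
        raise ValueError("total_len must be >= 1")
    protein_id = protein_id or f"sim_host_{seed:06d}"
    params = UniquenessParams(min_match=min_match)
    root = np.random.SeedSequence([int(seed), len(circ_peptide), k, total_len])
    for attempt_seq in root.spawn(max_attempts):
        rng = np.random.default_rng(attempt_seq)
        tail = "".join(_AA_ALPHABET[i] for i in rng.integers(0, 20, size=total_len - k))
        host = ProteinRecord(protein_id=protein_id, sequence=circ_peptide[:k] + tail, gene=gene)
        report = uniqueness_report(circ_peptide, [host], params)
        expected_covered = set(range(k)) if k >= min_match else set()
        actual_covered = {i for i, c in enumerate(report.covered_mask) if c}
        common_ok = report.common_area_aa == k if k >= 1 else report.common_area_aa < min_match
        if actual_covered == expected_covered and common_ok:
            return host
    raise ValueError(
        f"could not build host with exact shared prefix {k} after {max_attempts} attempts"
    )


def make_expression_matrix(
    n_circ: int,
    n_per_group: int,
    n_de: int,
    lfc: float,
    sigma: float,
    seed: int,
    baseline: float = 8.0,
) -> tuple[ExpressionMatrix, list[PlantedTruth]]:
    """Two-group Gaussian log2 expression with ``n_de`` planted rows whose
    tumor means are shifted by ±``lfc`` (alternating sign)."""
    if n_de > n_circ:
        raise ValueError("n_de cannot exceed n_circ")
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), n_circ, n_per_group]))
    circ_ids = [f"sim_circ_{i:05d}" for i in range(n_circ)]
    sample_ids = [f"normal_{j:02d}" for j in range(n_per_group)] + [
        f"tumor_{j:02d}" for j in range(n_per_group)
    ]
    groups = ["normal"] * n_per_group + ["tumor"] * n_per_group
    values = rng.normal(baseline, sigma, size=(n_circ, 2 * n_per_group))
    de_rows = rng.choice(n_circ, size=n_de, replace=False)
    truths = []
    for rank, i in enumerate(sorted(de_rows)):
        shift = lfc if rank % 2 == 0 else -lfc
        values[i, n_per_group:] += shift
        truths.append(
            PlantedTruth(
                circ_id=circ_ids[i],
                de_direction="up" if shift > 0 else "down",
                de_log2fc=shift,
            )
        )
    matrix = ExpressionMatrix(
        circ_ids=circ_ids, sample_ids=sample_ids, group_labels=groups, values=values
    )
    return matrix, truths
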