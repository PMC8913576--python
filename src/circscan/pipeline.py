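"""Candidate funnel orchestration.

Stages run in a fixed order — differential expression, junction spanning,
peptide length, base overlay, external database flag, peptide uniqueness —
and every candidate carries a per-stage pass/fail/skipped flag, so nothing
is silently dropped. A stage that fails marks all downstream stages
skipped; a disabled stage (or one whose inputs are absent, e.g. no host
protein) is skipped without penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from circscan.de import apply_de_gate
from circscan.orf import (
    CircularORF,
    OrfParams,
    best_orf,
    filter_orfs,
    find_circular_orfs,
)
from circscan.seq_io import AnnotationRow, CircRNARecord, DataError, ProteinRecord
from circscan.uniqueness import UniquenessParams, UniquenessReport, uniqueness_report

logger = logging.getLogger(__name__)

STAGES = ["de", "orf_junction", "pep_len", "overlay", "db", "uniqueness"]

PASS, FAIL, SKIPPED = "pass", "fail", "skipped"


@dataclass
class PipelineConfig:
    orf_params: OrfParams = field(default_factory=OrfParams)
    uniqueness_params: UniquenessParams = field(default_factory=UniquenessParams)
    lfc_cut: float = 1.0
    q_cut: float = 0.05
    de_pre_filtered: bool = False
    enable_de: bool = True
    enable_orf: bool = True
    enable_db: bool = True
    enable_uniqueness: bool = True

    def __post_init__(self) -> None:
        if not (self.enable_de or self.enable_orf or self.enable_db or self.enable_uniqueness):
            raise ValueError("at least one stage must be enabled")


@dataclass
class CandidateRow:
    """One circRNA's full filter provenance through the funnel."""

    circ_id: str
    log2fc: float = 0.0
    host_gene: str = ""
    transcript: str = ""
    genomic_position: str = ""
    db_coding_flag: Optional[bool] = None
    best_orf: Optional[CircularORF] = None
    uniqueness: Optional[UniquenessReport] = None
    stage_flags: dict = field(default_factory=dict)

    @property
    def final_pass(self) -> bool:
        flags = [self.stage_flags.get(s, SKIPPED) for s in STAGES]
        return all(f != FAIL for f in flags)

    def flatten(self) -> dict:
        d = {
            "circ_id": self.circ_id,
            "log2fc": self.log2fc,
            "host_gene": self.host_gene,
            "transcript": self.transcript,
            "genomic_position": self.genomic_position,
            "db_coding_flag": self.db_coding_flag,
            "orf_start_nt": self.best_orf.start_nt if self.best_orf else None,
            "orf_len_nt": self.best_orf.orf_len_nt if self.best_orf else None,
            "pep_len_aa": self.best_orf.pep_len_aa if self.best_orf else None,
            "spans_junction": self.best_orf.spans_junction if self.best_orf else None,
            "overlay_bp": self.best_orf.overlay_bp if self.best_orf else None,
            "common_area_aa": self.uniqueness.common_area_aa if self.uniqueness else None,
            "unique_aa_count": self.uniqueness.unique_aa_count if self.uniqueness else None,
        }
        for stage in STAGES:
            d[f"stage_{stage}"] = self.stage_flags.get(stage, SKIPPED)
        d["final_pass"] = self.final_pass
        return d


CANDIDATE_COLUMNS = list(CandidateRow(circ_id="x").flatten().keys())


def run_scan(
    records: Sequence[CircRNARecord],
    annotations: Sequence[AnnotationRow],
    hosts: Sequence[ProteinRecord],
    config: Optional[PipelineConfig] = None,
) -> list[CandidateRow]:
    """Run the full funnel over annotated circRNAs.

    Every annotation row becomes a CandidateRow; sequence lookup failures
    are reported on the row rather than raised. Output order is
    deterministic: descending log2fc, then circ_id.
    """
    config = config or PipelineConfig()
    seq_index = {}
    for rec in records:
        if rec.circ_id in seq_index:
            raise DataError(f"duplicate sequence record for {rec.circ_id}")
        seq_index[rec.circ_id] = rec
    seen = set()
    for ann in annotations:
        if ann.circ_id in seen:
            raise DataError(f"conflicting duplicate annotation for {ann.circ_id}")
        seen.add(ann.circ_id)
    host_index: dict = {}
    for host in hosts:
        host_index.setdefault(host.gene, []).append(host)

    de_survivors = {
        r.circ_id
        for r in apply_de_gate(
            annotations, config.lfc_cut, config.q_cut, pre_filtered=config.de_pre_filtered
        )
    }

    rows = []
    for ann in annotations:
        row = CandidateRow(
            circ_id=ann.circ_id,
            log2fc=ann.log2fc,
            host_gene=ann.host_gene,
            transcript=ann.transcript,
            genomic_position=ann.genomic_position,
            db_coding_flag=ann.db_coding_flag,
        )
        _run_stages(row, ann, seq_index.get(ann.circ_id), host_index, config)
        rows.append(row)

    rows.sort(key=lambda r: (-r.log2fc, r.circ_id))
    _log_summary(rows)
    return rows


def _run_stages(row, ann, rec, host_index, config) -> None:
    failed = False

    def mark(stage: str, ok: Optional[bool]) -> None:
        nonlocal failed
        if failed or ok is None:
            row.stage_flags[stage] = SKIPPED
        elif ok:
            row.stage_flags[stage] = PASS
        else:
            row.stage_flags[stage] = FAIL
            failed = True

    # DE gate
    if config.enable_de:
        if config.de_pre_filtered:
            mark("de", True)
        else:
            mark("de", abs(ann.log2fc) > config.lfc_cut and ann.adj_p is not None and ann.adj_p < config.q_cut)
    else:
        mark("de", None)

    # ORF rules: progressive filtering attributes the first rule that empties
    # the candidate set
    if config.enable_orf and not failed:
        if rec is None:
            logger.warning("no sequence for %s; ORF stages failed at input", row.circ_id)
            mark("orf_junction", False)
            mark("pep_len", None)
            mark("overlay", None)
        else:
            params = config.orf_params
            orfs = find_circular_orfs(rec, params)
            s1 = [o for o in orfs if not params.require_junction or o.spans_junction]
            mark("orf_junction", bool(s1) if params.require_junction else None)
            s2 = [o for o in s1 if o.pep_len_aa >= params.min_pep_aa]
            mark("pep_len", bool(s2) if not failed else None)
            s3 = [o for o in s2 if o.overlay_bp <= params.max_overlay_bp]
            mark("overlay", bool(s3) if not failed else None)
            row.best_orf = best_orf(s3) if s3 else None
    else:
        mark("orf_junction", None)
        mark("pep_len", None)
        mark("overlay", None)

    # external database coding flag: pass-through boolean gate
    if config.enable_db and not failed:
        mark("db", ann.db_coding_flag)  # None -> skipped
    else:
        mark("db", None)

    # uniqueness against host protein(s)
    if config.enable_uniqueness and not failed and row.best_orf is not None:
        matched = host_index.get(ann.host_gene, [])
        if not matched:
            mark("uniqueness", None)
        else:
            report = uniqueness_report(
                row.best_orf.peptide,
                matched,
                config.uniqueness_params,
                circ_id=row.circ_id,
            )
            row.uniqueness = report
            mark("uniqueness", report.passes)
    else:
        mark("uniqueness", None)


def _log_summary(rows) -> None:
    summary = summarize(rows)
    for stage in STAGES:
        logger.info("stage %-12s pass=%d", stage, summary["stage_pass_counts"][stage])
    logger.info("final candidates: %d (%d up / %d down)", summary["final"], summary["up"], summary["down"])


def summarize(rows: Sequence[CandidateRow]) -> dict:
    """Per-stage pass counts, final count, and up/down partition of finals."""
    stage_counts = {
        stage: sum(1 for r in rows if r.stage_flags.get(stage) == PASS) for stage in STAGES
    }
    finals = [r for r in rows if r.final_pass]
    return {
        "total": len(rows),
        "stage_pass_counts": stage_counts,
        "final": len(finals),
        "up": sum(1 for r in finals if r.log2fc > 0),
        "down": sum(1 for r in finals if r.log2fc < 0),
    }
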