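"""Input/output for every external format the pipeline touches.

FASTA (nucleotide and protein) is read and written through Biopython;
annotation and candidate tables are plain TSV with a fixed header. All
writers are deterministic so repeated runs produce byte-identical files.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

ANNOTATION_COLUMNS = [
    "circ_id",
    "log2fc",
    "adj_p",
    "host_gene",
    "transcript",
    "genomic_position",
    "db_coding_flag",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class CircRNARecord:
    """One circular RNA mature sequence, written linearly at an arbitrary
    rotation; the back-splice junction sits between the last and first base."""

    circ_id: str
    sequence: str
    host_gene: str = ""
    transcript: str = ""
    genomic_position: str = ""

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        if not self.circ_id:
            raise DataError("circ_id must be non-empty")
        if not self.sequence:
            raise DataError(f"{self.circ_id}: empty sequence")
        _check_alphabet(self.circ_id, self.sequence, NUCLEOTIDE_ALPHABET)


@dataclass(frozen=True)
class ProteinRecord:
    """A linear protein sequence (e.g. the host gene's translation product)."""

    protein_id: str
    sequence: str
    gene: str = ""

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise DataError("protein_id must be non-empty")
        if not self.sequence:
            raise DataError(f"{self.protein_id}: empty sequence")
        if "*" in self.sequence:
            raise DataError(f"{self.protein_id}: internal stop character")
        _check_alphabet(self.protein_id, self.sequence, PROTEIN_ALPHABET)


@dataclass
class AnnotationRow:
    """One circRNA's annotation: fold change, host gene, optional adjusted p
    and optional external database coding-potential verdict."""

    circ_id: str
    log2fc: float
    adj_p: Optional[float] = None
    host_gene: str = ""
    transcript: str = ""
    genomic_position: str = ""
    db_coding_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.adj_p is not None and not (0.0 <= self.adj_p <= 1.0):
            raise DataError(f"{self.circ_id}: adj_p {self.adj_p} outside [0, 1]")


def _check_alphabet(rec_id: str, seq: str, allowed: frozenset) -> None:
    for offset, ch in enumerate(seq):
        if ch not in allowed:
            raise DataError(f"record {rec_id}: illegal character {ch!r} at offset {offset}")


def read_fasta(
    path: Union[str, Path],
    alphabet: Literal["nucleotide", "protein"],
) -> list:
    """Parse a FASTA file into CircRNARecord or ProteinRecord objects.

    Sequences are uppercased; in nucleotide mode U is mapped to T. Record
    order is preserved. Raises ``DataError`` on an empty file, duplicate ids,
    or characters outside the declared alphabet (reporting record and offset).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen: set = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if entry.id in seen:
            raise DataError(f"duplicate record id {entry.id!r} in {path}")
        seen.add(entry.id)
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
            records.append(CircRNARecord(circ_id=entry.id, sequence=seq))
        elif alphabet == "protein":
            gene = _gene_from_description(entry.description)
            records.append(ProteinRecord(protein_id=entry.id, sequence=seq, gene=gene))
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return records


def _gene_from_description(description: str) -> str:
    # accepts either "id GENE" or a "gene=GENE" token in the description
    for token in description.split()[1:]:
        if token.startswith("gene="):
            return token[5:]
    parts = description.split()
    return parts[1] if len(parts) > 1 else ""


def write_fasta(records: Iterable, path: Union[str, Path], wrap: int = 60) -> None:
    """Write records as FASTA with fixed 60-character line wrapping."""
    path = Path(path)
    seq_records = []
    for rec in records:
        if isinstance(rec, CircRNARecord):
            rec_id, seq, desc = rec.circ_id, rec.sequence, ""
        else:
            rec_id, seq = rec.protein_id, rec.sequence
            desc = f"gene={rec.gene}" if rec.gene else ""
        seq_records.append(SeqRecord(Seq(seq), id=rec_id, description=desc))
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=wrap)
        writer.write_file(seq_records)


def read_annotation_table(path: Union[str, Path]) -> list[AnnotationRow]:
    """Read a tab-separated annotation table.

    Requires columns ``circ_id`` (or ``id``) and ``log2fc``; the remaining
    annotation columns are optional and yield missing values when absent.
    Duplicate circ_ids are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise DataError(f"{path}: empty file")
        fields = {f.strip(): f for f in reader.fieldnames}
        id_col = fields.get("circ_id") or fields.get("id")
        lfc_col = fields.get("log2fc")
        if id_col is None or lfc_col is None:
            raise DataError(f"{path}: required columns circ_id and log2fc not found")
        rows: list[AnnotationRow] = []
        seen: set = set()
        for lineno, raw in enumerate(reader, start=2):
            circ_id = (raw.get(id_col) or "").strip()
            if not circ_id:
                raise DataError(f"{path}:{lineno}: empty circ_id")
            if circ_id in seen:
                raise DataError(f"{path}:{lineno}: duplicate circ_id {circ_id!r}")
            seen.add(circ_id)
            lfc_text = (raw.get(lfc_col) or "").strip().replace("−", "-")
            try:
                log2fc = float(lfc_text)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-numeric log2fc {lfc_text!r}") from None
            rows.append(
                AnnotationRow(
                    circ_id=circ_id,
                    log2fc=log2fc,
                    adj_p=_opt_float(raw, fields, "adj_p"),
                    host_gene=_opt_str(raw, fields, "host_gene"),
                    transcript=_opt_str(raw, fields, "transcript"),
                    genomic_position=_opt_str(raw, fields, "genomic_position"),
                    db_coding_flag=_opt_bool(raw, fields, "db_coding_flag"),
                )
            )
    if not rows:
        logger.warning("annotation table %s contains a header but no rows", path)
    return rows


def _opt_str(raw: dict, fields: dict, name: str) -> str:
    col = fields.get(name)
    return (raw.get(col) or "").strip() if col else ""


def _opt_float(raw: dict, fields: dict, name: str) -> Optional[float]:
    text = _opt_str(raw, fields, name)
    return float(text) if text not in ("", "NA", "nan") else None


def _opt_bool(raw: dict, fields: dict, name: str) -> Optional[bool]:
    text = _opt_str(raw, fields, name).lower()
    if text in ("", "na", "nan"):
        return None
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    raise DataError(f"unparseable boolean {text!r} in column {name}")


def write_annotation_table(rows: Iterable[AnnotationRow], path: Union[str, Path]) -> None:
    """Write AnnotationRows as TSV with the canonical column order."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for row in rows:
            writer.writerow(
                [
                    row.circ_id,
                    f"{row.log2fc:.2f}",
                    "" if row.adj_p is None else repr(row.adj_p),
                    row.host_gene,
                    row.transcript,
                    row.genomic_position,
                    "" if row.db_coding_flag is None else str(row.db_coding_flag).lower(),
                ]
            )


def write_candidates(rows: list, path: Union[str, Path], format: Literal["tsv", "json"] = "tsv") -> None:
    """Write candidate rows (see :mod:`circscan.pipeline`) to TSV or JSON.

    Output ordering is deterministic: descending log2fc, then circ_id.
    """
    flattened = [row.flatten() for row in rows]
    flattened.sort(key=lambda d: (-d["log2fc"], d["circ_id"]))
    path = Path(path)
    if format == "tsv":
        columns = list(flattened[0].keys()) if flattened else _candidate_columns()
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(columns)
            for d in flattened:
                writer.writerow([_cell(d[c]) for c in columns])
    elif format == "json":
        with open(path, "w") as handle:
            json.dump(flattened, handle, indent=2, sort_keys=False)
            handle.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _candidate_columns() -> list[str]:
    from circscan.pipeline import CANDIDATE_COLUMNS

    return CANDIDATE_COLUMNS


def load_bundled_candidate_table() -> list[AnnotationRow]:
    """Load the bundled 57-row colorectal-cancer candidate circRNA table
    (pre-filtered differential-expression survivors with printed log2FC)."""
    ref = resources.files("circscan.data").joinpath("crc_candidates.tsv")
    with resources.as_file(ref) as path:
        return read_annotation_table(path)
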