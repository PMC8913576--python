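import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from circscan.seq_io import AnnotationRow, CircRNARecord, ProteinRecord
from circscan.simulate import make_circ_with_orf, make_host_protein


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def simple_circle():
    """Hand-readable circle: single linear ORF ATG AAA GGG TAG."""
    return CircRNARecord(circ_id="toy1", sequence="ATGAAAGGGTAG")


@pytest.fixture
def wrapping_circle():
    """Same ORF rotated so that it wraps the junction (start at 8)."""
    return CircRNARecord(circ_id="toy2", sequence="AAGGGTAGATGA")


@pytest.fixture(scope="session")
def planted_pass():
    """A 300-nt circle with one junction-spanning 60-aa ORF plus a matching
    half-shared host protein."""
    rec, truth = make_circ_with_orf(300, 60, 270, True, 0, seed=77, circ_id="planted1")
    host = make_host_protein(
        truth.peptide, 30, 120, seed=77, protein_id="host1", gene="HOSTG"
    )
    return rec, truth, host


@pytest.fixture
def nucleotide_fasta(tmp_path):
    path = tmp_path / "circ.fa"
    path.write_text(">circA desc\nATGAAAGGGTAG\n>circB\nAAGGGTAGATGA\n")
    return path


@pytest.fixture
def annotation_tsv(tmp_path):
    path = tmp_path / "ann.tsv"
    path.write_text(
        "circ_id\tlog2fc\tadj_p\thost_gene\ttranscript\tgenomic_position\tdb_coding_flag\n"
        "circA\t2.50\t0.01\tGENE1\tNM_000001\tchr1:100-200\ttrue\n"
        "circB\t-1.30\t0.02\tGENE2\tNM_000002\tchr2:300-400\t\n"
    )
    return path
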