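# circscan

Scan circular RNA (circRNA) mature sequences for peptide-coding potential.

Circular transcripts can be translated across their back-splice junction and
even around the circle more than once (rolling-circle reading), so ordinary
linear ORF finders miss or mangle their coding capacity. `circscan`
implements the full candidate funnel for coding circRNAs:

1. **Differential-expression gate** — strict |log2FC| > 1 and BH-adjusted
   p < 0.05, either from a precomputed table or from a two-group expression
   matrix via Welch t + Benjamini–Hochberg.
2. **Circular ORF scan** — every ATG start is walked with wraparound for up
   to 3 laps (provably exhaustive: frames cycle with period 3 when the
   circle length is not a multiple of 3); ORFs that never meet an in-frame
   stop are flagged *infinite* and excluded.
3. **Candidate rules** — the ORF must span the junction, encode strictly
   more than 50 amino acids, and reuse strictly fewer than 50 bases.
4. **External database flag gate** — optional boolean coding-potential
   verdicts consumed as annotations (no database queries are performed).
5. **Uniqueness gate** — residues of the circ-peptide not explainable by any
   exact host-protein match of ≥ 7 aa are counted; strictly more than 2
   unique residues are required for MS identifiability.
6. **MS support** — in-silico tryptic digestion (cleave after K/R, not
   before P), selection of evidence peptides covering unique residues,
   monoisotopic/average masses, and a protein-FASTA search database.

Every candidate carries per-stage pass/fail/skipped provenance; nothing is
silently dropped. A synthetic-fixture generator plants ORFs of exact
geometry (junction spanning, overlay, length) with verified ground truth so
the whole pipeline is testable without any downloads.

## CLI

```sh
# full funnel: candidates.tsv/.json + summary.json + effective config
circscan scan --circ-fasta circles.fa --annotations ann.tsv --hosts hosts.fa --out out/

# individual stages
circscan orfs --circ-fasta circles.fa --min-aa 51 --max-overlay 49
circscan unique --peptide-fasta peps.fa --hosts hosts.fa
circscan digest --peptide-fasta peps.fa
circscan defilter --annotations ann.tsv --lfc-cut 1 --q-cut 0.05

# synthetic fixtures with planted truth
circscan simulate --out sim/ --seed 7 --n-circ 10
```

The annotation TSV has header
`circ_id  log2fc  adj_p  host_gene  transcript  genomic_position  db_coding_flag`;
`adj_p` may be blank for tables already filtered upstream (pass
`--pre-filtered`). Exit codes: 0 success, 1 usage error, 2 data error.

## Python API

```python
from circscan import (CircRNARecord, OrfParams, find_circular_orfs,
                      filter_orfs, uniqueness_report, tryptic_digest)

rec = CircRNARecord(circ_id="c1", sequence="AAGGGTAGATGA")
orfs = find_circular_orfs(rec)           # finds the junction-wrapping ORF
kept = filter_orfs(orfs, OrfParams())    # strict >50 aa / <50 bp rules
```

Coordinates are 0-based half-open; the back-splice junction sits between the
last and first base of the supplied rotation, and `spans_junction` is true
when `start_nt + orf_len_nt > L`. `overlay_bp = max(0, orf_len_nt - L)`
counts bases read more than once.

## Tests

```sh
python -m pytest -q tests/
```

The suite validates the scanner against a brute-force modular-index walker
(exhaustively at small circle lengths), checks rotation covariance,
frame-cycle exhaustiveness, digest/mass identities, and end-to-end planted
recovery across 100 seeds. `tests/test_acceptance.py` holds the acceptance
criteria; two tests are skipped unless externally downloaded sequences are
provided via `CIRCSCAN_EXTERNAL_DIR`.

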