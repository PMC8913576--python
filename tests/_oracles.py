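"""Independent brute-force oracles used to validate the implementation.

Everything in this module is deliberately written in the most literal way
possible (explicit modular indexing, exhaustive enumeration, textbook
formulas) and shares no code with the package under test.
"""

from __future__ import annotations

import math

from Bio.Seq import Seq

ORACLE_STOPS = {"TAA", "TAG", "TGA"}


def oracle_translate(codon_string: str) -> str:
    """Independent translation via Biopython (ACGT-only input)."""
    return str(Seq(codon_string).translate())


def oracle_circular_orfs(seq: str, max_cycles: int = 3):
    """Walk every start position with explicit modular indexing.

    Returns (complete, infinite): complete is a set of
    (start, orf_len_nt, peptide) tuples, infinite a set of start positions.
    """
    L = len(seq)
    complete = set()
    infinite = set()
    for s in range(L):
        start_codon = "".join(seq[(s + k) % L] for k in range(3))
        if start_codon != "ATG":
            continue
        residues = []
        stopped = False
        for i in range((max_cycles * L) // 3):
            codon = "".join(seq[(s + 3 * i + k) % L] for k in range(3))
            if codon in ORACLE_STOPS:
                complete.add((s, 3 * (i + 1), "".join(residues)))
                stopped = True
                break
            residues.append(oracle_translate(codon))
        if not stopped:
            infinite.add(s)
    return complete, infinite


def oracle_lcs_length(a: str, b: str):
    """Exhaustive O(n^2 * m) longest-common-substring search."""
    best = (0, 0, 0)
    found = False
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            sub = a[i:j]
            pos = b.find(sub)
            if pos >= 0:
                length = j - i
                if not found or length > best[0]:
                    best = (length, i, pos)
                    found = True
    return best


def oracle_covered_positions(peptide: str, hosts, min_match: int) -> set:
    """Every peptide position inside some exact host match of length >= k."""
    covered = set()
    for host in hosts:
        for i in range(len(peptide)):
            for j in range(i + min_match, len(peptide) + 1):
                if peptide[i:j] in host:
                    covered.update(range(i, j))
    return covered


def oracle_welch_p(a, b) -> float:
    """Textbook Welch t-test with Welch-Satterthwaite df, via the
    regularized incomplete beta function."""
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # two-sided p from the t CDF via scipy's special function only
    from scipy.special import betainc

    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def oracle_bh(pvals):
    """Literal step-up Benjamini-Hochberg."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        value = min(prev, pvals[i] * m / rank)
        adjusted[i] = value
        prev = value
    return adjusted


def random_circle(rng, min_len: int = 3, max_len: int = 15) -> str:
    L = int(rng.integers(min_len, max_len + 1))
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
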