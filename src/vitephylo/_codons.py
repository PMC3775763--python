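"""Codon tables and codon-level substitution machinery (standard genetic code).

Shared by the sequence simulator (codon GTR model) and the Ks estimator
(Nei–Gojobori site/difference counting).
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCS)}

ALL_CODONS = ["".join(p) for p in product(NUCS, repeat=3)]
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOP_CODONS]
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_TO_AA = dict(standard_dna_table.forward_table)  # sense codons only

# prefixes whose third position is 4-fold degenerate under the standard code
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(q) for q in product(NUCS, repeat=2))
    if len({CODON_TO_AA.get(p + b) for b in NUCS}) == 1
    and all(p + b in CODON_TO_AA for b in NUCS)
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid, '*' for stop, 'X' if ambiguous."""
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    if codon in STOP_CODONS:
        return "*"
    return "X"


# --------------------------------------------------------------- GTR model
def gtr_rate_matrix(exchangeabilities, freqs) -> np.ndarray:
    """4x4 nucleotide GTR rate matrix, normalised to 1 substitution/site.

    Exchangeability order: AC, AG, AT, CG, CT, GT.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if s.shape != (6,) or np.any(s <= 0):
        raise ValueError("need 6 positive exchangeabilities (AC,AG,AT,CG,CT,GT)")
    if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-9 or np.any(pi <= 0):
        raise ValueError("base frequencies must be 4 positive values summing to 1")
    Q = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        Q[i, j] = s[k] * pi[j]
        Q[j, i] = s[k] * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def codon_rate_matrix(exchangeabilities, freqs) -> tuple[np.ndarray, np.ndarray]:
    """61-state sense-codon rate matrix built from a nucleotide GTR model.

    Single-nucleotide changes only; substitutions into stop codons are
    disallowed (the chain is the GTR chain restricted to sense codons, so it
    stays reversible w.r.t. the product measure over sense codons).  The
    matrix is normalised so one unit of branch length equals one expected
    nucleotide substitution per codon *site* (i.e. 3 per codon at most,
    before the stop-exclusion correction).

    Returns (Q, stationary_codon_frequencies).
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(freqs, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    ex = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for k, (i, j) in enumerate(pairs):
        ex[i, j] = ex[j, i] = s[k]
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            a, b = NUC_INDEX[ci[k]], NUC_INDEX[cj[k]]
            Q[i, j] = ex[a, b] * pi[b]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # stationary: product measure restricted to sense codons
    w = np.array([pi[NUC_INDEX[c[0]]] * pi[NUC_INDEX[c[1]]] * pi[NUC_INDEX[c[2]]]
                  for c in SENSE_CODONS])
    w /= w.sum()
    mu = -(w * np.diag(Q)).sum()  # expected nt substitutions per codon
    Q = Q * (3.0 / mu)            # branch length = nt substitutions per site
    return Q, w


# ------------------------------------------------- Nei–Gojobori NG86 tables
@lru_cache(maxsize=4)
def ng86_site_fractions(stop_mode: str = "exclude") -> np.ndarray:
    """Per-codon synonymous site count (0..3) under NG86.

    Each codon position contributes the fraction of its possible changes
    that are synonymous.  ``stop_mode="exclude"`` (the original method)
    removes mutations to stop codons from the denominator;
    ``"nonsynonymous"`` counts them as nonsynonymous changes (the
    convention of some later implementations).
    """
    syn = np.zeros(len(SENSE_CODONS))
    for i, codon in enumerate(SENSE_CODONS):
        aa = CODON_TO_AA[codon]
        total = 0.0
        for pos in range(3):
            n_valid = 0
            n_syn = 0
            for b in NUCS:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut in STOP_CODONS:
                    if stop_mode == "nonsynonymous":
                        n_valid += 1
                    continue
                n_valid += 1
                if CODON_TO_AA[mut] == aa:
                    n_syn += 1
            if n_valid:
                total += n_syn / n_valid
        syn[i] = total
    return syn


@lru_cache(maxsize=4)
def ng86_difference_tables(stop_mode: str = "exclude",
                           ) -> tuple[np.ndarray, np.ndarray]:
    """(Sd, Nd) matrices: pathway-averaged synonymous / nonsynonymous
    difference counts between every ordered pair of sense codons.

    With ``stop_mode="exclude"`` (original method) pathways passing through
    a stop codon are dropped from the average (if every pathway hits a
    stop, the differences count as nonsynonymous); with
    ``"nonsynonymous"`` stop-passing pathways are kept and each step
    to/from a stop counts as a nonsynonymous change.
    """
    n = len(SENSE_CODONS)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            paths = []
            for order in permutations(diffs):
                cur = ci
                s_cnt = n_cnt = 0
                ok = True
                for pos in order:
                    nxt = cur[:pos] + cj[pos] + cur[pos + 1:]
                    if nxt in STOP_CODONS and stop_mode == "exclude":
                        ok = False
                        break
                    if translate_codon(cur) == translate_codon(nxt):
                        s_cnt += 1
                    else:
                        n_cnt += 1
                    cur = nxt
                if ok:
                    paths.append((s_cnt, n_cnt))
            if not paths:
                paths = [(0, len(diffs))]  # all pathways blocked: count as nonsyn
            sd[i, j] = sum(p[0] for p in paths) / len(paths)
            nd[i, j] = sum(p[1] for p in paths) / len(paths)
    return sd, nd
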