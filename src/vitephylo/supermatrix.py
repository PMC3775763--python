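"""Per-family alignment, codon back-translation, missing-data filtering and
concatenation into partitioned nucleotide / amino-acid supermatrices.

The nucleotide matrix is always exactly three times the width of the
amino-acid matrix (each residue column expands to its source codon, each
gap to ``---``).  A gene passes the missing-data filter only when every
taxon's row is at most the allowed fraction missing (gaps plus wholly
absent taxa count as missing; X/N ambiguities count as present).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import similarity
from .trees import nj_tree

__all__ = ["GeneAlignment", "Supermatrix", "progressive_align", "backtranslate",
           "filter_genes_by_missing", "concatenate", "write_phylip",
           "write_partitions"]

GAP = "-"


@dataclass
class GeneAlignment:
    family_id: str
    protein: dict                 # taxon -> aligned protein row
    codon: dict = field(default_factory=dict)  # taxon -> aligned codon row

    @property
    def aa_width(self) -> int:
        return len(next(iter(self.protein.values())))

    def missing_fraction(self, taxon: str) -> float:
        row = self.protein.get(taxon)
        if row is None:
            return 1.0
        return row.count(GAP) / len(row)

    def validate(self) -> None:
        widths = {len(r) for r in self.protein.values()}
        if len(widths) != 1:
            raise ValueError(f"{self.family_id}: ragged protein block")
        if self.codon:
            if set(self.codon) != set(self.protein):
                raise ValueError(f"{self.family_id}: protein/codon row sets differ")
            for t, r in self.codon.items():
                if len(r) != 3 * self.aa_width:
                    raise ValueError(f"{self.family_id}: codon block width "
                                     "is not 3x the protein width")


@dataclass
class Supermatrix:
    taxa: list
    nt: dict                      # taxon -> concatenated nucleotide row
    aa: dict                      # taxon -> concatenated amino-acid row
    partitions: list              # (family_id, aa_start, aa_end, nt_start, nt_end)
    #                               0-based half-open internally

    @property
    def nt_width(self) -> int:
        return len(next(iter(self.nt.values())))

    @property
    def aa_width(self) -> int:
        return len(next(iter(self.aa.values())))


# ----------------------------------------------------------------- profiles
_PROT_ALPHA = "ACDEFGHIKLMNPQRSTVWYX"
_PIDX = {c: i for i, c in enumerate(_PROT_ALPHA)}


def _profile(rows: list[str], M: np.ndarray) -> np.ndarray:
    """Column score-profile: expected substitution score against each residue."""
    ncol = len(rows[0])
    freq = np.zeros((ncol, len(_PROT_ALPHA)))
    occ = np.zeros(ncol)
    for r in rows:
        for j, c in enumerate(r):
            if c != GAP:
                freq[j, _PIDX.get(c, _PIDX["X"])] += 1
                occ[j] += 1
    occ = np.maximum(occ, 1)
    freq /= occ[:, None]
    return freq @ M  # (ncol, alpha): expected score vs each residue


def _profile_align(rows_a: list[str], rows_b: list[str], M: np.ndarray,
                   gap_open: float, gap_extend: float) -> tuple[list, list]:
    """Global affine-gap alignment of two profiles; returns gapped row sets."""
    pa = _profile(rows_a, M)
    fb = np.zeros((len(rows_b[0]), len(_PROT_ALPHA)))
    occ = np.zeros(len(rows_b[0]))
    for r in rows_b:
        for j, c in enumerate(r):
            if c != GAP:
                fb[j, _PIDX.get(c, _PIDX["X"])] += 1
                occ[j] += 1
    fb /= np.maximum(occ, 1)[:, None]
    S = pa @ fb.T  # (na, nb) expected column-column scores

    n, m = S.shape
    NEG = -1e18
    go, ge = gap_open, gap_extend
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -go - ge * j
        H[0, j] = E[0, j]
        ptr[0, j] = 3
        ptrE[0, j] = 1 if j > 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -go - ge * i
        H[i, 0] = F[i, 0]
        ptr[i, 0] = 2
        ptrF[i, 0] = 1 if i > 1 else 0
    for i in range(1, n + 1):
        Hi, Hp, Ei, Fi, Fp = H[i], H[i - 1], E[i], F[i], F[i - 1]
        Si = S[i - 1]
        pi, pei, pfi = ptr[i], ptrE[i], ptrF[i]
        for j in range(1, m + 1):
            e_ext, e_new = Ei[j - 1] - ge, Hi[j - 1] - go - ge
            e = e_ext if e_ext >= e_new else e_new
            pei[j] = 1 if e_ext >= e_new else 0
            f_ext, f_new = Fp[j] - ge, Hp[j] - go - ge
            f = f_ext if f_ext >= f_new else f_new
            pfi[j] = 1 if f_ext >= f_new else 0
            d = Hp[j - 1] + Si[j - 1]
            h = max(d, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            pi[j] = 1 if h == d else (2 if h == f else 3)
    # traceback
    ops = []  # 'M', 'A' (gap in b), 'B' (gap in a)
    i, j, state = n, m, "H"
    while i > 0 or j > 0:
        if state == "H":
            p = ptr[i, j]
            if p == 1:
                ops.append("M")
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            ext = ptrF[i, j]
            ops.append("A")
            i -= 1
            if not ext:
                state = "H"
        else:
            ext = ptrE[i, j]
            ops.append("B")
            j -= 1
            if not ext:
                state = "H"
    ops.reverse()
    out_a, out_b = [], []
    for r in rows_a:
        it = iter(r)
        out_a.append("".join(next(it) if op != "B" else GAP for op in ops))
    for r in rows_b:
        it = iter(r)
        out_b.append("".join(next(it) if op != "A" else GAP for op in ops))
    return out_a, out_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    sa = {a[i:i + k] for i in range(len(a) - k + 1)}
    sb = {b[i:i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(sa & sb) / min(len(sa), len(sb))


def progressive_align(proteins: dict, matrix: Optional[dict] = None,
                      gap_open: float = 11.0, gap_extend: float = 1.0) -> dict:
    """Guide-tree progressive profile alignment of protein sequences.

    Guide tree: k-mer distances + neighbor joining; profiles merged by
    global affine-gap dynamic programming up the tree.  For two sequences
    this reduces to plain global pairwise alignment.
    """
    names = sorted(proteins)
    if len(names) == 1:
        return dict(proteins)
    matrix = matrix or similarity._matrix()
    M = np.zeros((len(_PROT_ALPHA), len(_PROT_ALPHA)))
    for a in _PROT_ALPHA:
        for b in _PROT_ALPHA:
            M[_PIDX[a], _PIDX[b]] = matrix.get((a, b), 0.0)

    if len(names) == 2:
        ra, rb = _profile_align([proteins[names[0]]], [proteins[names[1]]],
                                M, gap_open, gap_extend)
        return {names[0]: ra[0], names[1]: rb[0]}

    D = np.zeros((len(names), len(names)))
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            D[i, j] = D[j, i] = _kmer_distance(proteins[names[i]],
                                               proteins[names[j]])
    guide = nj_tree(D, names)
    blocks: dict[int, tuple[list, list]] = {}  # node id -> (names, rows)
    for node in guide.postorder():
        if node.is_leaf:
            blocks[id(node)] = ([node.name], [proteins[node.name]])
            continue
        cn, cr = blocks.pop(id(node.children[0]))
        for c in node.children[1:]:
            on, orows = blocks.pop(id(c))
            cr, orows = _profile_align(cr, orows, M, gap_open, gap_extend)
            cn, cr = cn + on, cr + orows
        blocks[id(node)] = (cn, cr)
    fn, fr = blocks[id(guide.root)]
    return dict(zip(fn, fr))


def pairwise_global_score(a: str, b: str, matrix: Optional[dict] = None,
                          gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Score of the global affine alignment of two sequences (via the
    profile DP restricted to single sequences)."""
    matrix = matrix or similarity._matrix()
    aligned = progressive_align({"a": a, "b": b}, matrix, gap_open, gap_extend)
    ra, rb = aligned["a"], aligned["b"]
    score, in_gap = 0.0, None
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP:
            which = "a" if x == GAP else "b"
            score -= gap_extend + (gap_open if in_gap != which else 0.0)
            in_gap = which
        else:
            score += matrix[(x, y)]
            in_gap = None
    return score


# ----------------------------------------------------------- backtranslate
def backtranslate(aligned_protein: dict, cds: dict) -> dict:
    """Expand each aligned residue to its source codon, gaps to ``---``.

    Every taxon's CDS must translate (length-wise) to its ungapped row:
    mismatches are a hard error naming the taxon and position.
    """
    from ._codons import translate_codon
    out = {}
    for taxon, row in aligned_protein.items():
        if taxon not in cds:
            raise ValueError(f"no CDS for taxon {taxon!r}")
        seq = cds[taxon]
        if len(seq) % 3 != 0:
            raise ValueError(f"{taxon}: CDS length not divisible by 3")
        nres = sum(1 for c in row if c != GAP)
        if nres != len(seq) // 3:
            raise ValueError(f"{taxon}: CDS has {len(seq) // 3} codons but the "
                             f"aligned row has {nres} residues")
        codons = []
        k = 0
        for pos, c in enumerate(row):
            if c == GAP:
                codons.append("---")
                continue
            codon = seq[3 * k:3 * k + 3]
            aa = translate_codon(codon)
            if aa != c and c != "X" and aa != "X":
                raise ValueError(f"{taxon}: column {pos + 1}: codon {codon} "
                                 f"translates to {aa}, alignment has {c}")
            codons.append(codon)
            k += 1
        out[taxon] = "".join(codons)
    return out


# ------------------------------------------------------------------ filter
def filter_genes_by_missing(alignments: list[GeneAlignment], taxa: list,
                            max_missing_fraction: float = 0.5,
                            quantifier: str = "any"):
    """Drop genes with too much per-taxon missing data.

    ``quantifier="any"`` (default): a gene is dropped as soon as ANY taxon
    exceeds the threshold, i.e. it is retained only when each taxon has at
    most ``max_missing_fraction`` of its row missing.  ``"mean"`` applies
    the threshold to the across-taxa mean instead.  Returns
    ``(retained, drop_log)`` with log rows (family_id, offending taxa).
    """
    if quantifier not in ("any", "mean"):
        raise ValueError("quantifier must be 'any' or 'mean'")
    retained, log = [], []
    for ga in alignments:
        fr = {t: ga.missing_fraction(t) for t in taxa}
        if quantifier == "any":
            bad = sorted(t for t, f in fr.items() if f > max_missing_fraction)
            if bad:
                log.append((ga.family_id, bad))
                continue
        else:
            if np.mean(list(fr.values())) > max_missing_fraction:
                log.append((ga.family_id, sorted(fr)))
                continue
        retained.append(ga)
    return retained, log


# ------------------------------------------------------------- concatenate
def concatenate(alignments: list[GeneAlignment], taxa: list) -> Supermatrix:
    """Concatenate gene alignments in lexicographic family-id order.

    Taxa absent from a gene get all-gap rows across that partition; the
    partition table records both amino-acid and nucleotide column ranges
    (0-based half-open).
    """
    if not alignments:
        raise ValueError("need at least one gene alignment")
    ordered = sorted(alignments, key=lambda g: g.family_id)
    seen = set()
    for g in ordered:
        if g.family_id in seen:
            raise ValueError(f"duplicate family id {g.family_id}")
        seen.add(g.family_id)
        g.validate()
    nt = {t: [] for t in taxa}
    aa = {t: [] for t in taxa}
    partitions = []
    aa_pos = nt_pos = 0
    for g in ordered:
        w = g.aa_width
        for t in taxa:
            aa[t].append(g.protein.get(t, GAP * w))
            if g.codon:
                nt[t].append(g.codon.get(t, GAP * 3 * w))
            else:
                nt[t].append(GAP * 3 * w)
        partitions.append((g.family_id, aa_pos, aa_pos + w,
                           nt_pos, nt_pos + 3 * w))
        aa_pos += w
        nt_pos += 3 * w
    return Supermatrix(list(taxa), {t: "".join(v) for t, v in nt.items()},
                       {t: "".join(v) for t, v in aa.items()}, partitions)


# ---------------------------------------------------------------------- io
def write_phylip(rows: dict, path) -> None:
    taxa = sorted(rows)
    width = len(rows[taxa[0]])
    with open(path, "w") as fh:
        fh.write(f" {len(taxa)} {width}\n")
        for t in taxa:
            fh.write(f"{t}  {rows[t]}\n")


def write_partitions(sm: Supermatrix, path, which: str = "nt") -> None:
    """Partition table in 1-based inclusive ``gene = start-end`` format."""
    with open(path, "w") as fh:
        for fam, a0, a1, n0, n1 in sm.partitions:
            s, e = (n0, n1) if which == "nt" else (a0, a1)
            fh.write(f"{fam} = {s + 1}-{e}\n")


def write_fasta(rows: dict, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(rows):
            fh.write(f">{name}\n{rows[name]}\n")
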