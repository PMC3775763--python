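"""In-house phylogenetic inference.

Neighbor-joining, Fitch parsimony with heuristic search (random stepwise
addition + branch swapping), GTR(+Γ) maximum likelihood via Felsenstein
pruning with an edge-based branch-length optimiser, nonparametric site
bootstrap, outgroup rooting and Robinson–Foulds topology comparison.

Rate heterogeneity uses a discrete gamma approximation (category rates are
the normalised medians of equal-probability quantile bins).  Gaps and
ambiguity codes enter the likelihood as partials of 1 over all compatible
states and parsimony as wildcards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from ._codons import gtr_rate_matrix
from ._tree import Node, Tree, bipartitions, rf_distance, topologies_equal

__all__ = [
    "SubstitutionModel", "nj_tree", "jc_distance_matrix", "fitch_score",
    "mp_search", "gtr_loglik", "ml_search", "bootstrap_support",
    "rf_distance", "topologies_equal", "root_with_outgroup", "Tree",
]

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
MIN_BL, MAX_BL = 1e-8, 10.0


@dataclass
class SubstitutionModel:
    """GTR exchangeabilities (AC,AG,AT,CG,CT,GT), base frequencies A,C,G,T,
    and an optional discrete-gamma shape (``alpha=None`` = rate-homogeneous)."""
    exchangeabilities: tuple = (1.0,) * 6
    freqs: tuple = (0.25,) * 4
    alpha: Optional[float] = None
    ncat: int = 4

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        if abs(f.sum() - 1.0) > 1e-9 or np.any(f <= 0):
            raise ValueError("freqs must be positive and sum to 1")
        if np.any(np.asarray(self.exchangeabilities) <= 0):
            raise ValueError("exchangeabilities must be positive")

    def category_rates(self) -> np.ndarray:
        if self.alpha is None:
            return np.array([1.0])
        a = self.alpha
        q = (np.arange(self.ncat) + 0.5) / self.ncat
        r = gamma_dist.ppf(q, a, scale=1.0 / a)
        return r / r.mean()


def empirical_model(alignment: dict, alpha: Optional[float] = None,
                    ncat: int = 4) -> SubstitutionModel:
    """GTR model with empirical base frequencies and unit exchangeabilities."""
    counts = np.zeros(4)
    for s in alignment.values():
        for b, i in _NT_INDEX.items():
            counts[i] += s.count(b)
    total = counts.sum()
    freqs = counts / total if total else np.full(4, 0.25)
    freqs = np.clip(freqs, 1e-6, None)
    freqs /= freqs.sum()
    return SubstitutionModel(freqs=tuple(freqs), alpha=alpha, ncat=ncat)


# --------------------------------------------------------------- encoding
def encode_alignment(alignment: dict) -> tuple[list, np.ndarray]:
    """Encode a nucleotide alignment as A=0 C=1 G=2 T=3, anything else 4."""
    names = sorted(alignment)
    width = {len(alignment[n]) for n in names}
    if len(width) != 1:
        raise ValueError("alignment rows have unequal lengths")
    mat = np.full((len(names), width.pop()), 4, dtype=np.uint8)
    for i, n in enumerate(names):
        row = np.frombuffer(alignment[n].upper().encode(), dtype="S1")
        for b, v in _NT_INDEX.items():
            mat[i, row == b.encode()] = v
    return names, mat


def compress_patterns(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    return pats, counts.astype(float)


# -------------------------------------------------------------- distances
def jc_distance_matrix(alignment: dict) -> tuple[list, np.ndarray]:
    """Pairwise Jukes–Cantor distances (sites where both rows are ACGT)."""
    names, mat = encode_alignment(alignment)
    n = len(names)
    D = np.zeros((n, n))
    ok = mat < 4
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = both.sum()
            if m == 0:
                D[i, j] = D[j, i] = MAX_BL
                continue
            p = (mat[i, both] != mat[j, both]).sum() / m
            p = min(p, 0.74999)
            d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            D[i, j] = D[j, i] = d
    return names, D


# ---------------------------------------------------------------------- NJ
def nj_tree(dist: np.ndarray, names: list) -> Tree:
    """Neighbor-joining; returns an unrooted tree (trifurcating root).

    Negative branch lengths are clamped to zero with the deficit shifted
    to the sister edge.
    """
    D = np.asarray(dist, float).copy()
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be square, symmetric, zero-diagonal")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(nm) for nm in names]
    active = list(range(n))
    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (k - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        parent = Node()
        nodes[ai].length = li
        nodes[aj].length = lj
        parent.add_child(nodes[ai])
        parent.add_child(nodes[aj])
        # distances from the new node
        new_d = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D[ai, :] = new_d
        D[:, ai] = new_d
        D[ai, ai] = 0.0
        nodes[ai] = parent
        active.remove(aj)
    # join the final three
    a, b, c = active
    root = Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
        root.add_child(nodes[idx])
    return Tree(root)


# -------------------------------------------------------------- parsimony
_FITCH_CODE = np.array([1, 2, 4, 8, 15], dtype=np.uint8)  # A C G T other


def fitch_score(tree: Tree, alignment: dict,
                weights: Optional[np.ndarray] = None,
                _enc: Optional[tuple] = None,
                _allow_subset: bool = False) -> int:
    """Minimum number of state changes (Fitch), gaps/ambiguities as wildcards."""
    if _enc is None:
        names, mat = encode_alignment(alignment)
        pats, w = compress_patterns(mat)
    else:
        names, pats, w = _enc
    if weights is not None:
        w = weights
    tree_names = sorted(tree.leaf_names())
    subset_ok = _allow_subset and set(tree_names) <= set(names)
    if tree_names != names and not subset_ok:
        raise ValueError(
            f"tree/alignment leaf mismatch: only-in-tree="
            f"{sorted(set(tree_names) - set(names))}, only-in-alignment="
            f"{sorted(set(names) - set(tree_names))}")
    row = {nm: i for i, nm in enumerate(names)}
    codes = _FITCH_CODE[pats]
    changes = np.zeros(pats.shape[1])
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[id(node)] = codes[row[node.name]]
            continue
        acc = sets.pop(id(node.children[0]))
        for c in node.children[1:]:
            other = sets.pop(id(c))
            inter = acc & other
            empty = inter == 0
            changes += empty * 1.0
            acc = np.where(empty, acc | other, inter)
        sets[id(node)] = acc
    return int(round((changes * w).sum()))


def _random_addition_tree(names: list, rng) -> tuple[Tree, list]:
    order = list(names)
    rng.shuffle(order)
    return order


def _insert_leaf_on_edge(tree: Tree, edge_child: Node, leaf_name: str) -> Node:
    """Split the edge above ``edge_child`` and attach a new leaf (in place)."""
    parent = edge_child.parent
    mid = Node()
    i = parent.children.index(edge_child)
    parent.children[i] = mid
    mid.parent = parent
    mid.length = edge_child.length / 2
    edge_child.length /= 2
    mid.add_child(edge_child)
    leaf = Node(leaf_name, 1.0)
    mid.add_child(leaf)
    return mid


def _remove_leaf(tree: Tree, leaf: Node) -> None:
    mid = leaf.parent
    mid.children.remove(leaf)
    tree._suppress_unifurcations()


def _all_edges(tree: Tree) -> list:
    return [n for n in tree.postorder() if n.parent is not None]


def _nni_candidates(tree: Tree):
    """Yield (edge_child, child_of_edge_child, sibling) swap triples."""
    for c in tree.postorder():
        p = c.parent
        if p is None or c.is_leaf:
            continue
        others = [z for z in p.children if z is not c]
        if not others:
            continue
        z = others[0]
        for x in c.children:
            yield c, x, z


def _apply_nni(c: Node, x: Node, z: Node) -> None:
    """Swap subtree x (child of c) with subtree z (sibling of c), in place."""
    p = c.parent
    ic, iz = c.children.index(x), p.children.index(z)
    c.children[ic], p.children[iz] = z, x
    z.parent, x.parent = c, p


def mp_search(alignment: dict, n_random_additions: int = 10,
              swap: str = "nni", seed: int = 0,
              keep_all_best: bool = True) -> tuple[list, int]:
    """Heuristic maximum-parsimony search.

    Random stepwise-addition starting trees followed by hill-climbing
    branch swapping (``nni`` or ``spr``; ``tbr`` runs the SPR scan, the
    documented simplification at this problem scale).  All distinct
    equally-best topologies found are retained.  Returns
    ``(best_trees, best_score)``.
    """
    names, mat = encode_alignment(alignment)
    if len(names) < 4:
        raise ValueError("need at least 4 taxa")
    pats, w = compress_patterns(mat)
    enc = (names, pats, w)
    rng = np.random.default_rng(seed)

    def score(t: Tree) -> int:
        return fitch_score(t, alignment, _enc=enc, _allow_subset=True)

    best_score = None
    best: dict[frozenset, Tree] = {}
    for _ in range(n_random_additions):
        order = list(names)
        rng.shuffle(order)
        root = Node()
        for nm in order[:3]:
            root.add_child(Node(nm, 1.0))
        tree = Tree(root)
        for nm in order[3:]:
            cand = []
            for e in _all_edges(tree):
                mid = _insert_leaf_on_edge(tree, e, nm)
                cand.append((score(tree), id(e)))
                leaf = [c for c in mid.children if c.name == nm][0]
                _remove_leaf(tree, leaf)
            best_edge_score = min(cand)[0]
            for e in _all_edges(tree):
                mid = _insert_leaf_on_edge(tree, e, nm)
                if score(tree) == best_edge_score:
                    break
                leaf = [c for c in mid.children if c.name == nm][0]
                _remove_leaf(tree, leaf)
        # hill climb
        s = score(tree)
        improved = True
        while improved:
            improved = False
            moves = _spr_moves(tree) if swap in ("spr", "tbr") else None
            if swap == "nni":
                for c, x, z in list(_nni_candidates(tree)):
                    _apply_nni(c, x, z)
                    s2 = score(tree)
                    if s2 < s:
                        s = s2
                        improved = True
                        break  # re-enumerate: candidate list is now stale
                    _apply_nni(c, z, x)  # revert
            else:
                for prune, regraft in moves:
                    t2 = _spr_apply(tree, prune, regraft)
                    if t2 is None:
                        continue
                    s2 = score(t2)
                    if s2 < s:
                        tree, s = t2, s2
                        improved = True
                        break
        key = frozenset(bipartitions(tree))
        if best_score is None or s < best_score:
            best_score = s
            best = {key: tree}
        elif s == best_score and keep_all_best and key not in best:
            best[key] = tree
    return list(best.values()), int(best_score)


def _spr_moves(tree: Tree) -> list:
    edges = _all_edges(tree)
    return [(i, j) for i in range(len(edges)) for j in range(len(edges)) if i != j]


def _spr_apply(tree: Tree, prune_idx: int, regraft_idx: int) -> Optional[Tree]:
    t = tree.copy()
    edges = _all_edges(t)
    if prune_idx >= len(edges) or regraft_idx >= len(edges):
        return None
    sub = edges[prune_idx]
    target = edges[regraft_idx]
    # target must not be inside the pruned subtree (or be its parent edge)
    n = target
    while n is not None:
        if n is sub:
            return None
        n = n.parent
    p = sub.parent
    p.children.remove(sub)
    sub.parent = None
    t._suppress_unifurcations()
    edges_after = _all_edges(t)
    if target not in edges_after:
        return None
    mid = Node()
    tp = target.parent
    i = tp.children.index(target)
    tp.children[i] = mid
    mid.parent = tp
    mid.length = target.length / 2
    target.length /= 2
    mid.add_child(target)
    mid.add_child(sub)
    if len(t.root.children) < 2:
        return None
    return t


# ------------------------------------------------------------- likelihood
class PruningEngine:
    """Felsenstein pruning with pattern compression and edge-based
    branch-length optimisation for one alignment + model."""

    def __init__(self, alignment: dict, model: SubstitutionModel):
        self.model = model
        self.names, mat = encode_alignment(alignment)
        self.patterns, self.weights = compress_patterns(mat)
        self.nsites = mat.shape[1]
        self._row = {nm: i for i, nm in enumerate(self.names)}
        self.freqs = np.asarray(model.freqs, float)
        Q = gtr_rate_matrix(model.exchangeabilities, model.freqs)
        d = np.sqrt(self.freqs)
        # S = D Q D^-1 with D = diag(sqrt(pi)) is symmetric for reversible Q
        S = Q * d[:, None] / d[None, :]
        lam, U = np.linalg.eigh((S + S.T) / 2)
        self._lam = lam
        self._U = U
        self._dinv = 1.0 / d
        self._d = d
        self.rates = model.category_rates()
        self._leaf_table = np.vstack([np.eye(4), np.ones((1, 4))])
        self._pcache: dict[float, np.ndarray] = {}

    # transition matrices for all categories, shape (ncat, 4, 4)
    def pmatrices(self, t: float) -> np.ndarray:
        P = self._pcache.get(t)
        if P is None:
            ts = np.clip(t, MIN_BL, MAX_BL) * self.rates
            e = np.exp(self._lam[None, :] * ts[:, None])  # (ncat, 4)
            A = self._U[None, :, :] * e[:, None, :]
            # expm(Qt) = D^-1 U e^(lam t) U^T D
            P = (self._dinv[None, :, None] * A) @ (self._U.T[None, :, :] *
                                                   self._d[None, None, :])
            np.clip(P, 1e-300, None, out=P)
            if len(self._pcache) < 8192:
                self._pcache[t] = P
        return P

    def leaf_partial(self, name: str) -> np.ndarray:
        return self._leaf_table[self.patterns[self._row[name]]]  # (npat, 4)

    def _down(self, tree: Tree):
        """Postorder conditional partials; returns (down, scale) dicts."""
        down, scale = {}, {}
        for node in tree.postorder():
            if node.is_leaf:
                down[id(node)] = np.broadcast_to(
                    self.leaf_partial(node.name),
                    (len(self.rates), self.patterns.shape[1], 4))
                scale[id(node)] = 0.0
                continue
            acc = None
            sc = 0.0
            for c in node.children:
                P = self.pmatrices(c.length)
                msg = down[id(c)] @ np.transpose(P, (0, 2, 1))
                acc = msg if acc is None else acc * msg
                sc = sc + scale[id(c)]
            m = acc.max(axis=(0, 2))
            m = np.where(m > 0, m, 1.0)
            acc = acc / m[None, :, None]
            down[id(node)] = acc
            scale[id(node)] = sc + np.log(m)
        return down, scale

    def loglik(self, tree: Tree) -> float:
        down, scale = self._down(tree)
        r = down[id(tree.root)]
        site = (r * self.freqs[None, None, :]).sum(axis=2).mean(axis=0)
        return float((self.weights * (np.log(site) + scale[id(tree.root)])).sum())

    # ---------------------------------------------------- edge machinery
    def _out_partials(self, tree: Tree, down, scale):
        """Preorder 'rest of tree' partials per non-root node (f of parent state)."""
        out, oscale = {}, {}
        for node in tree.preorder():
            for c in node.children:
                acc = None
                sc = 0.0
                for s in node.children:
                    if s is c:
                        continue
                    P = self.pmatrices(s.length)
                    msg = down[id(s)] @ np.transpose(P, (0, 2, 1))
                    acc = msg if acc is None else acc * msg
                    sc = sc + scale[id(s)]
                if node.parent is not None:
                    P = self.pmatrices(node.length)
                    msg = out[id(node)] @ np.transpose(P, (0, 2, 1))
                    acc = msg if acc is None else acc * msg
                    sc = sc + oscale[id(node)]
                if acc is None:  # root with a single child (degenerate)
                    acc = np.ones((len(self.rates), self.patterns.shape[1], 4))
                m = acc.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                acc = acc / m[None, :, None]
                out[id(c)] = acc
                oscale[id(c)] = sc + np.log(m)
        return out, oscale

    def _edge_loglik(self, node: Node, t: float, down, scale, out, oscale) -> float:
        left = out[id(node)] * self.freqs[None, None, :]
        const = float((self.weights *
                       (scale[id(node)] + oscale[id(node)])).sum())
        return self._edge_loglik_fast(t, left, down[id(node)], const)

    def _edge_loglik_fast(self, t: float, left, down_n, const: float) -> float:
        P = self.pmatrices(t)
        site = ((left @ P) * down_n).sum(axis=2).mean(axis=0)
        site = np.clip(site, 1e-300, None)
        return float(self.weights @ np.log(site)) + const

    def nni_screen(self, tree: Tree) -> list:
        """Log-likelihood of every NNI neighbour at current branch lengths.

        Uses one partial-computation pass plus local message substitution
        around each internal edge (exact, up to floating-point error), so
        screening all moves costs about two tree traversals instead of one
        per move.  Returns ``[(loglik, (c, x, z)), ...]`` matching
        ``_nni_candidates``.
        """
        down, dscale = self._down(tree)
        out, oscale = self._out_partials(tree, down, dscale)
        msg: dict[int, np.ndarray] = {}

        def get_msg(n: Node) -> np.ndarray:
            m = msg.get(id(n))
            if m is None:
                P = self.pmatrices(n.length)
                m = down[id(n)] @ np.transpose(P, (0, 2, 1))
                msg[id(n)] = m
            return m

        results = []
        for c, x, z in _nni_candidates(tree):
            y = next(ch for ch in c.children if ch is not x)
            m_x, m_y, m_z = get_msg(x), get_msg(y), get_msg(z)
            down_c = m_z * m_y
            dsc = dscale[id(z)] + dscale[id(y)]
            out_c = out[id(c)] * (m_x / m_z)
            osc = oscale[id(c)] + dscale[id(x)] - dscale[id(z)]
            P = self.pmatrices(c.length)
            left = out_c * self.freqs[None, None, :]
            site = ((left @ P) * down_c).sum(axis=2).mean(axis=0)
            site = np.clip(site, 1e-300, None)
            ll = float((self.weights * (np.log(site) + dsc + osc)).sum())
            results.append((ll, (c, x, z)))
        return results

    def optimize_branch_lengths(self, tree: Tree, sweeps: int = 2,
                                xatol: float = 1e-6) -> float:
        """Sweep Brent optimisation over every edge.

        Partials are computed once per sweep, so within a sweep each edge
        is optimised against slightly stale neighbours (Jacobi-style); a
        sweep that decreases the joint likelihood is reverted, which keeps
        the whole procedure monotone.
        """
        ll = self.loglik(tree)
        for _ in range(sweeps):
            old = {id(n): n.length for n in tree.postorder()}
            down, scale = self._down(tree)
            out, oscale = self._out_partials(tree, down, scale)
            for node in tree.preorder():
                if node.parent is None:
                    continue
                left = out[id(node)] * self.freqs[None, None, :]
                down_n = down[id(node)]
                const = float((self.weights *
                               (scale[id(node)] + oscale[id(node)])).sum())
                f = lambda t: -self._edge_loglik_fast(t, left, down_n, const)
                res = minimize_scalar(f, bounds=(MIN_BL, MAX_BL),
                                      method="bounded",
                                      options={"xatol": xatol})
                node.length = float(res.x)
            ll_new = self.loglik(tree)
            if ll_new < ll:
                for n in tree.postorder():
                    n.length = old[id(n)]
                break
            if ll_new - ll < 1e-9 * max(1.0, abs(ll)):
                ll = ll_new
                break
            ll = ll_new
        return ll


def gtr_loglik(tree: Tree, alignment: dict,
               model: Optional[SubstitutionModel] = None) -> float:
    """Log-likelihood of a (branch-length-bearing) tree under GTR(+Γ)."""
    model = model or SubstitutionModel()
    eng = PruningEngine(alignment, model)
    missing = set(eng.names) ^ set(tree.leaf_names())
    if missing:
        raise ValueError(f"tree/alignment leaf mismatch: {sorted(missing)}")
    return eng.loglik(tree)


def ml_search(alignment: dict, model: Optional[SubstitutionModel] = None,
              start: Optional[Tree] = None, seed: int = 0,
              max_nni_rounds: int = 20, bl_sweeps: int = 2,
              tol: float = 1e-6, xatol: float = 1e-6,
              engine: Optional[PruningEngine] = None,
              ) -> tuple[Tree, float]:
    """Maximum-likelihood tree search: NJ start, edge-length optimisation,
    greedy NNI hill climbing.  Returns (tree, log-likelihood)."""
    names = sorted(alignment)
    if len(names) < 4:
        raise ValueError("need at least 4 taxa")
    if model is None:
        model = empirical_model(alignment)
    eng = engine or PruningEngine(alignment, model)
    if start is None:
        nm, D = jc_distance_matrix(alignment)
        tree = nj_tree(D, nm)
    else:
        tree = start.copy().unroot()
    for n in tree.postorder():
        if n.parent is not None:
            n.length = float(np.clip(n.length, 1e-6, MAX_BL))
    ll = eng.optimize_branch_lengths(tree, sweeps=bl_sweeps, xatol=xatol)
    for _ in range(max_nni_rounds):
        # screen all NNI moves at current branch lengths
        scored = eng.nni_screen(tree)
        scored.sort(key=lambda s: -s[0])
        if scored and scored[0][0] - ll > tol:
            _apply_nni(*scored[0][1])
            ll = eng.optimize_branch_lengths(tree, sweeps=1, xatol=xatol)
            continue
        # no move improves at stale lengths: re-score the best few with
        # branch-length optimisation before giving up
        accepted = False
        for _llscr, move in scored[:3]:
            saved = {id(n): n.length for n in tree.postorder()}
            _apply_nni(*move)
            ll2 = eng.optimize_branch_lengths(tree, sweeps=1, xatol=xatol)
            if ll2 - ll > tol:
                ll = ll2
                accepted = True
                break
            c, x, z = move
            _apply_nni(c, z, x)
            for n in tree.postorder():
                n.length = saved[id(n)]
        if not accepted:
            break
    return tree, ll


def bootstrap_support(alignment: dict, builder: str = "ml",
                      n_replicates: int = 100, seed: int = 0,
                      model: Optional[SubstitutionModel] = None,
                      tree: Optional[Tree] = None,
                      bl_sweeps: int = 1, max_nni_rounds: int = 5,
                      ) -> tuple[Tree, dict]:
    """Nonparametric site bootstrap with a fast replicate strategy.

    Sites are resampled with replacement (as multinomial pattern weights);
    each replicate search restarts from the full-data tree with NNI-only
    refinement.  Support (0–100) is the percentage of replicate trees
    containing each internal bipartition; values are written onto the best
    tree's internal nodes.  Returns ``(best_tree, {bipartition: support})``.
    """
    rng = np.random.default_rng(seed)
    if model is None:
        model = empirical_model(alignment)
    if builder == "ml":
        eng = PruningEngine(alignment, model)
        if tree is None:
            tree, _ = ml_search(alignment, model, engine=eng, seed=seed)
        base_w = eng.weights.copy()
        nsites = int(base_w.sum())
        probs = base_w / base_w.sum()
        counts: dict[frozenset, int] = {}
        for _ in range(n_replicates):
            eng.weights = rng.multinomial(nsites, probs).astype(float)
            rep = tree.copy()
            if bl_sweeps > 0:
                eng.optimize_branch_lengths(rep, sweeps=bl_sweeps)
            ll = eng.loglik(rep)
            for _r in range(max_nni_rounds):
                best_gain, best_move = 0.0, None
                for ll2, move in eng.nni_screen(rep):
                    if ll2 - ll > best_gain + 1e-6:
                        best_gain, best_move = ll2 - ll, move
                if best_move is None:
                    break
                _apply_nni(*best_move)
                ll = eng.loglik(rep)
            for bp in bipartitions(rep):
                counts[bp] = counts.get(bp, 0) + 1
        eng.weights = base_w
    elif builder == "mp":
        names, mat = encode_alignment(alignment)
        pats, base_w = compress_patterns(mat)
        enc = (names, pats, base_w)
        if tree is None:
            trees_, _ = mp_search(alignment, n_random_additions=5, seed=seed)
            tree = trees_[0]
        nsites = int(base_w.sum())
        probs = base_w / base_w.sum()
        counts = {}
        for _ in range(n_replicates):
            w = rng.multinomial(nsites, probs).astype(float)
            rep = tree.copy()
            s = fitch_score(rep, alignment, weights=w, _enc=enc)
            improved = True
            while improved:
                improved = False
                for c, x, z in list(_nni_candidates(rep)):
                    _apply_nni(c, x, z)
                    s2 = fitch_score(rep, alignment, weights=w, _enc=enc)
                    if s2 < s:
                        s = s2
                        improved = True
                        break  # re-enumerate: candidate list is now stale
                    _apply_nni(c, z, x)
            for bp in bipartitions(rep):
                counts[bp] = counts.get(bp, 0) + 1
    else:
        raise ValueError("builder must be 'ml' or 'mp'")

    support = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    # annotate internal nodes of the best tree
    names_all = sorted(tree.leaf_names())
    ref = names_all[0]
    full = frozenset(names_all)
    below: dict[int, frozenset] = {}
    for n in tree.postorder():
        if n.is_leaf:
            below[id(n)] = frozenset([n.name])
        else:
            s = frozenset().union(*(below[id(c)] for c in n.children))
            below[id(n)] = s
            if n.parent is not None and 2 <= len(s) <= len(names_all) - 2:
                side = s if ref not in s else full - s
                n.support = support.get(side, 0.0)
    return tree, support


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Root on the outgroup's pendant edge (at its midpoint)."""
    leaf = tree.find_leaf(outgroup)  # raises KeyError if absent
    return tree.reroot_on_edge(leaf, fraction=0.5)
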