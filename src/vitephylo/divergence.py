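"""4-fold degenerate site extraction, strict-clock Bayesian node dating, and
Nei–Gojobori Ks estimation for paralog / whole-genome-duplication screening.

Dating is a deliberately simple strict-clock Metropolis–Hastings sampler:
node ages (child < parent) and a single substitution rate, likelihood from
Felsenstein pruning on the 4-fold-degenerate-site matrix with branch
lengths = rate x duration, normal calibration priors on chosen nodes and a
diffuse lognormal prior on the rate.  Uncalibrated node ages carry a
uniform prior over the order polytope normalised per root age (so with no
data the calibrated root's posterior reproduces its prior exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import trees as tr
from ._codons import (FOURFOLD_PREFIXES, SENSE_INDEX, ng86_difference_tables,
                      ng86_site_fractions)
from ._tree import Node, Tree

__all__ = ["CalibrationPrior", "DatedTree", "KsPair", "fourfold_sites",
           "strict_clock_date", "ks_pair", "ks_distribution"]


@dataclass
class CalibrationPrior:
    """Normal prior (mean, sd in Ma) on the age of a named clade's node.

    ``taxa`` lists leaves whose MRCA is calibrated ("root" = tree root);
    ``point="stem"`` moves the calibration to that node's parent edge node.
    """
    taxa: object                  # list of leaf names, or the string "root"
    mean: float
    sd: float
    point: str = "crown"

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("calibration sd must be positive")
        if self.point not in ("crown", "stem"):
            raise ValueError("point must be 'crown' or 'stem'")

    def resolve(self, tree: Tree) -> Node:
        if isinstance(self.taxa, str) and self.taxa == "root":
            node = tree.root
        else:
            node = tree.mrca(set(self.taxa))
        if self.point == "stem":
            if node.parent is None:
                raise ValueError("stem calibration on the root is undefined")
            node = node.parent
        if node.is_leaf:
            raise ValueError("calibration resolves to a leaf")
        return node


@dataclass
class DatedTree:
    tree: Tree                    # rooted topology with posterior-mean ages
    summary: pd.DataFrame         # node_id, clade, mean, lo95, hi95
    age_samples: dict             # node_id -> np.ndarray of posterior ages
    rate_samples: np.ndarray
    acceptance: dict


# ------------------------------------------------------------ 4-fold sites
def fourfold_sites(codon_alignment: dict) -> dict:
    """Third positions of codon columns that are 4-fold degenerate in EVERY
    taxon (ungapped, unambiguous, same 4-fold family membership required
    per taxon — the strict intersection rule, which guarantees the site is
    synonymous on the whole tree)."""
    taxa = sorted(codon_alignment)
    width = {len(v) for v in codon_alignment.values()}
    if len(width) != 1:
        raise ValueError("ragged alignment")
    w = width.pop()
    if w % 3 != 0:
        raise ValueError("alignment width not divisible by 3")
    keep = []
    for c0 in range(0, w, 3):
        ok = True
        for t in taxa:
            codon = codon_alignment[t][c0:c0 + 3]
            if codon not in SENSE_INDEX or codon[:2] not in FOURFOLD_PREFIXES:
                ok = False
                break
        if ok:
            keep.append(c0 + 2)
    return {t: "".join(codon_alignment[t][i] for i in keep) for t in taxa}


# ------------------------------------------------------------------ dating
class _IncrementalClockLik:
    """Clock-tree likelihood with per-node partial caching.

    Branch lengths are (parent age - child age) * rate.  A single node-age
    move only perturbs the edges meeting that node, so only its own and its
    ancestors' partials are recomputed; a rate move recomputes everything.
    ``revert()`` undoes the partial updates of the last rejected proposal.
    """

    def __init__(self, eng, tree: Tree):
        self.eng = eng
        self.tree = tree
        self.down: dict[int, np.ndarray] = {}
        self.scale: dict[int, object] = {}
        self.rate: Optional[float] = None
        self._saved: Optional[list] = None

    def _compute_node(self, n: Node, rate: float) -> None:
        eng = self.eng
        if n.is_leaf:
            self.down[id(n)] = np.broadcast_to(
                eng.leaf_partial(n.name),
                (len(eng.rates), eng.patterns.shape[1], 4))
            self.scale[id(n)] = 0.0
            return
        acc = None
        sc = 0.0
        for c in n.children:
            t = max((n.age - c.age) * rate, tr.MIN_BL)
            P = eng.pmatrices(t)
            msg = self.down[id(c)] @ np.transpose(P, (0, 2, 1))
            acc = msg if acc is None else acc * msg
            sc = sc + self.scale[id(c)]
        m = acc.max(axis=(0, 2))
        m = np.where(m > 0, m, 1.0)
        self.down[id(n)] = acc / m[None, :, None]
        self.scale[id(n)] = sc + np.log(m)

    def loglik(self, rate: float, changed: Optional[Node] = None) -> float:
        if changed is None or rate != self.rate:
            self._saved = [("all", dict(self.down), dict(self.scale))]
            self.rate = rate
            for n in self.tree.postorder():
                self._compute_node(n, rate)
        else:
            path = []
            n = changed
            while n is not None:
                path.append(n)
                n = n.parent
            self._saved = [(id(n), self.down.get(id(n)), self.scale.get(id(n)))
                           for n in path]
            for n in path:  # changed node first, then ancestors
                self._compute_node(n, rate)
        eng = self.eng
        r = self.down[id(self.tree.root)]
        site = (r * eng.freqs[None, None, :]).sum(axis=2).mean(axis=0)
        site = np.clip(site, 1e-300, None)
        return float((eng.weights *
                      (np.log(site) + self.scale[id(self.tree.root)])).sum())

    def revert(self) -> None:
        if not self._saved:
            return
        if self._saved[0][0] == "all":
            _, self.down, self.scale = self._saved[0]
            self.rate = None
        else:
            for key, d, s in self._saved:
                self.down[key] = d
                self.scale[key] = s
        self._saved = None


def _init_ages(tree: Tree, calibrated: dict, root_guess: float) -> None:
    """Heuristic starting ages: depth-proportional below the root guess."""
    depth = {}
    for n in tree.postorder():
        depth[id(n)] = 0 if n.is_leaf else 1 + max(depth[id(c)] for c in n.children)
    root_d = depth[id(tree.root)]
    for n in tree.postorder():
        if n.is_leaf:
            n.age = 0.0
        else:
            n.age = root_guess * depth[id(n)] / root_d
    for node, cal in calibrated.items():
        lo = max(c.age for c in node.children)
        node.age = max(cal.mean, lo * 1.01)
    # repair any violated ordering bottom-up
    for n in tree.postorder():
        if not n.is_leaf:
            lo = max(c.age for c in n.children)
            if n.age <= lo:
                n.age = lo * 1.0001 + 1e-6


def strict_clock_date(tree: Tree, alignment_4d: Optional[dict],
                      calibrations: list, steps: int = 20000,
                      burn_in: float = 0.25, thin: int = 10,
                      rate_prior: tuple = (np.log(0.005), 2.0),
                      proposal_scale: float = 0.1,
                      model: Optional[tr.SubstitutionModel] = None,
                      seed: int = 0) -> DatedTree:
    """Strict-clock MCMC dating of a rooted topology.

    ``alignment_4d`` maps taxon -> 4-fold-degenerate-site string (pass
    ``None`` or empty sites for a prior-only run).  ``calibrations`` is a
    list of :class:`CalibrationPrior`.  Ages are in Ma; the clock rate is
    in substitutions/site/Ma with a lognormal(meanlog, sdlog) prior given
    by ``rate_prior``.  Returns posterior node-age samples, posterior-mean
    ages with 95% credible intervals, and rate samples.
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    work = tree.copy()
    if len(work.root.children) != 2:
        raise ValueError("dating requires a rooted (bifurcating-root) topology")
    rng = np.random.default_rng(seed)
    calibrated = {}
    for cal in calibrations:
        node = cal.resolve(work)
        calibrated[node] = cal

    internals = [n for n in work.postorder() if not n.is_leaf]
    n_free = sum(1 for n in internals if n is not work.root and n not in calibrated)
    root_guess = max(c.mean for c in calibrations) * 1.2
    _init_ages(work, calibrated, root_guess)

    use_data = alignment_4d is not None and \
        len(next(iter(alignment_4d.values()), "")) > 0
    lik = None
    if use_data:
        model = model or tr.SubstitutionModel()
        eng = tr.PruningEngine(alignment_4d, model)
        missing = set(eng.names) ^ set(work.leaf_names())
        if missing:
            raise ValueError(f"4D matrix / tree taxa mismatch: {sorted(missing)}")
        lik = _IncrementalClockLik(eng, work)

    rate = float(np.exp(rate_prior[0]))

    def log_prior() -> float:
        lp = 0.0
        for node, cal in calibrated.items():
            lp += -0.5 * ((node.age - cal.mean) / cal.sd) ** 2 - np.log(cal.sd)
        lp += -n_free * np.log(work.root.age)
        mu, sd = rate_prior
        lr = np.log(rate)
        lp += -0.5 * ((lr - mu) / sd) ** 2 - lr
        return lp

    def log_lik(changed: Optional[Node] = None) -> float:
        if not use_data:
            return 0.0
        return lik.loglik(rate, changed)

    lp, ll = log_prior(), log_lik()
    n_samples = 0
    keys = {}
    for n in internals:
        leaves = sorted(l.name for l in Tree(n).leaves()) if n.children else []
        keys[id(n)] = ",".join(leaves)
    age_samples: dict[str, list] = {keys[id(n)]: [] for n in internals}
    rate_samples: list[float] = []
    acc = {"age": [0, 0], "rate": [0, 0], "root": [0, 0]}

    for step in range(steps):
        which = rng.random()
        if use_data and which < 0.2:
            kind = "rate"
            old_rate = rate
            c = float(np.exp(proposal_scale * (rng.random() - 0.5) * 2))
            rate = rate * c
            lp2, ll2 = log_prior(), log_lik()
            log_alpha = (lp2 + ll2) - (lp + ll) + np.log(c)
            if np.log(rng.random()) < log_alpha:
                lp, ll = lp2, ll2
                acc[kind][0] += 1
            else:
                rate = old_rate
                if lik is not None:
                    lik.revert()
            acc[kind][1] += 1
        else:
            node = internals[rng.integers(len(internals))]
            old_age = node.age
            lo = max(c.age for c in node.children)
            hi = node.parent.age if node.parent is not None else None
            kind = "root" if node.parent is None else "age"
            if hi is not None and hi <= lo:
                acc[kind][1] += 1
                continue
            if hi is not None and rng.random() < 0.5:
                # big jump: uniform on the allowed interval (symmetric)
                new_age = lo + rng.random() * (hi - lo)
            else:
                # local move: reflected window (symmetric)
                w = proposal_scale * ((hi - lo) if hi is not None
                                      else max(node.age, 1.0))
                new_age = node.age + (rng.random() - 0.5) * 2 * w
                for _r in range(8):
                    if hi is not None and new_age > hi:
                        new_age = 2 * hi - new_age
                    elif new_age < lo:
                        new_age = 2 * lo - new_age
                    else:
                        break
                if new_age <= lo or (hi is not None and new_age >= hi):
                    acc[kind][1] += 1
                    continue
            node.age = new_age
            lp2, ll2 = log_prior(), log_lik(changed=node)
            if np.log(rng.random()) < (lp2 + ll2) - (lp + ll):
                lp, ll = lp2, ll2
                acc[kind][0] += 1
            else:
                node.age = old_age
                if lik is not None:
                    lik.revert()
            acc[kind][1] += 1
        if step >= int(burn_in * steps) and step % thin == 0:
            for n in internals:
                age_samples[keys[id(n)]].append(n.age)
            rate_samples.append(rate)
            n_samples += 1

    samples = {k: np.asarray(v) for k, v in age_samples.items()}
    rows = []
    for n in internals:
        s = samples[keys[id(n)]]
        n.age = float(s.mean())
        rows.append((keys[id(n)], float(s.mean()),
                     float(np.percentile(s, 2.5)), float(np.percentile(s, 97.5))))
    for n in work.postorder():
        if n.parent is not None:
            n.length = max(n.parent.age - n.age, 0.0) if not n.is_leaf \
                else n.parent.age
    summary = pd.DataFrame(rows, columns=["clade", "mean", "lo95", "hi95"])
    acc_rates = {k: (a / t if t else 0.0) for k, (a, t) in acc.items()}
    return DatedTree(work, summary, samples, np.asarray(rate_samples), acc_rates)


# ---------------------------------------------------------------------- Ks
@dataclass
class KsPair:
    gene1: str
    gene2: str
    ks: float                    # nan when undefined/saturated
    ka: Optional[float] = None
    saturated: bool = False
    s_sites: float = 0.0
    n_sites: float = 0.0
    s_diffs: float = 0.0
    n_diffs: float = 0.0


def _codon_align(cds1: str, cds2: str) -> tuple[str, str]:
    """Codon-wise alignment via pairwise protein alignment, back-translated."""
    from .supermatrix import backtranslate, progressive_align
    from .synthetic_data import translate_cds
    p1, p2 = translate_cds(cds1), translate_cds(cds2)
    aligned = progressive_align({"s1": p1, "s2": p2})
    codons = backtranslate(aligned, {"s1": cds1, "s2": cds2})
    return codons["s1"], codons["s2"]


def ks_pair(cds1: str, cds2: str, gene1: str = "g1", gene2: str = "g2",
            aligned: bool = False, stop_mode: str = "exclude") -> KsPair:
    """Nei–Gojobori (NG86) synonymous divergence between two CDS.

    Synonymous/nonsynonymous site counts are codon-degeneracy fractions
    averaged over both sequences; differences are counted over the
    equally-weighted parsimonious substitution pathways (pathways through
    stop codons excluded); the Jukes–Cantor correction
    ``Ks = -3/4 ln(1 - 4/3 (Sd/S))`` is applied, with a saturation flag
    when Sd/S >= 3/4.  Codon columns with gaps or ambiguity are skipped.
    """
    if len(cds1) % 3 or len(cds2) % 3:
        raise ValueError("CDS lengths must be divisible by 3")
    if aligned:
        if len(cds1) != len(cds2):
            raise ValueError("aligned CDS must have equal lengths")
        a1, a2 = cds1, cds2
    else:
        a1, a2 = (cds1, cds2) if len(cds1) == len(cds2) else _codon_align(cds1, cds2)
    syn_sites = ng86_site_fractions(stop_mode)
    sd_tab, nd_tab = ng86_difference_tables(stop_mode)
    S = N = Sd = Nd = 0.0
    ncod = 0
    for k in range(0, len(a1), 3):
        c1, c2 = a1[k:k + 3], a2[k:k + 3]
        if c1 not in SENSE_INDEX or c2 not in SENSE_INDEX:
            continue
        i, j = SENSE_INDEX[c1], SENSE_INDEX[c2]
        S += 0.5 * (syn_sites[i] + syn_sites[j])
        Sd += sd_tab[i, j]
        Nd += nd_tab[i, j]
        ncod += 1
    N = 3.0 * ncod - S
    if S <= 0:
        return KsPair(gene1, gene2, float("nan"), None, True, S, N, Sd, Nd)
    ps, pn = Sd / S, (Nd / N if N > 0 else 0.0)
    saturated = ps >= 0.75
    ks = float("nan") if saturated else -0.75 * np.log(1.0 - 4.0 * ps / 3.0)
    ka = float("nan") if pn >= 0.75 else -0.75 * np.log(1.0 - 4.0 * pn / 3.0)
    return KsPair(gene1, gene2, ks, ka, saturated, S, N, Sd, Nd)


def ks_distribution(families: list, bin_width: float = 0.05,
                    max_ks: float = 3.0) -> dict:
    """Per-taxon Ks histograms over within-taxon paralog pairs.

    ``families`` are objects with ``sequences`` (gene id -> CDS) and
    optionally a ``gene_tree`` whose duplication nodes are labelled "dup";
    with a gene tree one pair is taken per (duplication node, taxon)
    — the first gene from each daughter subtree — otherwise all
    within-taxon pairs are used.  Returns
    ``{taxon: {"edges": array, "counts": array, "pairs": [KsPair, ...]}}``.
    """
    from .synthetic_data import parse_gene_id
    per_taxon_pairs: dict[str, list] = {}
    for fam in families:
        seqs = fam.sequences
        pairs = []
        gt = getattr(fam, "gene_tree", None)
        if gt is not None:
            for node in gt.postorder():
                if node.is_leaf or node.name != "dup" or len(node.children) < 2:
                    continue
                left = sorted(l.name for l in Tree(node.children[0]).leaves())
                right = sorted(l.name for l in Tree(node.children[1]).leaves())
                by_tax_l: dict[str, str] = {}
                for g in left:
                    by_tax_l.setdefault(parse_gene_id(g)[0], g)
                for g in right:
                    t = parse_gene_id(g)[0]
                    if t in by_tax_l:
                        pairs.append((t, by_tax_l[t], g))
                        break
        else:
            by_tax: dict[str, list] = {}
            for g in seqs:
                by_tax.setdefault(parse_gene_id(g)[0], []).append(g)
            for t, genes in by_tax.items():
                genes.sort()
                for i in range(len(genes)):
                    for j in range(i + 1, len(genes)):
                        pairs.append((t, genes[i], genes[j]))
        for t, g1, g2 in pairs:
            if g1 in seqs and g2 in seqs:
                per_taxon_pairs.setdefault(t, []).append(
                    ks_pair(seqs[g1], seqs[g2], g1, g2))
    edges = np.arange(0.0, max_ks + bin_width, bin_width)
    out = {}
    for t, kp in sorted(per_taxon_pairs.items()):
        vals = [p.ks for p in kp if not p.saturated and np.isfinite(p.ks)]
        counts, _ = np.histogram(vals, bins=edges)
        out[t] = {"edges": edges, "counts": counts, "pairs": kp}
    return out


def write_ks_histograms(dist: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tbin_lo\tbin_hi\tcount\n")
        for t, d in dist.items():
            for lo, hi, c in zip(d["edges"][:-1], d["edges"][1:], d["counts"]):
                fh.write(f"{t}\t{lo:.3f}\t{hi:.3f}\t{c}\n")
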