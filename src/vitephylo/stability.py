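"""Gene-resampling topology stability and gene-tree concordance.

The jackknife protocol: for each gene count N, draw random N-gene subsets,
build a tree from the concatenation, and count draws until the topology
matches the reference; repeat for a fixed number of accepted trees per N
and record their bootstrap supports.  The mean number of repeats measures
how concentrated the phylogenetic signal is; mean support measures how
fast it saturates with gene number.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import trees as tr
from ._tree import Tree, rf_distance

__all__ = ["gene_jackknife", "count_matching_gene_trees", "default_builder"]


def default_builder(model: Optional[tr.SubstitutionModel] = None) -> Callable:
    """Fast ML builder (NJ start, NNI refinement) for jackknife replicates."""
    model = model or tr.SubstitutionModel()

    def build(alignment: dict, seed: int) -> Tree:
        t, _ = tr.ml_search(alignment, model=model, seed=seed,
                            bl_sweeps=1, xatol=1e-3)
        return t

    return build


def _concat(genes: dict, subset: list) -> dict:
    taxa = sorted(next(iter(genes.values())))
    return {t: "".join(genes[g][t] for g in subset) for t in taxa}


def gene_jackknife(genes: dict, reference: Tree,
                   n_grid=None, trees_per_n: int = 30,
                   max_attempts_per_slot: int = 1000,
                   builder: Optional[Callable] = None,
                   n_bootstrap: int = 20,
                   model: Optional[tr.SubstitutionModel] = None,
                   seed: int = 0) -> pd.DataFrame:
    """Run the gene-subsampling stability protocol.

    ``genes`` maps family id -> {taxon: aligned nucleotide row}.  For each
    N in ``n_grid`` and each of ``trees_per_n`` slots, N-gene subsets are
    drawn uniformly without replacement (independently across draws) until
    the built tree matches the reference topology (unrooted RF = 0); the
    number of draws is recorded, and the accepted tree's bootstrap support
    (``n_bootstrap`` site-resampling replicates) is summarised.  A slot
    that exhausts ``max_attempts_per_slot`` is recorded as censored at the
    cap.  Returns a tidy DataFrame (N, slot, repeats, censored,
    mean_support, min_support).
    """
    ids = sorted(genes)
    if n_grid is None:
        n_grid = list(range(10, min(220, len(ids)) + 1, 10))
    if max(n_grid) > len(ids):
        raise ValueError(f"grid value {max(n_grid)} exceeds gene count {len(ids)}")
    ref_leaves = set(reference.leaf_names())
    taxa = set(next(iter(genes.values())))
    if ref_leaves != taxa:
        raise ValueError("reference topology and gene alignments disagree on taxa")
    builder = builder or default_builder(model)
    rng = np.random.default_rng(seed)
    rows = []
    for N in n_grid:
        for slot in range(trees_per_n):
            repeats = 0
            censored = True
            tree = None
            while repeats < max_attempts_per_slot:
                repeats += 1
                subset = [ids[i] for i in rng.choice(len(ids), N, replace=False)]
                aln = _concat(genes, subset)
                tree = builder(aln, int(rng.integers(2 ** 31 - 1)))
                if rf_distance(tree, reference) == 0:
                    censored = False
                    break
            mean_sup = min_sup = np.nan
            if not censored and n_bootstrap > 0:
                # fast replicates: fixed branch lengths, NNI-only refinement
                _, support = tr.bootstrap_support(
                    aln, builder="ml", n_replicates=n_bootstrap,
                    seed=int(rng.integers(2 ** 31 - 1)), model=model, tree=tree,
                    bl_sweeps=0, max_nni_rounds=3)
                vals = [support.get(bp, 0.0)
                        for bp in _internal_splits(reference)]
                if vals:
                    mean_sup, min_sup = float(np.mean(vals)), float(np.min(vals))
            rows.append((N, slot, repeats, censored, mean_sup, min_sup))
    return pd.DataFrame(rows, columns=["N", "slot", "repeats", "censored",
                                       "mean_support", "min_support"])


def _internal_splits(tree: Tree):
    from ._tree import bipartitions
    return sorted(bipartitions(tree), key=sorted)


def summarize_jackknife(table: pd.DataFrame) -> pd.DataFrame:
    """Per-N means: repeats-until-match and bootstrap support."""
    return table.groupby("N").agg(
        mean_repeats=("repeats", "mean"),
        mean_support=("mean_support", "mean"),
        n_censored=("censored", "sum"),
    ).reset_index()


def count_matching_gene_trees(gene_trees: dict, reference: Tree):
    """Count gene trees topologically identical to the reference.

    Trees whose leaf set differs from the reference are excluded and
    reported.  Returns ``(matching, total_compared, rf_values, excluded)``.
    """
    ref_leaves = set(reference.leaf_names())
    matching = 0
    rf_values = {}
    excluded = []
    for fam, t in sorted(gene_trees.items()):
        if set(t.leaf_names()) != ref_leaves:
            excluded.append(fam)
            continue
        d = rf_distance(t, reference)
        rf_values[fam] = d
        if d == 0:
            matching += 1
    return matching, len(rf_values), rf_values, excluded
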