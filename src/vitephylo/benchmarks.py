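"""Synthetic benchmark scenarios used by the analysis scripts and tests.

Each function sets up one validation experiment at its study conditions
(taxon counts, family counts, divergence levels, rates) and runs the real
pipeline on it.  The conditions are fixed here as module constants; the
``seed`` argument only moves the stochastic replicate, not the design.

Scale notes: the benchmark species tree has 15 taxa (root age 1 time unit,
pure birth, a fixed tree draw chosen for non-negligible internal edges);
sequence divergence uses ~0.3 substitutions/site per unit time, giving
moderately diverged proteins; the ortholog benchmark simulates 300
families with a duplication rate of 0.05 events per lineage per unit time,
which yields roughly 30% multi-copy families on this tree.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import divergence as dv
from . import orthology as orth
from . import similarity as sim
from . import stability as stab
from . import synthetic_data as sd
from . import trees as tr
from ._tree import Tree, bipartitions, rf_distance

SPECIES_TREE_SEED = 24       # fixed benchmark tree (min internal edge ~0.07)
N_TAXA = 15
RATE_PER_TIME = 0.3          # nt substitutions/site per unit tree time
ORTHO_N_FAMILIES = 300
ORTHO_DUP_RATE = 0.05        # ~30% multi-copy families on this tree
ORTHO_N_CODONS = 150


def benchmark_species_tree() -> Tree:
    """The fixed 15-taxon ultrametric benchmark tree (root age 1)."""
    return sd.simulate_species_tree(N_TAXA, birth_rate=1.0, root_age=1.0,
                                    seed=SPECIES_TREE_SEED)


def benchmark_model(rate: float = RATE_PER_TIME) -> sd.GTRModel:
    return sd.GTRModel(rate_multiplier=rate)


# -------------------------------------------------------- ortholog recovery
def ortholog_recovery(seed: int = 0, n_families: int = ORTHO_N_FAMILIES,
                      use_blast: bool = True) -> dict:
    """Simulate families with duplications, run similarity + clustering +
    single-copy selection, and score recovery against truth.

    Returns recovered/true family sets plus summary statistics:
    ``recall`` (fraction of true single-copy families recovered exactly)
    and ``n_chimeric`` (recovered families mixing genes from different
    true families).
    """
    tree = benchmark_species_tree()
    fams = sd.simulate_gene_families(tree, n_families,
                                     dup_rate=ORTHO_DUP_RATE, loss_rate=0.0,
                                     seed=seed)
    sd.simulate_family_sequences(fams, n_codons=ORTHO_N_CODONS,
                                 model=benchmark_model(), seed=seed + 1)
    proteins = {}
    for f in fams:
        for g, s in f.sequences.items():
            proteins[g] = sd.translate_cds(s)
    if use_blast:
        hits = sim.blast_all_vs_all(proteins)
    else:
        hits = sim.all_vs_all(proteins)
    lengths = {g: len(p) for g, p in proteins.items()}
    G = orth.build_graph(hits, lengths=lengths)
    families = orth.cluster_families(G)
    single = orth.select_single_copy(families, tree.leaf_names())

    true_single = {frozenset(f.gene_ids()) for f in fams if f.single_copy}
    recovered = {frozenset(f.gene_ids()) for f in single}
    exact = recovered & true_single

    def true_family_of(g):
        return sd.parse_gene_id(g)[1]

    n_chimeric = sum(
        1 for f in families
        if len(f.members) > 1 and len({true_family_of(g) for g in f.gene_ids()}) > 1)
    frac_multi = float(np.mean([not f.single_copy for f in fams]))
    return {
        "tree": tree, "families_truth": fams, "families_recovered": families,
        "single_recovered": single, "recall": len(exact) / max(len(true_single), 1),
        "n_true_single": len(true_single), "n_recovered_single": len(recovered),
        "n_exact": len(exact), "n_chimeric": n_chimeric,
        "fraction_multicopy_truth": frac_multi,
    }


# --------------------------------------------------------- topology recovery
def simulate_single_copy_gene_matrix(n_genes: int, n_codons: int, seed: int,
                                     rate: float = RATE_PER_TIME,
                                     rate_jitter_sd: float = 0.0,
                                     tree_seed: int = SPECIES_TREE_SEED,
                                     ) -> tuple[Tree, dict]:
    """Strictly single-copy families on the benchmark tree; returns
    (species_tree, {family_id: {taxon: cds_row}})."""
    tree = sd.simulate_species_tree(N_TAXA, birth_rate=1.0, root_age=1.0,
                                    seed=tree_seed)
    fams = sd.simulate_gene_families(tree, n_genes, dup_rate=0.0,
                                     loss_rate=0.0, seed=seed)
    sd.simulate_family_sequences(fams, n_codons=n_codons,
                                 model=benchmark_model(rate),
                                 rate_jitter_sd=rate_jitter_sd, seed=seed + 1)
    genes = {}
    for f in fams:
        genes[f.family_id] = {sd.parse_gene_id(g)[0]: s
                              for g, s in f.sequences.items()}
    return tree, genes


def concatenate_genes(genes: dict) -> dict:
    taxa = sorted(next(iter(genes.values())))
    return {t: "".join(genes[g][t] for g in sorted(genes)) for t in taxa}


def topology_recovery(seed: int = 0, n_genes: int = 30, n_codons: int = 300,
                      ) -> dict:
    """Concatenated ML on single-copy genes vs the generating topology."""
    tree, genes = simulate_single_copy_gene_matrix(n_genes, n_codons, seed)
    aln = concatenate_genes(genes)
    ml, ll = tr.ml_search(aln, model=tr.SubstitutionModel(), seed=seed)
    return {"tree": tree, "genes": genes, "ml_tree": ml, "loglik": ll,
            "rf": rf_distance(ml, tree.unroot())}


def bootstrap_saturation(seed: int = 0, n_genes: int = 40,
                         n_codons: int = 300, n_replicates: int = 100) -> dict:
    """Bootstrap support on all internal edges of the concatenated ML tree."""
    tree, genes = simulate_single_copy_gene_matrix(n_genes, n_codons, seed)
    aln = concatenate_genes(genes)
    best, support = tr.bootstrap_support(aln, builder="ml",
                                         n_replicates=n_replicates, seed=seed,
                                         model=tr.SubstitutionModel())
    true_splits = bipartitions(tree.unroot())
    sup_on_true = {tuple(sorted(bp)): support.get(bp, 0.0) for bp in true_splits}
    return {"tree": tree, "ml_tree": best, "support": support,
            "rf": rf_distance(best, tree.unroot()),
            "min_support_true_splits": min(sup_on_true.values()),
            "support_true_splits": sup_on_true}


# ------------------------------------------------------------ gene jackknife
JACKKNIFE_POOL = 80          # genes in the resampling pool
JACKKNIFE_N_CODONS = 50      # short genes -> appreciable per-gene noise
JACKKNIFE_TREE_SEED = 19     # tree draw with a short internal edge (~0.004)


def jackknife_protocol(seed: int = 0, n_grid=None, trees_per_n: int = 30,
                       n_bootstrap: int = 10) -> dict:
    """Gene-subsampling stability on a noisy synthetic gene pool.

    Per-gene topological noise comes from gene length (50 codons) on a
    tree draw with a genuinely short internal edge: short genes estimate
    that edge imperfectly, so small-N concatenations need several draws to
    match the reference while large-N ones match almost immediately, and
    bootstrap support saturates as N grows.  The reference is the
    all-genes ML tree.
    """
    if n_grid is None:
        n_grid = list(range(10, 61, 10))
    _, genes = simulate_single_copy_gene_matrix(
        JACKKNIFE_POOL, JACKKNIFE_N_CODONS, seed, rate_jitter_sd=0.3,
        tree_seed=JACKKNIFE_TREE_SEED)
    full = concatenate_genes(genes)
    reference, _ = tr.ml_search(full, model=tr.SubstitutionModel(), seed=seed)
    table = stab.gene_jackknife(genes, reference, n_grid=n_grid,
                                trees_per_n=trees_per_n,
                                n_bootstrap=n_bootstrap, seed=seed + 17)
    summary = stab.summarize_jackknife(table)
    rep_rho = spearmanr(summary["N"], summary["mean_repeats"]).statistic
    sup_rho = spearmanr(summary["N"], summary["mean_support"]).statistic
    if np.isnan(rep_rho):     # constant column (all repeats equal)
        rep_rho = 0.0
    if np.isnan(sup_rho):
        sup_rho = 0.0
    return {"genes": genes, "reference": reference, "table": table,
            "summary": summary, "repeats_trend": float(rep_rho),
            "support_trend": float(sup_rho)}


def gene_tree_concordance(seed: int = 0, n_genes: int = 60,
                          n_codons: int = 100) -> dict:
    """Per-gene ML trees vs the concatenated tree (concordance count)."""
    tree, genes = simulate_single_copy_gene_matrix(n_genes, n_codons, seed,
                                                   rate_jitter_sd=0.3)
    full = concatenate_genes(genes)
    reference, _ = tr.ml_search(full, model=tr.SubstitutionModel(), seed=seed)
    gene_trees = {}
    for fam, rows in genes.items():
        gene_trees[fam], _ = tr.ml_search(rows, model=tr.SubstitutionModel(),
                                          seed=seed)
    matching, total, rf_values, _ = stab.count_matching_gene_trees(
        gene_trees, reference)
    return {"reference": reference, "matching": matching, "total": total,
            "rf_values": rf_values,
            "concat_rf_to_truth": rf_distance(reference, tree.unroot())}


# --------------------------------------------------- long-branch attraction
def felsenstein_zone(seed: int = 0, n_sites: int = 500,
                     n_replicates: int = 100) -> dict:
    """4-taxon simulation with two long non-sister branches.

    Under parsimony the long branches attract each other; ML with the
    generating model stays consistent.  Returns the fraction of replicates
    in which MP picks the wrong (long-branch) topology and ML the true one.
    """
    true = Tree.from_newick("((A:0.7,C:0.1):0.1,B:0.7,D:0.1);")
    model = sd.GTRModel(exchangeabilities=(1.0,) * 6, freqs=(0.25,) * 4)
    rng = np.random.default_rng(seed)
    mp_wrong = ml_right = 0
    for _ in range(n_replicates):
        aln = sd.simulate_nucleotide_sites(true, n_sites, model,
                                           seed=int(rng.integers(2 ** 31 - 1)))
        mp_trees, _ = tr.mp_search(aln, n_random_additions=3,
                                   seed=int(rng.integers(2 ** 31 - 1)))
        mp_ok = any(rf_distance(t, true) == 0 for t in mp_trees)
        if not mp_ok:
            mp_wrong += 1
        ml_tree, _ = tr.ml_search(aln, model=tr.SubstitutionModel(),
                                  seed=int(rng.integers(2 ** 31 - 1)))
        if rf_distance(ml_tree, true) == 0:
            ml_right += 1
    return {"mp_wrong_fraction": mp_wrong / n_replicates,
            "ml_right_fraction": ml_right / n_replicates}


# ----------------------------------------------------------------- dating
ROOT_AGE_MA = 90.7
CLOCK_RATE = 0.005           # subst/site/Ma


def dated_benchmark_tree() -> Tree:
    """Benchmark topology with ages rescaled to a 90.7 Ma root."""
    t = benchmark_species_tree()
    for n in t.postorder():
        n.age = n.age * ROOT_AGE_MA
        if n.parent is not None:
            n.length *= ROOT_AGE_MA
    return t


def dating_prior_recovery(seed: int = 0, steps: int = 80000) -> dict:
    """Prior-only strict-clock run: the root posterior must reproduce the
    90.7 +/- 1.0 Ma normal calibration prior."""
    t = dated_benchmark_tree()
    cal = dv.CalibrationPrior("root", 90.7, 1.0)
    res = dv.strict_clock_date(t, None, [cal], steps=steps, seed=seed)
    root_key = ",".join(sorted(t.leaf_names()))
    s = res.age_samples[root_key]
    return {"result": res, "root_mean": float(s.mean()),
            "root_sd": float(s.std())}


def dating_parameter_recovery(seed: int = 0, n_replicates: int = 20,
                              n_sites: int = 800, steps: int = 8000) -> dict:
    """Strict-clock simulation with true-age calibrations: coverage of true
    node ages by 95% credible intervals, pooled over replicates."""
    t = dated_benchmark_tree()
    true_ages = {}
    for n in t.postorder():
        if not n.is_leaf:
            leaves = ",".join(sorted(l.name for l in Tree(n).leaves()))
            true_ages[leaves] = n.age
    root_key = ",".join(sorted(t.leaf_names()))
    # calibrations: root at truth, plus one internal node at truth
    internal = [k for k in true_ages if k != root_key]
    internal.sort(key=lambda k: -true_ages[k])
    cals = [dv.CalibrationPrior("root", true_ages[root_key], 2.0),
            dv.CalibrationPrior(internal[0].split(","),
                                true_ages[internal[0]],
                                max(0.05 * true_ages[internal[0]], 0.5))]
    model = sd.GTRModel(exchangeabilities=(1.0,) * 6, freqs=(0.25,) * 4)
    rng = np.random.default_rng(seed)
    covered = total = 0
    acc_rates = []
    chain_means = []
    for _ in range(n_replicates):
        aln = sd.simulate_nucleotide_sites(t, n_sites, model, rate=CLOCK_RATE,
                                           seed=int(rng.integers(2 ** 31 - 1)))
        res = dv.strict_clock_date(t, aln, cals, steps=steps,
                                   seed=int(rng.integers(2 ** 31 - 1)))
        for _, row in res.summary.iterrows():
            total += 1
            if row.lo95 <= true_ages[row.clade] <= row.hi95:
                covered += 1
        acc_rates.append(res.acceptance)
        chain_means.append(res.summary.set_index("clade")["mean"])
    return {"coverage": covered / total, "acceptance": acc_rates,
            "true_ages": true_ages, "chain_means": chain_means}


# --------------------------------------------------------------------- Ks
def ks_consistency(seed: int = 0, true_ds=(0.1, 0.5, 1.0),
                   n_codons: int = 3333, n_replicates: int = 3) -> dict:
    """NG86 Ks on two-sequence simulations at known synonymous divergence.

    The simulator applies no selection (all nucleotide changes equally
    likely, uniform frequencies), so the expected synonymous divergence per
    synonymous site equals the nucleotide branch length.
    """
    rng = np.random.default_rng(seed)
    model = sd.GTRModel(exchangeabilities=(1.0,) * 6, freqs=(0.25,) * 4)
    out = {}
    for ds in true_ds:
        est = []
        for _ in range(n_replicates):
            pair_tree = Tree.from_newick(f"(x:{ds / 2},y:{ds / 2});")
            seqs = sd.simulate_codon_sequences(
                pair_tree, n_codons, model, seed=int(rng.integers(2 ** 31 - 1)))
            kp = dv.ks_pair(seqs["x"], seqs["y"], aligned=True)
            est.append(kp.ks)
        out[ds] = {"mean_ks": float(np.mean(est)), "values": est}
    return out


WGD_AGE = 0.75               # on the root-age-1 benchmark tree
WGD_RATE = 1.0 / (2 * WGD_AGE)  # so paralog synonymous divergence ~= 1.0


def wgd_ks_peak(seed: int = 0, n_families: int = 60, n_codons: int = 400,
                retained_fraction: float = 0.8, bin_width: float = 0.1) -> dict:
    """Simulate a whole-genome duplication and locate the paralog Ks peak."""
    tree = benchmark_species_tree()
    fams = sd.simulate_gene_families(tree, n_families, dup_rate=0.0,
                                     loss_rate=0.0, seed=seed)
    model = sd.GTRModel(exchangeabilities=(1.0,) * 6, freqs=(0.25,) * 4,
                        rate_multiplier=WGD_RATE)
    sd.simulate_family_sequences(fams, n_codons=n_codons, model=model,
                                 wgd=(WGD_AGE, retained_fraction),
                                 seed=seed + 1)
    dist = dv.ks_distribution(fams, bin_width=bin_width)
    pooled = None
    for t, d in dist.items():
        pooled = d["counts"].copy() if pooled is None else pooled + d["counts"]
    edges = next(iter(dist.values()))["edges"]
    mode_bin = int(np.argmax(pooled))
    mode_center = 0.5 * (edges[mode_bin] + edges[mode_bin + 1])
    return {"distribution": dist, "pooled_counts": pooled, "edges": edges,
            "mode_center": float(mode_center), "target_ks": 1.0}
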