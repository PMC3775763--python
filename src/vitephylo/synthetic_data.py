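"""Synthetic transcriptome-phylogenomics data with known truth.

Generates (i) an ultrametric species tree (pure-birth conditioned on the
taxon count), (ii) gene families evolved inside it by a duplication–loss
branching process, (iii) codon sequences under a GTR nucleotide model
restricted to sense codons, and (iv) degraded transcripts plus paired-end
reads with quality/N artifacts.  Every emitted sequence is traceable through
the truth map to (taxon, family, copy), so downstream ortholog detection,
supermatrix filters and tree inference can be validated against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from ._codons import SENSE_CODONS, codon_rate_matrix, translate_codon
from ._tree import Node, Tree

__all__ = [
    "GTRModel", "FamilyTruth", "simulate_species_tree", "simulate_gene_families",
    "simulate_codon_sequences", "degrade_and_emit", "DegradeResult",
]


@dataclass
class GTRModel:
    """Nucleotide GTR parameters driving the codon simulator.

    exchangeabilities: AC, AG, AT, CG, CT, GT (relative); freqs: A,C,G,T.
    rate_multiplier scales branch lengths (per-gene rate variation).
    """
    exchangeabilities: tuple = (1.0, 2.0, 1.0, 1.0, 2.0, 1.0)
    freqs: tuple = (0.30, 0.20, 0.20, 0.30)
    rate_multiplier: float = 1.0

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        if f.shape != (4,) or abs(f.sum() - 1.0) > 1e-9 or np.any(f <= 0):
            raise ValueError("freqs must be 4 positive values summing to 1")


@dataclass
class FamilyTruth:
    """Ground truth for one simulated gene family."""
    family_id: str
    gene_tree: Tree                       # leaves named taxon|family|copy
    counts: dict                          # taxon -> gene copy count
    single_copy: bool
    sequences: dict = field(default_factory=dict)   # leaf name -> CDS string
    alignment: dict = field(default_factory=dict)   # leaf name -> aligned CDS

    def gene_ids(self) -> list[str]:
        return self.gene_tree.leaf_names()


def _leaf_label(taxon: str, family_id: str, copy_index: int) -> str:
    return f"{taxon}|{family_id}|{copy_index}"


def parse_gene_id(gene_id: str) -> tuple[str, str, int]:
    """Split a synthetic gene id into (taxon, family_id, copy_index)."""
    taxon, fam, copy = gene_id.rsplit("|", 2)
    return taxon, fam, int(copy)


# ------------------------------------------------------------ species tree
def simulate_species_tree(n_taxa: int, birth_rate: float = 1.0,
                          root_age: float = 1.0, seed: int = 0) -> Tree:
    """Pure-birth (Yule) tree conditioned on ``n_taxa``, rescaled to ``root_age``.

    Leaves are named T01..Tnn; node ages are stored on ``Node.age`` and
    branch lengths are in the same time units (leaf age 0, root ``root_age``).
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if birth_rate <= 0 or root_age <= 0:
        raise ValueError("birth_rate and root_age must be positive")
    rng = np.random.default_rng(seed)
    root = Node()
    active = [root.add_child(Node()), root.add_child(Node())]
    t = 0.0
    times = {root: 0.0, active[0]: None, active[1]: None}
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        node = active.pop(idx)
        times[node] = t
        active.append(node.add_child(Node()))
        active.append(node.add_child(Node()))
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for leaf in active:
        times[leaf] = t_end
    # assign ages (time before present), rescale root to root_age
    scale = root_age / t_end
    tree = Tree(root)
    for node in tree.postorder():
        node.age = (t_end - times[node]) * scale
    for node in tree.postorder():
        if node.parent is not None:
            node.length = node.parent.age - node.age
    for i, leaf in enumerate(tree.leaves()):
        leaf.name = f"T{i + 1:02d}"
    return tree


# ------------------------------------------------------------ gene families
def _evolve_on_branch(gene_node: Node, species_node: Node, start_age: float,
                      dup_rate: float, loss_rate: float, rng) -> None:
    """Evolve one gene lineage down a species-tree branch and recurse.

    ``gene_node`` is the lineage entering the branch at ``start_age``;
    events (duplication/loss) occur until the branch's child node age.
    Gene-tree node ages mirror species time; leaves are tagged with the
    taxon via ``Node.name`` (= taxon) and relabelled later.
    """
    end_age = species_node.age
    age = start_age
    total = dup_rate + loss_rate
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if age - wait <= end_age:
            break
        age -= wait
        if rng.random() < (dup_rate / total):
            gene_node.age = age
            gene_node.name = "dup"
            left, right = gene_node.add_child(Node()), gene_node.add_child(Node())
            _evolve_on_branch(left, species_node, age, dup_rate, loss_rate, rng)
            _evolve_on_branch(right, species_node, age, dup_rate, loss_rate, rng)
            return
        gene_node.age = age
        gene_node.name = "lost"
        return
    gene_node.age = end_age
    if species_node.is_leaf:
        gene_node.name = species_node.name
        return
    gene_node.name = "spec"
    for sc in species_node.children:
        child = gene_node.add_child(Node())
        _evolve_on_branch(child, sc, end_age, dup_rate, loss_rate, rng)


def _prune_lost(node: Node) -> Optional[Node]:
    if node.is_leaf:
        return None if node.name == "lost" else node
    kept = [c for c in (_prune_lost(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].parent = node.parent
        return kept[0]
    node.children = kept
    for c in kept:
        c.parent = node
    return node


def simulate_gene_families(tree: Tree, n_families: int, dup_rate: float = 0.0,
                           loss_rate: float = 0.0, seed: int = 0) -> list[FamilyTruth]:
    """Evolve ``n_families`` gene trees inside the species tree.

    Each family starts as a single gene at the root and undergoes a linear
    birth–death process (duplication/loss) along species branches, splitting
    at speciations.  Duplication nodes keep the label ``dup``.  A family
    whose every taxon carries exactly one surviving copy is flagged
    single-copy.  Families that go extinct everywhere are re-drawn so the
    output always has ``n_families`` non-empty families.
    """
    if dup_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    taxa = tree.leaf_names()
    out: list[FamilyTruth] = []
    fam_idx = 0
    while len(out) < n_families:
        root = Node()
        root.age = tree.root.age
        root.name = "spec"
        for sc in tree.root.children:
            child = root.add_child(Node())
            _evolve_on_branch(child, sc, tree.root.age, dup_rate, loss_rate, rng)
        pruned = _prune_lost(root)
        if pruned is None or pruned.is_leaf:
            continue  # extinct or single survivor: not a usable family
        pruned.parent = None
        gt = Tree(pruned)
        fam_id = f"F{fam_idx:04d}"
        fam_idx += 1
        counts = {t: 0 for t in taxa}
        for leaf in gt.leaves():
            taxon = leaf.name
            leaf.name = _leaf_label(taxon, fam_id, counts[taxon])
            counts[taxon] += 1
        # branch lengths from ages
        for n in gt.postorder():
            if n.parent is not None:
                n.length = n.parent.age - n.age
        single = all(c == 1 for c in counts.values())
        out.append(FamilyTruth(fam_id, gt, counts, single))
    return out


# ---------------------------------------------------------- codon sequences
class _CodonSampler:
    """Caches the eigendecomposition of a codon rate matrix for fast P(t)."""

    def __init__(self, model: GTRModel):
        Q, w = codon_rate_matrix(model.exchangeabilities, model.freqs)
        self.stationary = w
        # S = D Q D^-1 (D = diag(sqrt(w))) is symmetric for reversible Q;
        # then expm(Qt) = D^-1 U e^(lam t) U^T D
        d = np.sqrt(w)
        S = Q * d[:, None] / d[None, :]
        lam, U = np.linalg.eigh((S + S.T) / 2)
        self._lam = lam
        self._left = U * d[:, None]
        self._right = U / d[:, None]
        self._cache: dict[float, np.ndarray] = {}

    def pmatrix(self, t: float) -> np.ndarray:
        P = self._cache.get(t)
        if P is None:
            P = (self._right * np.exp(self._lam * t)[None, :]) @ self._left.T
            np.clip(P, 0.0, None, out=P)
            P /= P.sum(axis=1, keepdims=True)
            if len(self._cache) < 4096:
                self._cache[t] = P
        return P


def _apply_wgd(gene_tree: Tree, wgd_age: float, retained_fraction: float,
               rng) -> Tree:
    """Insert a genome-wide duplication at ``wgd_age`` into a copy of the tree.

    Every lineage alive at that age duplicates; each extra copy is retained
    with probability ``retained_fraction`` (otherwise the duplication leaves
    no trace, emulating immediate post-WGD gene loss).
    """
    t = gene_tree.copy()
    # collect edges spanning wgd_age
    spanning = [n for n in t.postorder()
                if n.parent is not None and n.age < wgd_age <= n.parent.age]
    if t.root.age is not None and t.root.age < wgd_age:
        spanning = []  # WGD predates the family root: no observable copies
    for node in spanning:
        if rng.random() >= retained_fraction:
            continue
        parent = node.parent
        dup = Node("dup")
        dup.age = wgd_age
        dup.length = parent.age - wgd_age
        i = parent.children.index(node)
        parent.children[i] = dup
        dup.parent = parent
        dup.add_child(node)
        node.length = wgd_age - node.age
        # the retained duplicate evolves independently to the present: clone
        sub = _clone_subtree(node)
        dup.add_child(sub)
    _relabel_copies(t)
    return t


def _clone_subtree(node: Node) -> Node:
    m = Node(node.name, node.length)
    m.age = node.age
    for c in node.children:
        m.add_child(_clone_subtree(c))
    return m


def _relabel_copies(t: Tree) -> None:
    counts: dict[tuple, int] = {}
    for leaf in t.leaves():
        taxon, fam, _ = parse_gene_id(leaf.name)
        k = counts.get((taxon, fam), 0)
        leaf.name = _leaf_label(taxon, fam, k)
        counts[(taxon, fam)] = k + 1


def simulate_codon_sequences(gene_tree: Tree, n_codons: int,
                             model: Optional[GTRModel] = None,
                             wgd: Optional[tuple] = None,
                             seed: int = 0,
                             _sampler: Optional[_CodonSampler] = None) -> dict:
    """Evolve codon sequences along a gene tree.

    Branch lengths (time units) are multiplied by ``model.rate_multiplier``
    to give expected nucleotide substitutions per site.  States are the 61
    sense codons; the root sequence is drawn from the stationary
    distribution, and substitutions into stop codons never occur.  ``wgd``
    is an optional ``(age, retained_fraction)`` pair inserting a genome-wide
    duplication before simulation.  Returns ``{leaf_name: cds_string}``;
    with no indels the true alignment is the sequences themselves.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    model = model or GTRModel()
    rng = np.random.default_rng(seed)
    if wgd is not None:
        age, retained = wgd
        gene_tree = _apply_wgd(gene_tree, age, retained, rng)
    sampler = _sampler or _CodonSampler(model)
    n_states = len(SENSE_CODONS)
    root_states = rng.choice(n_states, size=n_codons, p=sampler.stationary)
    out: dict[str, str] = {}

    def evolve(node: Node, states: np.ndarray) -> None:
        if node.parent is not None:
            t = node.length * model.rate_multiplier
            if t > 0:
                P = sampler.pmatrix(t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(len(states))
                new = np.empty_like(states)
                for s in np.unique(states):
                    m = states == s
                    new[m] = np.searchsorted(cum[s], u[m], side="right")
                states = np.minimum(new, n_states - 1)
        if node.is_leaf:
            out[node.name] = "".join(SENSE_CODONS[s] for s in states)
        else:
            for c in node.children:
                evolve(c, states.copy())

    evolve(gene_tree.root, root_states)
    return out


def translate_cds(cds: str) -> str:
    return "".join(translate_codon(cds[i:i + 3]) for i in range(0, len(cds), 3))


def simulate_family_sequences(families: list, n_codons: int = 150,
                              model: Optional[GTRModel] = None,
                              rate_jitter_sd: float = 0.0,
                              wgd: Optional[tuple] = None,
                              seed: int = 0) -> None:
    """Attach simulated CDS to every family (in place).

    Each family draws an independent root sequence (families are unrelated,
    so cross-family similarity is random noise).  ``rate_jitter_sd`` adds
    lognormal per-family rate variation.  A ``wgd`` (age, retained_fraction)
    is applied to the gene tree itself so the truth records (copy counts,
    single-copy flags, duplication labels) reflect the event.
    """
    from dataclasses import replace
    model = model or GTRModel()
    sampler = _CodonSampler(model)
    rng = np.random.default_rng(seed)
    for fam in families:
        if wgd is not None:
            age, retained = wgd
            fam.gene_tree = _apply_wgd(fam.gene_tree, age, retained, rng)
            counts: dict[str, int] = {t: 0 for t in fam.counts}
            for leaf in fam.gene_tree.leaves():
                counts[parse_gene_id(leaf.name)[0]] += 1
            fam.counts = counts
            fam.single_copy = all(c == 1 for c in counts.values())
        m = model
        if rate_jitter_sd > 0:
            m = replace(model, rate_multiplier=model.rate_multiplier *
                        float(rng.lognormal(0.0, rate_jitter_sd)))
        fam.sequences = simulate_codon_sequences(
            fam.gene_tree, n_codons, m, seed=int(rng.integers(2 ** 31 - 1)),
            _sampler=sampler)
        fam.alignment = dict(fam.sequences)


def simulate_nucleotide_sites(tree: Tree, n_sites: int,
                              model: Optional[GTRModel] = None,
                              rate: float = 1.0, seed: int = 0) -> dict:
    """Evolve independent nucleotide sites along a tree (no codon structure).

    Branch lengths are ``tree`` lengths times ``rate`` (expected
    substitutions per site) — handy for strict-clock dating benchmarks
    where lengths are ages in Ma and ``rate`` is subst/site/Ma.
    """
    from ._codons import NUCS, gtr_rate_matrix
    model = model or GTRModel()
    rng = np.random.default_rng(seed)
    Q = gtr_rate_matrix(model.exchangeabilities, model.freqs)
    pi = np.asarray(model.freqs)
    d = np.sqrt(pi)
    S = Q * d[:, None] / d[None, :]
    lam, U = np.linalg.eigh((S + S.T) / 2)

    def pmat(t):
        P = ((1.0 / d)[:, None] * U * np.exp(lam * t)[None, :]) @ (U.T * d[None, :])
        np.clip(P, 0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    out: dict[str, str] = {}

    def evolve(node: Node, states: np.ndarray) -> None:
        if node.parent is not None:
            t = node.length * rate
            if t > 0:
                P = pmat(t)
                cum = np.cumsum(P, axis=1)
                u = rng.random(len(states))
                new = np.empty_like(states)
                for s in range(4):
                    m = states == s
                    if m.any():
                        new[m] = np.searchsorted(cum[s], u[m], side="right")
                states = np.minimum(new, 3)
        if node.is_leaf:
            out[node.name] = "".join(NUCS[s] for s in states)
        else:
            for c in node.children:
                evolve(c, states.copy())

    root_states = rng.choice(4, size=n_sites, p=pi)
    evolve(tree.root, root_states)
    return out


# ----------------------------------------------------------- degradation
@dataclass
class DegradeResult:
    transcripts: dict            # gene id -> (possibly truncated) sequence
    truth_rows: list             # (taxon, family, gene, copy, single, masked_frac)
    fastq_paths: Optional[tuple] = None
    skipped: list = field(default_factory=list)


def degrade_and_emit(families: list[FamilyTruth], outdir=None,
                     missing_fraction: float = 0.0,
                     mask_overrides: Optional[dict] = None,
                     read_pairs: int = 0, read_length: int = 90,
                     low_quality_rate: float = 0.02, n_rate: float = 0.002,
                     bad_read_fraction: float = 0.02,
                     insert_mean: float = 250.0, insert_sd: float = 30.0,
                     encoding: str = "phred33",
                     seed: int = 0) -> DegradeResult:
    """Truncate transcripts and sample paired-end reads with artifacts.

    Each transcript loses a terminal fraction drawn uniformly on
    ``[0, 2*missing_fraction]`` (capped at 0.9), from a random end;
    ``mask_overrides[(taxon, gene_id)]`` forces an exact masked fraction.
    Reads of length ``read_length`` are sampled uniformly from transcripts
    (length-weighted), with per-base low-quality and N artifacts; a
    ``bad_read_fraction`` of pairs is wholly degraded (weak-signal reads
    with mostly low-quality bases and frequent Ns), the kind the quality
    screen is meant to remove.  Files are
    written only when ``outdir`` is given: per-taxon transcript FASTA and
    ``reads_1.fastq``/``reads_2.fastq``, plus ``truth_map.tsv``.
    """
    if not (0 <= missing_fraction < 1):
        raise ValueError("missing_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mask_overrides = mask_overrides or {}
    transcripts: dict[str, str] = {}
    truth_rows = []
    for fam in families:
        for gid, seqv in sorted(fam.sequences.items()):
            taxon, famid, copy = parse_gene_id(gid)
            frac = mask_overrides.get((taxon, gid),
                                      mask_overrides.get((taxon, famid), None))
            if frac is None:
                frac = min(rng.uniform(0.0, 2.0 * missing_fraction), 0.9) \
                    if missing_fraction > 0 else 0.0
            keep = len(seqv) - int(round(frac * len(seqv)))
            if frac > 0 and rng.random() < 0.5:
                trunc = seqv[-keep:] if keep > 0 else ""
            else:
                trunc = seqv[:keep]
            realized = 1.0 - len(trunc) / len(seqv)
            transcripts[gid] = trunc
            truth_rows.append((taxon, famid, gid, copy, fam.single_copy, realized))

    skipped = []
    reads = []
    if read_pairs > 0:
        frag_min = read_length
        usable = [(g, s) for g, s in transcripts.items() if len(s) >= frag_min]
        skipped = [g for g, s in transcripts.items() if len(s) < frag_min]
        if not usable:
            raise ValueError("no transcript long enough for the requested reads")
        lens = np.array([len(s) for _, s in usable], float)
        pidx = rng.choice(len(usable), size=read_pairs, p=lens / lens.sum())
        comp = str.maketrans("ACGTN", "TGCAN")
        for ri, ti in enumerate(pidx):
            gid, seqv = usable[ti]
            frag = int(np.clip(rng.normal(insert_mean, insert_sd),
                               read_length, len(seqv)))
            start = rng.integers(0, len(seqv) - frag + 1)
            fragment = seqv[start:start + frag]
            r1 = fragment[:read_length]
            r2 = fragment[-read_length:].translate(comp)[::-1]
            bad = rng.random() < bad_read_fraction
            lq = 0.6 if bad else low_quality_rate
            nr = 0.1 if bad else n_rate
            pair = []
            for mate in (r1, r2):
                bases = np.frombuffer(mate.encode(), dtype="S1").copy()
                qual = rng.integers(30, 41, size=len(mate))
                low = rng.random(len(mate)) < lq
                qual[low] = rng.integers(2, 8, size=low.sum())
                nn = rng.random(len(mate)) < nr
                bases[nn] = b"N"
                qual[nn] = 2
                pair.append((bases.tobytes().decode(), qual.tolist()))
            reads.append((f"read{ri}/{gid}", pair))

    fastq_paths = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_taxon: dict[str, list] = {}
        for gid, s in transcripts.items():
            by_taxon.setdefault(parse_gene_id(gid)[0], []).append((gid, s))
        for taxon, items in sorted(by_taxon.items()):
            with open(outdir / f"{taxon}_transcripts.fasta", "w") as fh:
                for gid, s in items:
                    if s:
                        fh.write(f">{gid}\n{s}\n")
        with open(outdir / "truth_map.tsv", "w") as fh:
            fh.write("taxon\tfamily_id\tgene_id\tcopy_index\tsingle_copy\tmasked_fraction\n")
            for row in truth_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        if reads:
            offset = 33 if encoding == "phred33" else 64
            p1, p2 = outdir / "reads_1.fastq", outdir / "reads_2.fastq"
            with open(p1, "w") as f1, open(p2, "w") as f2:
                for rid, (m1, m2) in reads:
                    for fh, (bases, qual), suff in ((f1, m1, "/1"), (f2, m2, "/2")):
                        qs = "".join(chr(q + offset) for q in qual)
                        fh.write(f"@{rid}{suff}\n{bases}\n+\n{qs}\n")
            fastq_paths = (p1, p2)

    res = DegradeResult(transcripts, truth_rows, fastq_paths, skipped)
    res.reads = reads  # in-memory access for tests
    return res
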