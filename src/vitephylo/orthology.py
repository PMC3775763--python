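"""H-score graph construction and gene-family clustering.

Cross-hit raw scores are normalised by the larger of the two self-scores
(H-score, 0–100), edges are kept only when the alignment covers more than a
third of both genes and the H-score exceeds the minimum weight, and the
resulting graph is cut into families by constrained average-linkage
agglomeration: a merge is admissible only while the merged cluster keeps
edge density above the minimum and the average linkage above the minimum
edge weight.  Families with exactly one gene per required taxon are the
1:1 single-copy orthologs used for supermatrix construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import networkx as nx

from .similarity import SimilarityHit

__all__ = ["GeneFamily", "h_score", "build_graph", "cluster_families",
           "select_single_copy", "default_taxon_of"]


def default_taxon_of(gene_id: str) -> str:
    """Taxon from a ``taxon|family|copy`` style gene id (first field)."""
    return gene_id.split("|")[0]


@dataclass
class GeneFamily:
    family_id: str
    members: list            # (taxon, gene_id) pairs
    edge_density: float
    single_copy: Optional[bool] = None

    def taxa_counts(self) -> dict:
        out: dict[str, int] = {}
        for taxon, _ in self.members:
            out[taxon] = out.get(taxon, 0) + 1
        return out

    def gene_ids(self) -> list[str]:
        return sorted(g for _, g in self.members)


def h_score(raw_ab: float, raw_aa: float, raw_bb: float) -> float:
    """Normalised similarity: raw_ab * 100 / max(raw_aa, raw_bb), in [0, 100]."""
    if raw_aa <= 0 or raw_bb <= 0:
        raise ValueError("self-scores must be positive")
    if raw_ab < 0:
        raise ValueError("cross score must be >= 0")
    return min(100.0, raw_ab * 100.0 / max(raw_aa, raw_bb))


def build_graph(hits: Iterable[SimilarityHit], lengths: Optional[dict] = None,
                min_mutual_coverage: float = 1.0 / 3.0,
                min_h: float = 5.0,
                taxon_of: Callable[[str], str] = default_taxon_of) -> nx.Graph:
    """Build the H-score-weighted ortholog graph from similarity hits.

    An edge (a, b) exists iff the aligned length is strictly longer than
    ``min_mutual_coverage`` of BOTH genes and the H-score is strictly
    larger than ``min_h``.  Raw cross-scores are symmetrised as the max of
    the two directions.  Gene lengths default to the self-hit aligned
    length; a missing self-hit is a hard error.
    """
    hits = list(hits)
    selfs = {h.query: h.raw_score for h in hits if h.query == h.subject}
    if lengths is None:
        lengths = {h.query: h.aligned_length_query
                   for h in hits if h.query == h.subject}
    genes = {h.query for h in hits} | {h.subject for h in hits}
    missing = sorted(g for g in genes if g not in selfs)
    if missing:
        raise ValueError(f"missing self-hits for: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    G = nx.Graph()
    for g in sorted(genes):
        G.add_node(g, taxon=taxon_of(g))
    # symmetrise: per unordered pair keep max raw score and per-gene max span
    pair: dict[tuple, list] = {}
    for h in hits:
        if h.query == h.subject:
            continue
        a, b = sorted((h.query, h.subject))
        cov_a = h.aligned_length_query if h.query == a else h.aligned_length_subject
        cov_b = h.aligned_length_subject if h.query == a else h.aligned_length_query
        rec = pair.setdefault((a, b), [0.0, 0, 0])
        rec[0] = max(rec[0], h.raw_score)
        rec[1] = max(rec[1], cov_a)
        rec[2] = max(rec[2], cov_b)
    for (a, b), (raw, cov_a, cov_b) in pair.items():
        if cov_a <= lengths[a] * min_mutual_coverage:
            continue
        if cov_b <= lengths[b] * min_mutual_coverage:
            continue
        w = h_score(raw, selfs[a], selfs[b])
        if w > min_h:
            G.add_edge(a, b, h_score=w)
    return G


def _avg_linkage(G: nx.Graph, ca: tuple, cb: tuple) -> float:
    """Mean H-score over all cross pairs; absent edges count 0."""
    total = 0.0
    for a in ca:
        for b in cb:
            d = G.get_edge_data(a, b)
            if d is not None:
                total += d["h_score"]
    return total / (len(ca) * len(cb))


def _internal_edges(G: nx.Graph, cluster: tuple) -> int:
    s = set(cluster)
    return sum(1 for a, b in G.edges(s) if a in s and b in s)


def cluster_families(G: nx.Graph, min_density: float = 1.0 / 3.0,
                     min_h: float = 5.0, density_mode: str = "merge",
                     ) -> list[GeneFamily]:
    """Cut the ortholog graph into gene families by constrained
    average-linkage agglomeration.

    Starting from singletons (within each connected component), the pair of
    clusters with the highest average linkage is merged repeatedly; a merge
    is admissible only if the merged cluster's edge density exceeds
    ``min_density`` AND the linkage exceeds ``min_h``.  A pair cluster has
    one theoretical edge, so pairs always satisfy the density rule.  Ties
    break on the lexicographically smallest (cluster-id, cluster-id) pair,
    where a cluster's id is its sorted member tuple.

    ``density_mode="post"`` instead merges on linkage alone and afterwards
    dissolves families that fail the density rule into singletons.
    """
    if density_mode not in ("merge", "post"):
        raise ValueError("density_mode must be 'merge' or 'post'")
    families: list[tuple] = []
    for comp in nx.connected_components(G):
        clusters = [(g,) for g in sorted(comp)]
        while len(clusters) > 1:
            best = None  # (neg linkage handled via comparisons)
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    ca, cb = clusters[i], clusters[j]
                    w = _avg_linkage(G, ca, cb)
                    if w <= min_h:
                        continue
                    merged = tuple(sorted(ca + cb))
                    if density_mode == "merge":
                        k = len(merged)
                        dens = _internal_edges(G, merged) / (k * (k - 1) / 2)
                        if dens <= min_density:
                            continue
                    key = (-w, tuple(sorted((ca, cb))))
                    if best is None or key < best[0]:
                        best = (key, i, j, merged)
            if best is None:
                break
            _, i, j, merged = best
            clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
            clusters.append(merged)
        families.extend(clusters)
    if density_mode == "post":
        final = []
        for c in families:
            k = len(c)
            if k <= 2:
                final.append(c)
                continue
            dens = _internal_edges(G, c) / (k * (k - 1) / 2)
            if dens > min_density:
                final.append(c)
            else:
                final.extend((g,) for g in c)
        families = final
    families.sort(key=lambda c: c[0])
    out = []
    for idx, c in enumerate(families):
        k = len(c)
        dens = 1.0 if k == 1 else _internal_edges(G, c) / (k * (k - 1) / 2)
        members = [(G.nodes[g]["taxon"], g) for g in c]
        out.append(GeneFamily(f"OG{idx:05d}", members, dens))
    return out


def select_single_copy(families: Iterable[GeneFamily],
                       required_taxa: Iterable[str]) -> list[GeneFamily]:
    """Keep 1:1 families: exactly one gene in every required taxon, none extra."""
    req = set(required_taxa)
    if not req:
        raise ValueError("required_taxa must be non-empty")
    out = []
    for fam in families:
        counts = fam.taxa_counts()
        ok = set(counts) == req and all(counts[t] == 1 for t in req)
        fam.single_copy = ok
        if ok:
            out.append(fam)
    return out


def write_families_tsv(families: Iterable[GeneFamily], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\ttaxon\tgene_id\n")
        for fam in families:
            for taxon, gid in sorted(fam.members):
                fh.write(f"{fam.family_id}\t{taxon}\t{gid}\n")
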