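"""Promoter sequence clustering and neighborhood-based candidate selection.

Promoters with similar sequence composition tend to share methylation
behaviour, so candidates can be picked by proximity — in a hierarchical
clustering of promoter sequences — to known methylation markers, or by
membership in clusters rich in demethylation-reactivated genes.

Sequences are summarised as normalised k-mer frequency profiles and
clustered by average linkage (UPGMA) on cosine distance.  "Distance"
between two genes is the number of internal nodes on the leaf-to-leaf
path of the dendrogram: siblings are 1 node apart, a gene is 0 nodes
from itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


def kmer_profile(seq: str, k: int = 6) -> dict[str, float]:
    """Normalised k-mer frequency profile of a DNA sequence.

    k-mers containing characters outside ACGT (e.g. N) are skipped.
    """
    seq = seq.upper()
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    counts: dict[str, int] = {}
    valid = set("ACGT")
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if set(kmer) <= valid:
            counts[kmer] = counts.get(kmer, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no valid k-mers (sequence all ambiguous?)")
    return {kmer: c / total for kmer, c in counts.items()}


@dataclass
class Dendrogram:
    """UPGMA tree over genes with leaf-to-leaf node distances."""

    leaves: list[str]  # lexicographically sorted gene ids
    merge: np.ndarray  # scipy linkage matrix
    _parent: dict[int, int]  # node id -> parent node id

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _path_to_root(self, node: int) -> list[int]:
        path = [node]
        while path[-1] in self._parent:
            path.append(self._parent[path[-1]])
        return path

    def node_distance(self, gene_a: str, gene_b: str) -> int:
        """Number of internal nodes on the unique path between two leaves."""
        try:
            a = self.leaves.index(gene_a)
            b = self.leaves.index(gene_b)
        except ValueError as exc:
            raise KeyError(f"unknown leaf: {exc}") from exc
        if a == b:
            return 0
        path_a = self._path_to_root(a)
        path_b = self._path_to_root(b)
        set_b = set(path_b)
        lca = next(n for n in path_a if n in set_b)
        # internal nodes strictly below the LCA on each side, plus the LCA
        below_a = path_a.index(lca) - 1  # excludes leaf itself and the LCA
        below_b = path_b.index(lca) - 1
        return below_a + below_b + 1


def build_dendrogram(profiles: dict[str, dict[str, float]]) -> Dendrogram:
    """UPGMA clustering of k-mer profiles under cosine distance.

    Genes are sorted lexicographically before clustering so the result is
    independent of input order; identical profiles merge at height 0.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 genes to cluster")
    genes = sorted(profiles)
    vocab = sorted({k for p in profiles.values() for k in p})
    mat = np.array(
        [[profiles[g].get(k, 0.0) for k in vocab] for g in genes], dtype=float
    )
    dist = pdist(mat, metric="cosine")
    dist = np.clip(dist, 0.0, None)  # numerical noise can go slightly negative
    z = linkage(dist, method="average")
    n = len(genes)
    parent: dict[int, int] = {}
    for i, (left, right, _, _) in enumerate(z):
        parent[int(left)] = n + i
        parent[int(right)] = n + i
    return Dendrogram(genes, z, parent)


def _clusters(tree: Dendrogram, max_nodes: int) -> list[set[str]]:
    """Connected components of the graph linking leaves < max_nodes apart."""
    genes = tree.leaves
    n = len(genes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if tree.node_distance(genes[i], genes[j]) < max_nodes:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i, g in enumerate(genes):
        comps.setdefault(find(i), set()).add(g)
    return list(comps.values())


def select_candidates(
    tree: Dendrogram,
    known_markers: set[str],
    events: dict[str, int],
    max_nodes: int = 8,
    min_genes: int = 2,
    min_events: int = 3,
) -> pd.DataFrame:
    """Select candidate genes by marker neighborhood or reactive clusters.

    A gene is selected if it lies fewer than ``max_nodes`` internal nodes
    from a known methylation marker (reason ``near_known_marker``), or if
    its cluster — a connected component of leaf pairs closer than
    ``max_nodes`` — contains at least ``min_genes`` genes with at least
    ``min_events`` reactivation events (reason ``reactive_cluster``).
    Marker proximity takes precedence as the recorded primary reason.
    """
    missing = [g for g in tree.leaves if g not in events]
    if missing:
        raise ValueError(f"reactivation events undefined for {missing}")

    rows: list[dict] = []
    selected: set[str] = set()
    markers_in_tree = sorted(known_markers & set(tree.leaves))
    for gene in tree.leaves:
        dists = [
            tree.node_distance(gene, m) for m in markers_in_tree if m != gene
        ]
        near = [d for d in dists if d < max_nodes]
        if near:
            rows.append(
                {
                    "gene": gene,
                    "reason": "near_known_marker",
                    "distance_to_marker": min(near),
                    "cluster": pd.NA,
                }
            )
            selected.add(gene)

    for cid, comp in enumerate(_clusters(tree, max_nodes)):
        rich = [g for g in comp if events[g] >= min_events]
        if len(rich) >= min_genes:
            for gene in sorted(comp):
                if gene not in selected:
                    rows.append(
                        {
                            "gene": gene,
                            "reason": "reactive_cluster",
                            "distance_to_marker": pd.NA,
                            "cluster": cid,
                        }
                    )
                    selected.add(gene)

    return pd.DataFrame(
        rows, columns=["gene", "reason", "distance_to_marker", "cluster"]
    )
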