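"""k-means clustering of TSS matrices and hypergeometric set intersections."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from chromaquant.annotation import GeneAnnotation
from chromaquant.coverage import TSSMatrix


@dataclass
class ClusterAssignment:
    """Deterministically renumbered k-means result.

    Labels run 1..k ordered by descending cluster size (ties by descending
    centroid norm). ``dropped`` lists genes excluded for excessive masking.
    """

    gene_ids: List[str]
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    seed: int
    n_init: int
    dropped: List[str]

    def members(self, label: int) -> List[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == label]

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="cluster")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def _prepare_rows(
    matrix: TSSMatrix, max_masked_frac: float = 0.5
) -> Tuple[List[str], np.ndarray, List[str]]:
    """Drop heavily masked genes, impute remaining NaNs with the row mean."""
    kept_ids: List[str] = []
    rows: List[np.ndarray] = []
    dropped: List[str] = []
    n = matrix.window_spec.n_windows
    for gid in matrix.gene_ids:
        row = matrix.row(gid)
        frac_masked = np.isnan(row).sum() / n
        if frac_masked > max_masked_frac:
            dropped.append(gid)
            continue
        filled = row.copy()
        filled[np.isnan(filled)] = np.nanmean(row)
        kept_ids.append(gid)
        rows.append(filled)
    data = np.stack(rows) if rows else np.empty((0, n))
    return kept_ids, data, dropped


def kmeans_clusters(
    delta_matrix: TSSMatrix,
    k: int = 6,
    seed: int = 0,
    n_init: int = 20,
    standardize: bool = False,
) -> ClusterAssignment:
    """Euclidean k-means (k-means++ init, best of ``n_init`` restarts).

    Genes with more than half their windows masked are dropped; remaining
    masked cells are imputed with the gene's row mean. Rows are clustered
    raw unless ``standardize`` is set (then z-scored per row).
    """
    gene_ids, data, dropped = _prepare_rows(delta_matrix)
    if len(gene_ids) < k:
        raise ValueError(f"only {len(gene_ids)} usable genes for k={k}")
    if standardize:
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=1, keepdims=True)) / sd
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, init="k-means++")
    raw_labels = km.fit_predict(data)
    sizes = np.bincount(raw_labels, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], -norms[c], c))
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in raw_labels])
    centroids = km.cluster_centers_[order]
    return ClusterAssignment(
        gene_ids=gene_ids,
        labels=labels,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
        dropped=dropped,
    )


def hypergeom_p(universe_size: int, annotated: int, drawn: int, overlap: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap).

    ``universe_size`` = N, ``annotated`` = K marked items, ``drawn`` = n
    items drawn, ``overlap`` = k marked items observed in the draw.
    """
    N, K, n, k = universe_size, annotated, drawn, overlap
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent sizes N={N}, K={K}, n={n}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def rate_class_table(
    clusters: ClusterAssignment, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Hypergeometric intersection of every cluster with every rate class.

    The universe is the clustered genes that carry a rate class; classes must
    partition that universe (one class per gene).
    """
    rate_map = annotation.rate_class_map()
    universe = [g for g in clusters.gene_ids if g in rate_map]
    n_universe = len(universe)
    if n_universe == 0:
        raise ValueError("no clustered genes carry a rate class")
    class_members: Dict[str, Set[str]] = {}
    for g in universe:
        class_members.setdefault(rate_map[g], set()).add(g)
    rows = []
    label_of = dict(zip(clusters.gene_ids, clusters.labels))
    for label in range(1, clusters.k + 1):
        members = {g for g in universe if label_of[g] == label}
        for rc, cls in sorted(class_members.items()):
            overlap = len(members & cls)
            p = hypergeom_p(n_universe, len(cls), len(members), overlap)
            rows.append(
                {
                    "cluster": label,
                    "rate_class": rc,
                    "cluster_size": len(members),
                    "class_size": len(cls),
                    "overlap": overlap,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- set algebra


def venn_partition(
    named_sets: Mapping[str, Set[str]]
) -> Dict[FrozenSet[str], Set[str]]:
    """Exact exclusive regions of an n-way Venn diagram.

    Maps each non-empty combination of set names to the elements belonging
    to exactly those sets. Regions are pairwise disjoint and their union is
    the union of the inputs.
    """
    names = list(named_sets)
    regions: Dict[FrozenSet[str], Set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(named_sets[c] for c in combo)) if combo else set()
            outside = set.union(*(named_sets[c] for c in names if c not in combo), set())
            regions[frozenset(combo)] = inside - outside
    return regions


def venn_sets(
    de_tables: Mapping[str, pd.DataFrame]
) -> Dict[Tuple[str, str], Dict[str, object]]:
    """Common/unique up- and down-regulated sets across strains.

    Each table needs columns ``gene_id``, ``strand_class`` and ``status``
    over an identical (gene, strand_class) universe. For every
    (strand_class, direction) the result holds the all-strain intersection
    (``common``), per-strain exclusive sets (``unique``) and the full Venn
    partition (``partition``).
    """
    strains = list(de_tables)
    if not strains:
        raise ValueError("venn_sets: no tables given")
    universes = {
        s: set(zip(t["gene_id"], t["strand_class"])) for s, t in de_tables.items()
    }
    first = universes[strains[0]]
    for s in strains[1:]:
        if universes[s] != first:
            raise ValueError(f"venn_sets: universe mismatch between {strains[0]} and {s}")
    out: Dict[Tuple[str, str], Dict[str, object]] = {}
    strand_classes = sorted({sc for _, sc in first})
    for sc in strand_classes:
        for direction in ("up", "down"):
            sets = {
                s: set(
                    t.loc[
                        (t["strand_class"] == sc) & (t["status"] == direction),
                        "gene_id",
                    ]
                )
                for s, t in de_tables.items()
            }
            partition = venn_partition(sets)
            out[(sc, direction)] = {
                "common": set.intersection(*sets.values()),
                "unique": {s: partition[frozenset([s])] for s in strains},
                "partition": partition,
            }
    return out
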