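"""Ward.D2 hierarchical clustering of germplasms and subgroup summaries.

Germplasms are clustered on Euclidean distances over the final standardized
trait set (ordinal-coded qualitative and quantitative traits enter
identically) with Ward's minimum-variance criterion on squared distances.
Merge heights are reported on the distance scale, sqrt(2 x increase in
within-cluster sum of squares), so a two-point merge sits at the points'
Euclidean distance. Partitions are taken by cluster count k — cut heights
are data- and convention-dependent, counts are reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .traitdata import (
    CULTIVAR,
    SPECIES,
    GermplasmRegister,
    TraitMatrix,
    _mode_smallest_code,
)
from .util import round_half_up

logger = logging.getLogger("phenotax")


def euclidean_distances(m: TraitMatrix) -> pd.DataFrame:
    """Symmetric germplasm x germplasm Euclidean distance matrix."""
    d = squareform(pdist(m.data.to_numpy(dtype=float), metric="euclidean"))
    ids = m.germplasm_ids
    return pd.DataFrame(d, index=ids, columns=ids)


def gower_distances(m: TraitMatrix) -> pd.DataFrame:
    """Gower distance for mixed traits: range-normalized Manhattan per
    quantitative trait, simple mismatch per qualitative trait, averaged."""
    cb = m.codebook
    X = m.data
    n = len(X)
    acc = np.zeros((n, n))
    for trait in m.trait_names:
        col = X[trait].to_numpy(dtype=float)
        if cb.is_qualitative(trait):
            part = (col[:, None] != col[None, :]).astype(float)
        else:
            rng = col.max() - col.min()
            part = np.zeros((n, n)) if rng == 0 else np.abs(
                col[:, None] - col[None, :]) / rng
        acc += part
    d = acc / len(m.trait_names)
    return pd.DataFrame(d, index=m.germplasm_ids, columns=m.germplasm_ids)


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form plus leaf labels.

    ``linkage`` rows are (node a, node b, height, size); leaves 0..n-1 map
    onto ``labels`` in input order.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences."""
        tree = hierarchy.to_tree(self.linkage)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        root = f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"
        return root


def ward_d2(dist: pd.DataFrame) -> Dendrogram:
    """Ward minimum-variance clustering on a Euclidean distance matrix.

    Heights follow the distance-scale convention: the height of a merge is
    sqrt(2 x increase in total within-cluster sum of squares), which for two
    singletons equals their Euclidean distance.
    """
    if len(dist) < 2:
        raise ValueError("need at least 2 germplasms")
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    Z = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(Z, list(dist.index))


@dataclass
class Partition:
    """Germplasm -> cluster label map; labels are 1..k by first occurrence
    in leaf input order."""

    assignments: dict[str, int]
    level: str = "group"

    def clusters(self) -> list[int]:
        return sorted(set(self.assignments.values()))

    def members(self, label: int) -> list[str]:
        return [g for g, c in self.assignments.items() if c == label]

    def sizes(self) -> dict[int, int]:
        return {c: len(self.members(c)) for c in self.clusters()}

    def labels_for(self, ids: list[str]) -> list[int]:
        return [self.assignments[g] for g in ids]


def cut(d: Dendrogram, k: int, level: str = "group") -> Partition:
    """Cut the tree into exactly k clusters; labels renumbered 1..k by first
    occurrence in input order (deterministic)."""
    if not 1 <= k <= d.n_leaves:
        raise ValueError(f"k={k} out of range 1..{d.n_leaves}")
    raw = hierarchy.fcluster(d.linkage, t=k, criterion="maxclust")
    if len(set(raw)) != k:
        # maxclust can undershoot with tied heights; cut between merge heights
        n = d.n_leaves
        if k < n:
            lo = d.linkage[n - k - 1, 2]
            hi = d.linkage[n - k, 2]
            if hi > lo:
                raw = hierarchy.fcluster(d.linkage, t=(lo + hi) / 2,
                                         criterion="distance")
        else:
            raw = np.arange(1, n + 1)
    if len(set(raw)) != k:
        raise ValueError(f"could not produce exactly {k} clusters (tied merge heights)")
    relabel: dict[int, int] = {}
    for r in raw:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
    return Partition({g: relabel[r] for g, r in zip(d.labels, raw)}, level=level)


@dataclass
class GroupSummary:
    counts: pd.DataFrame  # cluster x (n, n_species, n_cultivars)
    quantitative: pd.DataFrame  # (cluster, trait) -> mean, sd, singleton flag
    qualitative_modes: pd.DataFrame  # cluster x trait modal level


def summarize_groups(p: Partition, m: TraitMatrix,
                     reg: GermplasmRegister) -> GroupSummary:
    """Per-cluster membership counts, quantitative mean +/- sd, and
    qualitative modal levels. A singleton cluster's sd is reported as 0 and
    flagged."""
    cb = m.codebook
    quant = [t for t in m.trait_names if not cb.is_qualitative(t)]
    qual = [t for t in m.trait_names if cb.is_qualitative(t)]
    count_rows, quant_rows, mode_rows = [], [], []
    total = 0
    for c in p.clusters():
        ids = [g for g in p.members(c) if g in m.germplasm_ids]
        assert ids, f"empty cluster {c}"
        total += len(ids)
        sub = m.data.loc[ids]
        n_sp = sum(1 for g in ids if reg[g].rank == SPECIES)
        count_rows.append({"cluster": c, "n": len(ids), "n_species": n_sp,
                           "n_cultivars": len(ids) - n_sp})
        for t in quant:
            vals = sub[t].to_numpy()
            singleton = len(vals) < 2
            quant_rows.append({
                "cluster": c, "trait": t,
                "mean": float(vals.mean()),
                "sd": 0.0 if singleton else float(vals.std(ddof=1)),
                "singleton": singleton,
            })
        mode_rows.append({"cluster": c, **{
            t: _mode_smallest_code(sub[t].to_numpy()) for t in qual}})
    counts = pd.DataFrame(count_rows).set_index("cluster")
    assert counts["n"].sum() == total
    quant_df = (pd.DataFrame(quant_rows).set_index(["cluster", "trait"])
                if quant_rows else pd.DataFrame())
    modes = pd.DataFrame(mode_rows).set_index("cluster") if qual else pd.DataFrame()
    return GroupSummary(counts, quant_df, modes)


def species_proportions(p: Partition, reg: GermplasmRegister) -> dict[int, float]:
    """Per cluster, the percentage of its members that are species
    (rounded to 1 decimal, half-up)."""
    out = {}
    for c in p.clusters():
        ids = p.members(c)
        if not ids:
            raise ValueError(f"empty cluster {c}")
        n_sp = sum(1 for g in ids if reg[g].rank == SPECIES)
        out[c] = round_half_up(100.0 * n_sp / len(ids), 1)
    return out


def species_share(p: Partition, reg: GermplasmRegister) -> dict[int, float]:
    """How the species (not cultivars) distribute across clusters: per
    cluster, the percentage of all species found there (rounds to 1 decimal,
    half-up; values sum to ~100)."""
    species = [g for g in p.assignments if reg[g].rank == SPECIES]
    if not species:
        raise ValueError("no species in partition")
    out = {}
    for c in p.clusters():
        n_sp = sum(1 for g in species if p.assignments[g] == c)
        out[c] = round_half_up(100.0 * n_sp / len(species), 1)
    return out
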