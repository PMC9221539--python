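"""Ensemble-level comparison: pairwise dissimilarity, hierarchical
clustering, the predicted-model outlier test and the resolution–deviation
correlation.

The null hypothesis under test is that a predicted model is an outlier
clustering apart from the crystal structures; it is rejected when, at the
stated dendrogram cut height, the model shares a cluster with crystal
structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import confstats
from .irdm import distance_matrix, irdm_compare
from .structio import CorrespondenceMap, Level, ResidueId, Structure, _atoms_for_level
from .superpose import rmsd_structures

__all__ = [
    "DissimilarityMatrix",
    "ClusterTree",
    "common_residues",
    "pairwise_dissimilarity",
    "hcluster",
    "split_groups",
    "group_comparison",
    "outlier_test",
    "resolution_correlation",
]

MetricKind = Literal["rmsd", "irdm"]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    values: np.ndarray  # m×m, Å
    metric_kind: MetricKind
    level: Level

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if self.values.shape != (m, m):
            raise ValueError("labels/values size mismatch")
        if not np.allclose(self.values, self.values.T) or np.any(np.diag(self.values) != 0):
            raise ValueError("dissimilarity matrix must be symmetric with zero diagonal")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class ClusterTree:
    """Agglomerative clustering result: a scipy linkage matrix plus leaf labels."""

    linkage_matrix: np.ndarray  # (m-1, 4) scipy format, heights in Å
    labels: list[str]
    linkage: str

    def cut(self, height: float) -> dict[str, int]:
        """Partition by cutting at the given height; returns label -> cluster id."""
        assign = hierarchy.fcluster(self.linkage_matrix, t=height, criterion="distance")
        return dict(zip(self.labels, (int(c) for c in assign)))

    def n_clusters_at(self, height: float) -> int:
        return len(set(self.cut(height).values()))

    def newick(self) -> str:
        """Dendrogram as a Newick string with branch lengths from merge heights."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def walk(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(root.left, root.dist)
        right = walk(root.right, root.dist)
        return f"({left},{right});"


def common_residues(structures: Sequence[Structure], level: Level) -> list[ResidueId]:
    """Residue ids present in every structure with all atoms the level needs.

    At the allatom level a residue qualifies if every structure pair shares
    at least its Cα and main-chain names; side-chain names are intersected
    pairwise at comparison time.
    """
    if not structures:
        raise ValueError("empty ensemble")
    first = structures[0]
    ids: list[ResidueId] = []
    for r in first.residues:
        ok = True
        for s in structures:
            r2 = s.residue_map().get(r.rid)
            if r2 is None or _atoms_for_level(r, r2, level) is None:
                ok = False
                break
        if ok:
            ids.append(r.rid)
    return ids


def pairwise_dissimilarity(
    structures: Sequence[Structure],
    metric_kind: MetricKind = "rmsd",
    level: Level = "calpha",
    residue_mode: Literal["ensemble_common", "pairwise_common"] = "ensemble_common",
) -> DissimilarityMatrix:
    """All-against-all RMSD or IRDM metric over an ensemble.

    By default every pair is compared on the ensemble-wide common residue
    set so all entries share one n (required for a coherent clustering);
    ``pairwise_common`` compares each pair on its own intersection instead.
    """
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    labels = [s.id for s in structures]
    m = len(structures)
    values = np.zeros((m, m))

    shared = common_residues(structures, level) if residue_mode == "ensemble_common" else None
    if residue_mode == "ensemble_common" and not shared:
        raise ValueError("no residues common to the whole ensemble at this level")

    irdm_cache = {}
    if metric_kind == "irdm" and shared is not None:
        ca_shared = shared if level == "calpha" else common_residues(structures, "calpha")
        irdm_cache = {i: distance_matrix(s, ca_shared) for i, s in enumerate(structures)}

    for i in range(m):
        for j in range(i + 1, m):
            a, b = structures[i], structures[j]
            if metric_kind == "rmsd":
                if shared is not None:
                    sub_a, sub_b = a.subset(shared), b.subset(shared)
                else:
                    sub_a, sub_b = a, b
                from .structio import build_correspondence
                cmap = build_correspondence(sub_a, sub_b, level)
                values[i, j] = values[j, i] = rmsd_structures(sub_a, sub_b, cmap)
            else:
                if shared is not None:
                    d1, d2 = irdm_cache[i], irdm_cache[j]
                else:
                    from .structio import build_correspondence
                    cmap = build_correspondence(a, b, "calpha")
                    d1 = distance_matrix(a, cmap.a_ids())
                    d2 = distance_matrix(b, cmap.b_ids())
                values[i, j] = values[j, i] = irdm_compare(d1, d2).metric
    return DissimilarityMatrix(labels=labels, values=values, metric_kind=metric_kind, level=level)


def hcluster(d: DissimilarityMatrix, linkage: Literal["average", "complete", "single"] = "average") -> ClusterTree:
    """Agglomerative clustering of the ensemble (UPGMA by default)."""
    z = hierarchy.linkage(d.condensed(), method=linkage)
    return ClusterTree(linkage_matrix=z, labels=list(d.labels), linkage=linkage)


def split_groups(d: DissimilarityMatrix, predicted_label: str) -> tuple[np.ndarray, np.ndarray]:
    """Split a dissimilarity matrix into the two comparison groups.

    Returns (predicted-vs-crystal values: m entries, crystal-vs-crystal
    values: m(m−1)/2 upper-triangle entries), where m is the number of
    crystal structures.
    """
    if predicted_label not in d.labels:
        raise ValueError(f"unknown label {predicted_label!r}")
    k = d.labels.index(predicted_label)
    others = [i for i in range(len(d.labels)) if i != k]
    af_vs_crystal = d.values[k, others]
    sub = d.values[np.ix_(others, others)]
    iu = np.triu_indices(len(others), k=1)
    return af_vs_crystal, sub[iu]


def group_comparison(af_vs_crystal: Sequence[float], within_crystal: Sequence[float]) -> dict:
    """Medians, means and Welch's t-test between the two comparison groups."""
    a = np.asarray(af_vs_crystal, dtype=float)
    b = np.asarray(within_crystal, dtype=float)
    test = confstats.welch_t(a, b)
    return {
        "median_af_vs_crystal": float(np.median(a)),
        "median_within_crystal": float(np.median(b)),
        "mean_af_vs_crystal": float(np.mean(a)),
        "mean_within_crystal": float(np.mean(b)),
        "welch": test,
    }


def outlier_test(tree: ClusterTree, member: str, height: float) -> dict:
    """Is ``member`` alone in its cluster when the tree is cut at ``height``?"""
    if member not in tree.labels:
        raise ValueError(f"unknown label {member!r}")
    assign = tree.cut(height)
    cluster = assign[member]
    co_members = [l for l, c in assign.items() if c == cluster and l != member]
    return {"is_singleton": not co_members, "cluster_members": co_members, "height": height}


def resolution_correlation(
    structures: Sequence[Structure],
    reference: Structure,
    level: Level = "calpha",
) -> dict:
    """Pearson correlation between crystal resolution and RMSD to a reference.

    The reference structure is excluded from the (resolution, RMSD) pairs.
    """
    from .structio import build_correspondence

    xs, ys, labels = [], [], []
    for s in structures:
        if s.id == reference.id:
            continue
        if s.resolution is None:
            continue
        cmap = build_correspondence(s, reference, level)
        xs.append(s.resolution)
        ys.append(rmsd_structures(s, reference, cmap))
        labels.append(s.id)
    if len(xs) < 3:
        raise ValueError(f"need at least 3 structures with resolution, got {len(xs)}")
    test = confstats.pearson(xs, ys)
    return {"cc": test.statistic, "p": test.p, "n": len(xs),
            "resolutions": xs, "rmsds": ys, "labels": labels}
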