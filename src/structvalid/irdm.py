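"""Inter-residue distance map (IRDM) metric.

An IRDM is the n×n matrix of Cα–Cα Euclidean distances within one
structure.  Because inter-atomic distances are invariant under translation
and rotation, comparing two structures through their IRDMs needs no
superposition: each residue i is represented by its distance vector to all
n residues, the per-residue discrepancy is the Euclidean distance between
the corresponding rows,

    e_i = sqrt( Σ_j (d1[i,j] − d2[i,j])² ),

and the overall metric is the root mean square of the e_i,

    IRDM(d1, d2) = sqrt( (1/n) Σ_i e_i² ) = ‖D1 − D2‖_F / √n ,

a norm-induced metric in Å.  Note that distances are blind to chirality: a
structure and its mirror image have identical IRDMs but nonzero RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structio import ResidueId, ResidueProfile, Structure, format_residue_id

__all__ = ["DistanceMatrix", "IrdmComparison", "distance_matrix", "irdm_compare"]


@dataclass
class DistanceMatrix:
    d: np.ndarray  # n×n, Å
    residue_ids: list[ResidueId]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.residue_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n},{n})")
        if np.any(self.d < 0) or not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("not a valid distance matrix (symmetry/diagonal/sign)")

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass
class IrdmComparison:
    metric: float  # Å
    row_profile: ResidueProfile  # e_i per residue
    diff_map: np.ndarray  # |d1 - d2|, n×n


def distance_matrix(s: Structure, ids: Sequence[ResidueId] | None = None) -> DistanceMatrix:
    """Cα inter-residue distance map over all residues or a stated subset."""
    if ids is None:
        ids = [r.rid for r in s.residues]
    rmap = s.residue_map()
    missing = [rid for rid in ids if rmap[rid].atom("CA") is None]
    if missing:
        raise ValueError(
            "residues without CA: " + ", ".join(format_residue_id(r) for r in missing)
        )
    coords = np.vstack([rmap[rid].atom("CA").coord for rid in ids])
    return DistanceMatrix(squareform(pdist(coords)), list(ids))


def irdm_compare(d1: DistanceMatrix, d2: DistanceMatrix) -> IrdmComparison:
    """Compare two aligned IRDMs; both must be built on the same residue pairing."""
    if d1.n != d2.n:
        raise ValueError(f"shape mismatch: {d1.n} vs {d2.n} residues")
    delta = d1.d - d2.d
    e = np.sqrt(np.sum(delta**2, axis=1))
    metric = float(np.sqrt(np.mean(e**2)))
    profile = ResidueProfile(list(d1.residue_ids), e, label="irdm_row_distance")
    return IrdmComparison(metric=metric, row_profile=profile, diff_map=np.abs(delta))
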