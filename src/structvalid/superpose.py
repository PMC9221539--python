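"""Kabsch least-squares superposition and RMSD.

RMSD is computed after optimal rigid superposition (proper rotations only;
no reflection), at three atom levels: Cα only, main chain (N, CA, C, O), or
all heavy atoms shared by name between paired residues.  Residue-wise
deviation profiles use a single global Cα superposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structio import (
    CorrespondenceMap,
    Level,
    ResidueProfile,
    Structure,
    _atoms_for_level,
    structure_coords,
)

__all__ = ["SuperpositionResult", "kabsch", "rmsd_structures", "per_residue_deviation", "raw_rmsd"]


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector, Å
    rmsd: float  # Å
    npoints: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map coordinates from the mobile frame onto the reference frame."""
        return coords @ self.rotation.T + self.translation


def kabsch(p: np.ndarray, q: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of ``q`` (mobile) onto ``p`` (reference).

    Minimizes the RMSD between paired rows over proper rotations and
    translations; the returned transform maps q-frame coordinates into the
    p frame.  Collinear (rank-deficient) point sets succeed with a warning
    since the minimizing rotation is then non-unique.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("p and q must be matching N×3 arrays")
    n = p.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    p0 = p - pc
    q0 = q - qc
    h = q0.T @ p0
    u, s, vt = np.linalg.svd(h)
    if np.linalg.matrix_rank(q0, tol=1e-8) < 2 or s[1] < 1e-10 * max(s[0], 1e-30):
        warnings.warn("collinear/degenerate point set: superposition is not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = pc - rot @ qc
    moved = q @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - p) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd, npoints=n)


def _paired_coords(a: Structure, b: Structure, cmap: CorrespondenceMap) -> tuple[np.ndarray, np.ndarray]:
    pa = structure_coords(a, cmap.a_ids(), cmap.level, other=b, other_side=cmap.b_ids())
    pb = structure_coords(b, cmap.b_ids(), cmap.level, other=a, other_side=cmap.a_ids())
    return pa, pb


def rmsd_structures(a: Structure, b: Structure, cmap: CorrespondenceMap) -> float:
    """RMSD (Å) between two structures over the mapped atoms, after superposition."""
    if len(cmap) == 0:
        raise ValueError("empty correspondence map")
    pa, pb = _paired_coords(a, b, cmap)
    return kabsch(pa, pb).rmsd


def raw_rmsd(a: Structure, b: Structure, cmap: CorrespondenceMap) -> float:
    """RMSD of the coordinates as stored, with no superposition."""
    pa, pb = _paired_coords(a, b, cmap)
    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))


def per_residue_deviation(a: Structure, b: Structure, cmap: CorrespondenceMap) -> ResidueProfile:
    """Residue-wise deviation after one global Cα superposition.

    Each residue's value is the RMSD over its mapped atoms at the map's
    level; for ``calpha`` maps this is simply the Cα–Cα distance.  Keys are
    the map's A-side residue ids in map order.
    """
    if len(cmap) == 0:
        raise ValueError("empty correspondence map")
    # global fit always on Cα, regardless of the map's level
    amap = a.residue_map()
    bmap = b.residue_map()
    ca_pairs = [(ra, rb) for ra, rb in cmap.pairs
                if amap[ra].atom("CA") is not None and bmap[rb].atom("CA") is not None]
    if len(ca_pairs) < 3:
        raise ValueError("fewer than 3 Cα pairs for the global superposition")
    pa = np.vstack([amap[ra].atom("CA").coord for ra, _ in ca_pairs])
    pb = np.vstack([bmap[rb].atom("CA").coord for _, rb in ca_pairs])
    fit = kabsch(pa, pb)

    keys = []
    values = []
    for ra, rb in cmap.pairs:
        res_a, res_b = amap[ra], bmap[rb]
        names = _atoms_for_level(res_a, res_b, cmap.level)
        if names is None:
            continue
        ca_coords = np.vstack([res_a.atom(n).coord for n in names])
        cb_coords = fit.apply(np.vstack([res_b.atom(n).coord for n in names]))
        keys.append(ra)
        values.append(float(np.sqrt(np.mean(np.sum((ca_coords - cb_coords) ** 2, axis=1)))))
    return ResidueProfile(keys, np.array(values), label=f"deviation_{cmap.level}")
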