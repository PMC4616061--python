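"""Rigid-body superposition, RMSD and dihedral mathematics.

Every similarity measure in the pipeline — Cα/backbone RMSD to a reference,
pairwise RMSD matrices for clustering, and the mass-weighted RMSD series that
drives the trajectory-convergence criterion — reduces to a least-squares
rigid superposition (Kabsch) followed by a root-mean-square of the residual
pairwise distances.  Dihedral angles use the IUPAC sign convention
(cis = 0°, trans = 180°, value in (-180, 180]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structio import Structure

__all__ = [
    "Superposition",
    "kabsch_superpose",
    "ca_rmsd",
    "backbone_rmsd",
    "heavy_atom_rmsd",
    "dihedral",
    "rmsd_series_std",
]

# Atomic masses (amu) used for mass-weighted fits.
ATOM_MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999, "H": 1.008, "CB": 12.011}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid fit of a mobile point set onto a target.

    ``rotation`` is a proper rotation (det = +1); applying
    ``rotation @ x + translation`` to the mobile points minimises the
    (weighted) RMSD, whose optimal value is stored in ``rmsd``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> Superposition:
    """Least-squares optimal rigid superposition of ``mobile`` onto ``target``.

    Uses the SVD formulation with the determinant sign fix, so the returned
    rotation is always proper (no reflection).  ``weights`` (e.g. atomic
    masses) give the weighted variant used by the convergence monitor.

    Raises ``ValueError`` for mismatched sizes or fewer than 3 points.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"point sets differ in shape: {mobile.shape} vs {target.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must be one value per point")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(axis=0) / wsum
    ct = (w[:, None] * target).sum(axis=0) / wsum
    p = mobile - cm
    q = target - ct
    h = (w[:, None] * p).T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    dmat = np.diag([1.0, 1.0, d])
    rot = vt.T @ dmat @ u.T
    diff = p @ rot.T - q
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    trans = ct - rot @ cm
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def _region_indices(length: int, region: Optional[Sequence[int]]) -> np.ndarray:
    if region is None:
        return np.arange(length)
    idx = np.asarray(sorted(region), dtype=int)
    if idx.size == 0:
        raise ValueError("region is empty")
    if idx.min() < 0 or idx.max() >= length:
        raise ValueError(f"region indices out of range for length {length}")
    return idx


def _selection_coords(struct: "Structure", atoms: Sequence[str], idx: np.ndarray) -> np.ndarray:
    coords = []
    for name in atoms:
        arr = struct.coords.get(name)
        if arr is None:
            raise ValueError(f"atoms unavailable: structure lacks {name} coordinates")
        sub = arr[idx]
        if np.isnan(sub).any():
            raise ValueError(f"atoms unavailable: {name} missing in selected region")
        coords.append(sub)
    # interleave per residue: res0 atoms..., res1 atoms...
    return np.stack(coords, axis=1).reshape(-1, 3)


def _pair_rmsd(a: "Structure", b: "Structure", atoms: Sequence[str], region) -> float:
    if len(a.sequence) != len(b.sequence):
        raise ValueError("structures differ in length")
    idx = _region_indices(len(a.sequence), region)
    pa = _selection_coords(a, atoms, idx)
    pb = _selection_coords(b, atoms, idx)
    return kabsch_superpose(pa, pb).rmsd


def ca_rmsd(a: "Structure", b: "Structure", region: Optional[Sequence[int]] = None) -> float:
    """Cα RMSD after optimal superposition, optionally over a residue subset.

    ``region`` is a 0-based index set (see :func:`msamd.structio.residue_range`
    for converting the 1-based inclusive intervals used in reports).
    """
    return _pair_rmsd(a, b, ("CA",), region)


def backbone_rmsd(a: "Structure", b: "Structure", region: Optional[Sequence[int]] = None) -> float:
    """Backbone (N, CA, C, O) RMSD after optimal superposition."""
    return _pair_rmsd(a, b, BACKBONE_ATOMS, region)


def heavy_atom_rmsd(a: "Structure", b: "Structure", region: Optional[Sequence[int]] = None) -> float:
    """All-heavy-atom RMSD; requires both structures to carry full atom records.

    Only structures read from an all-atom PDB have these; simulator output is
    backbone-level and raises ``ValueError("atoms unavailable ...")``.
    """
    if a.heavy_atoms is None or b.heavy_atoms is None:
        raise ValueError("atoms unavailable: heavy-atom records absent (backbone-only structure)")
    if len(a.sequence) != len(b.sequence):
        raise ValueError("structures differ in length")
    idx = set(_region_indices(len(a.sequence), region).tolist())
    ka = [(r, n) for r, n in zip(a.heavy_atoms["res_index"], a.heavy_atoms["name"]) if r in idx]
    kb = [(r, n) for r, n in zip(b.heavy_atoms["res_index"], b.heavy_atoms["name"]) if r in idx]
    if ka != kb:
        raise ValueError("heavy-atom records do not match between structures")
    mask_a = [r in idx for r in a.heavy_atoms["res_index"]]
    mask_b = [r in idx for r in b.heavy_atoms["res_index"]]
    pa = a.heavy_atoms["coords"][mask_a]
    pb = b.heavy_atoms["coords"][mask_b]
    return kabsch_superpose(pa, pb).rmsd


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle (degrees, IUPAC convention) of four points."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise ValueError("degenerate geometry: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate geometry: collinear points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def rmsd_series_std(series: Sequence[float]) -> float:
    """Sample (n-1) standard deviation of a windowed RMSD series.

    This is the fluctuation statistic of the trajectory-convergence
    criterion: a window whose RMSD-vs-initial values have a standard
    deviation below the threshold terminates the production run.
    """
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    return float(np.std(arr, ddof=1))
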