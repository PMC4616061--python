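"""Backbone construction from internal coordinates (NeRF chain extension).

Builds peptide backbones (N, CA, C, O, amide H) from per-residue torsions
(phi, psi, omega) with ideal bond lengths and angles.  This is how the
simulator obtains its fully extended start (phi = psi = 180°) and the ideal
alpha-helix reference (phi, psi = -57°, -47°), and how tests construct
geometries with known torsions to measure them back.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np

from .structio import Structure, VALID_RESIDUES

__all__ = [
    "place_atom",
    "build_from_torsions",
    "build_extended",
    "build_ideal_helix",
    "reconstruct_amide_hydrogens",
    "IDEAL_BONDS",
    "IDEAL_ANGLES",
]

# Engh-Huber style ideal backbone geometry (Å, degrees).
IDEAL_BONDS = {
    ("N", "CA"): 1.458,
    ("CA", "C"): 1.525,
    ("C", "N"): 1.329,   # peptide bond to the next residue
    ("C", "O"): 1.231,
    ("N", "H"): 1.010,
}
IDEAL_ANGLES = {
    ("N", "CA", "C"): 111.2,
    ("CA", "C", "N"): 116.2,
    ("C", "N", "CA"): 121.7,
    ("CA", "C", "O"): 120.8,
}


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D bonded to C given the reference frame A-B-C.

    ``bond`` = |C-D|, ``angle_deg`` = angle B-C-D, ``torsion_deg`` =
    dihedral A-B-C-D (IUPAC sign).  Standard natural-extension (NeRF)
    placement.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        -bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _as_per_residue(value, L: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(L, float(arr))
    if arr.shape != (L,):
        raise ValueError(f"{name} must be a scalar or length-{L} array")
    return arr


def build_from_torsions(
    sequence: str,
    phi: Union[float, Sequence[float]],
    psi: Union[float, Sequence[float]],
    omega: Union[float, Sequence[float]] = 180.0,
    label: str = "",
    with_hydrogens: bool = True,
) -> Structure:
    """Backbone from per-residue (phi, psi, omega) with ideal geometry.

    phi[0] and psi[-1] are not geometrically defined by the chain; psi[-1]
    still orients the terminal carbonyl O.  omega[i] is the torsion of the
    peptide bond *preceding* residue i (omega[0] unused).
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L < 2:
        raise ValueError(f"sequence too short to build: {L} residue(s)")
    bad = [r for r in sequence if r not in VALID_RESIDUES]
    if bad:
        raise ValueError(f"invalid residue code(s): {sorted(set(bad))}")
    phi = _as_per_residue(phi, L, "phi")
    psi = _as_per_residue(psi, L, "psi")
    omega = _as_per_residue(omega, L, "omega")

    N = np.zeros((L, 3))
    CA = np.zeros((L, 3))
    C = np.zeros((L, 3))
    O = np.zeros((L, 3))

    # First residue in a canonical frame.
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (IDEAL_BONDS[("N", "CA")], 0.0, 0.0)
    ang = np.radians(IDEAL_ANGLES[("N", "CA", "C")])
    b = IDEAL_BONDS[("CA", "C")]
    C[0] = CA[0] + (-b * np.cos(ang), b * np.sin(ang), 0.0)

    for i in range(1, L):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          IDEAL_BONDS[("C", "N")], IDEAL_ANGLES[("CA", "C", "N")], psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           IDEAL_BONDS[("N", "CA")], IDEAL_ANGLES[("C", "N", "CA")], omega[i])
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          IDEAL_BONDS[("CA", "C")], IDEAL_ANGLES[("N", "CA", "C")], phi[i])
        # carbonyl O of residue i-1, trans to the new N across CA-C
        O[i - 1] = place_atom(N[i], CA[i - 1], C[i - 1],
                              IDEAL_BONDS[("C", "O")], IDEAL_ANGLES[("CA", "C", "O")], 180.0)
    # terminal carbonyl from psi[-1]
    O[L - 1] = place_atom(N[L - 1], CA[L - 1], C[L - 1],
                          IDEAL_BONDS[("C", "O")], IDEAL_ANGLES[("CA", "C", "O")],
                          psi[L - 1] - 180.0)

    coords = {"N": N, "CA": CA, "C": C, "O": O}
    struct = Structure(sequence=sequence, coords=coords, label=label)
    if with_hydrogens:
        reconstruct_amide_hydrogens(struct)
    return struct


def build_extended(sequence: str, label: str = "extended") -> Structure:
    """Fully extended conformation: phi = psi = omega = 180°."""
    return build_from_torsions(sequence, phi=180.0, psi=180.0, omega=180.0, label=label)


def build_ideal_helix(sequence: str, label: str = "ideal_helix") -> Structure:
    """Ideal alpha helix: (phi, psi) = (-57°, -47°) everywhere, omega trans."""
    return build_from_torsions(sequence, phi=-57.0, psi=-47.0, omega=180.0, label=label)


def reconstruct_amide_hydrogens(struct: Structure, force: bool = False) -> Structure:
    """Place amide H on each N (residues 2..L, except proline).

    H sits in the peptide plane on the bisector opposite the C(i-1)-N-CA
    angle at 1.01 Å — the standard geometric reconstruction for structures
    lacking protons.  Existing H coordinates are kept unless ``force``.
    """
    L = struct.n_residues
    if "H" not in struct.coords:
        struct.coords["H"] = np.full((L, 3), np.nan)
    H = struct.coords["H"]
    N = struct.coords["N"]
    CA = struct.coords["CA"]
    C = struct.coords["C"]
    for i in range(1, L):
        if struct.sequence[i] == "P":
            continue
        if not force and not np.isnan(H[i]).any():
            continue
        u = N[i] - C[i - 1]
        v = N[i] - CA[i]
        u /= np.linalg.norm(u)
        v /= np.linalg.norm(v)
        w = u + v
        nw = np.linalg.norm(w)
        if nw < 1e-8:  # pathological straight angle; fall back to normal
            w = np.cross(u, np.array([1.0, 0.0, 0.0]))
            nw = np.linalg.norm(w)
        H[i] = N[i] + IDEAL_BONDS[("N", "H")] * w / nw
    return struct
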