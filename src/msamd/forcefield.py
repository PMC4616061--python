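"""Coarse-grained backbone potential for the annealing simulator.

This is a declared stand-in for an all-atom force field: its job is to give
the annealing/production machinery a realistic-feeling energy landscape —
sequence-dependent helix/extended preferences, backbone hydrogen bonding,
excluded volume, stiff ideal bonded geometry and a trans-peptide (omega)
restraint that plays the role of the backbone chirality restraint — not to
reproduce any particular all-atom energetics.

Energy terms (kcal/mol, distances in Å, angles internal in radians):

* bonds:      k (r - r0)^2 over N-CA, CA-C, C-N(+1), C=O, N-H
* angles:     k (theta - theta0)^2 over the backbone and carbonyl/amide angles
* omega:      k (1 + cos omega) about every peptide bond (minimum at trans)
* impropers:  same periodic form keeping carbonyl O and amide H planar
* torsion map: per residue, a sum of two Gaussian wells on the (phi, psi)
  torus — one at the alpha-helical basin (-57, -47), one at the extended/
  beta basin (-140, 150) — whose depths come from a per-residue-type bias
  table (helix formers A/E/L/K... deep helix well; G nearly flat; P gets a
  harmonic phi restraint near -65 instead of a free phi)
* H-bond:     Gaussian well on the O(i)···H(i+3 / i+4) distance
* repulsion:  soft-core quartic between heavy atoms >= 2 residues apart,
  finite at full overlap

All gradients are analytic; a finite-difference check is part of the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .builder import IDEAL_ANGLES, IDEAL_BONDS
from .structio import Structure

__all__ = ["ToyForceField", "Topology", "structure_to_coords", "coords_to_structure"]

# per-residue (helix well depth, extended well depth) in kcal/mol
DEFAULT_BIAS: Dict[str, Tuple[float, float]] = {
    # strong helix formers
    "A": (3.0, 0.8), "E": (3.0, 0.8), "L": (3.0, 0.8), "K": (3.0, 0.8),
    "M": (2.6, 1.0), "Q": (2.6, 1.0), "R": (2.6, 1.0), "H": (2.2, 1.2),
    # intermediate
    "I": (1.8, 1.6), "W": (1.8, 1.4), "F": (1.8, 1.4), "Y": (1.6, 1.6),
    "D": (1.6, 1.4), "N": (1.4, 1.4), "S": (1.4, 1.4), "C": (1.4, 1.6),
    "T": (1.2, 1.8), "V": (1.2, 2.0),
    # breakers
    "G": (0.4, 0.4), "P": (0.5, 0.5),
    # unknown residue: alanine-like
    "X": (3.0, 0.8),
}

HELIX_WELL = (-57.0, -47.0)
EXTENDED_WELL = (-140.0, 150.0)

MASSES = {"N": 14.007, "CA": 12.011, "C": 12.011, "O": 15.999, "H": 1.008}


@dataclass
class ToyForceField:
    """Parameter set of the coarse-grained backbone potential."""

    bond_k: float = 300.0          # kcal/mol/Å^2
    bond_k_h: float = 100.0
    angle_k: float = 80.0          # kcal/mol/rad^2
    angle_k_h: float = 30.0
    omega_k: float = 20.0          # kcal/mol, k(1+cos w) trans restraint
    improper_k: float = 15.0
    well_sigma_deg: float = 32.0   # width of the (phi, psi) Gaussian wells
    hbond_epsilon: float = 1.5     # kcal/mol well depth
    hbond_r0: float = 2.0          # Å, O···H optimum
    hbond_sigma: float = 0.35      # Å
    repulsion_epsilon: float = 50.0  # kcal/mol at full overlap
    repulsion_cutoff: float = 2.7    # Å
    pro_phi0_deg: float = -65.0
    pro_phi_k: float = 5.0         # kcal/mol/rad^2
    bias: Dict[str, Tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BIAS))


# ---------------------------------------------------------------------------
# topology: flat atom arrays + per-term index lists
# ---------------------------------------------------------------------------

def _atom_layout(sequence: str):
    """Atom names per residue: N, CA, C, O, and amide H except residue 1 / Pro."""
    layout = []
    for i, res in enumerate(sequence):
        names = ["N", "CA", "C", "O"]
        if i > 0 and res != "P":
            names.append("H")
        layout.append(names)
    return layout


class Topology:
    """Precomputed index arrays for every energy term of one sequence."""

    def __init__(self, sequence: str, ff: Optional[ToyForceField] = None):
        self.sequence = sequence.upper()
        self.ff = ff or ToyForceField()
        L = len(self.sequence)
        layout = _atom_layout(self.sequence)
        self.layout = layout
        index: Dict[Tuple[int, str], int] = {}
        names = []
        k = 0
        for i, res_names in enumerate(layout):
            for nm in res_names:
                index[(i, nm)] = k
                names.append(nm)
                k += 1
        self.index = index
        self.n_atoms = k
        self.atom_names = names
        self.masses = np.array([MASSES[nm] for nm in names])
        ff_ = self.ff

        bonds = []   # (i, j, r0, k)
        angles = []  # (i, j, k, theta0_rad, k)
        diheds = []  # (i, j, k, l, k) periodic k(1+cos)
        deg = np.radians

        def a(i, nm):
            return index[(i, nm)]

        for i in range(L):
            bonds.append((a(i, "N"), a(i, "CA"), IDEAL_BONDS[("N", "CA")], ff_.bond_k))
            bonds.append((a(i, "CA"), a(i, "C"), IDEAL_BONDS[("CA", "C")], ff_.bond_k))
            bonds.append((a(i, "C"), a(i, "O"), IDEAL_BONDS[("C", "O")], ff_.bond_k))
            angles.append((a(i, "N"), a(i, "CA"), a(i, "C"),
                           deg(IDEAL_ANGLES[("N", "CA", "C")]), ff_.angle_k))
            angles.append((a(i, "CA"), a(i, "C"), a(i, "O"),
                           deg(IDEAL_ANGLES[("CA", "C", "O")]), ff_.angle_k))
            if (i, "H") in index:
                bonds.append((a(i, "N"), a(i, "H"), IDEAL_BONDS[("N", "H")], ff_.bond_k_h))
                angles.append((a(i, "H"), a(i, "N"), a(i, "CA"),
                               deg(119.15), ff_.angle_k_h))
            if i + 1 < L:
                bonds.append((a(i, "C"), a(i + 1, "N"), IDEAL_BONDS[("C", "N")], ff_.bond_k))
                angles.append((a(i, "CA"), a(i, "C"), a(i + 1, "N"),
                               deg(IDEAL_ANGLES[("CA", "C", "N")]), ff_.angle_k))
                angles.append((a(i, "O"), a(i, "C"), a(i + 1, "N"),
                               deg(123.0), ff_.angle_k))
                angles.append((a(i, "C"), a(i + 1, "N"), a(i + 1, "CA"),
                               deg(IDEAL_ANGLES[("C", "N", "CA")]), ff_.angle_k))
                if (i + 1, "H") in index:
                    angles.append((a(i, "C"), a(i + 1, "N"), a(i + 1, "H"),
                                   deg(119.15), ff_.angle_k_h))
                # omega: CA(i)-C(i)-N(i+1)-CA(i+1), trans restraint
                diheds.append((a(i, "CA"), a(i, "C"), a(i + 1, "N"), a(i + 1, "CA"),
                               ff_.omega_k))
                # carbonyl O planarity: N(i+1)-CA(i)-C(i)-O(i) at 180
                diheds.append((a(i + 1, "N"), a(i, "CA"), a(i, "C"), a(i, "O"),
                               ff_.improper_k))
                # amide H planarity: CA(i+1)-C(i)-N(i+1)-H(i+1) at 180
                if (i + 1, "H") in index:
                    diheds.append((a(i + 1, "CA"), a(i, "C"), a(i + 1, "N"), a(i + 1, "H"),
                                   ff_.improper_k))

        self.bond_idx = np.array([(b[0], b[1]) for b in bonds], dtype=int)
        self.bond_r0 = np.array([b[2] for b in bonds])
        self.bond_k = np.array([b[3] for b in bonds])
        self.angle_idx = np.array([(t[0], t[1], t[2]) for t in angles], dtype=int)
        self.angle_t0 = np.array([t[3] for t in angles])
        self.angle_k = np.array([t[4] for t in angles])
        self.dihed_idx = np.array([(d[0], d[1], d[2], d[3]) for d in diheds], dtype=int)
        self.dihed_k = np.array([d[4] for d in diheds])

        # (phi, psi) torsion map for interior residues
        rama = []   # (phi quad, psi quad, A_helix, A_ext)
        pro_phi = []  # (phi quad, phi0_rad, k) for prolines
        for i in range(1, L - 1):
            phi_q = (a(i - 1, "C"), a(i, "N"), a(i, "CA"), a(i, "C"))
            psi_q = (a(i, "N"), a(i, "CA"), a(i, "C"), a(i + 1, "N"))
            res = self.sequence[i]
            ah, ae = ff_.bias.get(res, ff_.bias["X"])
            if res == "P":
                pro_phi.append((phi_q, np.radians(ff_.pro_phi0_deg), ff_.pro_phi_k))
            rama.append((phi_q, psi_q, ah, ae))
        self.rama_phi_idx = np.array([r[0] for r in rama], dtype=int).reshape(-1, 4)
        self.rama_psi_idx = np.array([r[1] for r in rama], dtype=int).reshape(-1, 4)
        self.rama_ah = np.array([r[2] for r in rama])
        self.rama_ae = np.array([r[3] for r in rama])
        self.pro_phi_idx = np.array([p[0] for p in pro_phi], dtype=int).reshape(-1, 4)
        self.pro_phi0 = np.array([p[1] for p in pro_phi])
        self.pro_phi_k = np.array([p[2] for p in pro_phi])

        # H-bond pairs: O(i) ··· H(i+3), H(i+4)
        hb = []
        for i in range(L):
            for dj in (3, 4):
                j = i + dj
                if j < L and (j, "H") in index:
                    hb.append((a(i, "O"), a(j, "H")))
        self.hbond_idx = np.array(hb, dtype=int).reshape(-1, 2)

        # soft repulsion between heavy atoms >= 2 residues apart
        heavy = [(i, nm) for i in range(L) for nm in layout[i] if nm != "H"]
        rep = []
        for p in range(len(heavy)):
            ri, _ = heavy[p]
            for q in range(p + 1, len(heavy)):
                rj, _ = heavy[q]
                if abs(ri - rj) >= 2:
                    rep.append((index[heavy[p]], index[heavy[q]]))
        self.rep_idx = np.array(rep, dtype=int).reshape(-1, 2)

        # masks for the two-stage minimization (backbone = N, CA, C, O)
        self.backbone_mask = np.array([nm in ("N", "CA", "C", "O") for nm in names])


# ---------------------------------------------------------------------------
# structure <-> flat coordinates
# ---------------------------------------------------------------------------

def structure_to_coords(struct: Structure, top: Topology) -> np.ndarray:
    if struct.sequence != top.sequence:
        raise ValueError("structure sequence does not match topology")
    x = np.empty((top.n_atoms, 3))
    for (ri, nm), k in top.index.items():
        arr = struct.coords.get(nm)
        if arr is None or np.isnan(arr[ri]).any():
            raise ValueError(f"structure missing {nm} of residue {ri + 1}")
        x[k] = arr[ri]
    return x


def coords_to_structure(x: np.ndarray, top: Topology, label: str = "",
                        potential_energy: Optional[float] = None) -> Structure:
    L = len(top.sequence)
    coords = {nm: np.full((L, 3), np.nan) for nm in ("N", "CA", "C", "O", "H")}
    for (ri, nm), k in top.index.items():
        coords[nm][ri] = x[k]
    return Structure(sequence=top.sequence, coords=coords, label=label,
                     potential_energy=potential_energy)


# ---------------------------------------------------------------------------
# vectorised term helpers
# ---------------------------------------------------------------------------

def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product without np.cross's axis-juggling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _dihedral_and_grad(x: np.ndarray, quads: np.ndarray):
    """Angles (rad, in (-pi, pi]) and gradients (m, 4, 3) for m quadruples."""
    p = x[quads]                       # (m, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = np.sqrt(np.einsum("ij,ij->i", b2, b2))
    m1 = _cross(n1, b2 / b2n[:, None])
    xx = np.einsum("ij,ij->i", n1, n2)
    yy = np.einsum("ij,ij->i", m1, n2)
    theta = np.arctan2(yy, xx)

    n1sq = np.einsum("ij,ij->i", n1, n1)
    n2sq = np.einsum("ij,ij->i", n2, n2)
    # guard collinear degeneracies (never reached for bonded geometry)
    n1sq = np.maximum(n1sq, 1e-12)
    n2sq = np.maximum(n2sq, 1e-12)
    f = (b2n / n1sq)[:, None] * n1             # d theta / d p1
    h = -(b2n / n2sq)[:, None] * n2            # d theta / d p4
    c = (np.einsum("ij,ij->i", b1, b2) / b2n**2)[:, None]
    d = (np.einsum("ij,ij->i", b3, b2) / b2n**2)[:, None]
    g = np.empty_like(p)
    g[:, 0] = f
    g[:, 1] = -(1.0 + c) * f + d * h
    g[:, 2] = c * f - (1.0 + d) * h
    g[:, 3] = h
    return theta, g


def _wrap_rad(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# compiled kernel (numba): same maths as the numpy path, loop-structured
# ---------------------------------------------------------------------------

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard part of the stack
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco


@_njit(cache=True, fastmath=False)
def _dihedral_term(x, i, j, k, l, g, coef, need_grad):
    """Dihedral angle of atoms i-j-k-l; adds coef * dtheta/dp into g."""
    b1x = x[j, 0] - x[i, 0]; b1y = x[j, 1] - x[i, 1]; b1z = x[j, 2] - x[i, 2]
    b2x = x[k, 0] - x[j, 0]; b2y = x[k, 1] - x[j, 1]; b2z = x[k, 2] - x[j, 2]
    b3x = x[l, 0] - x[k, 0]; b3y = x[l, 1] - x[k, 1]; b3z = x[l, 2] - x[k, 2]
    n1x = b1y * b2z - b1z * b2y
    n1y = b1z * b2x - b1x * b2z
    n1z = b1x * b2y - b1y * b2x
    n2x = b2y * b3z - b2z * b3y
    n2y = b2z * b3x - b2x * b3z
    n2z = b2x * b3y - b2y * b3x
    b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
    m1x = (n1y * b2z - n1z * b2y) / b2n
    m1y = (n1z * b2x - n1x * b2z) / b2n
    m1z = (n1x * b2y - n1y * b2x) / b2n
    xx = n1x * n2x + n1y * n2y + n1z * n2z
    yy = m1x * n2x + m1y * n2y + m1z * n2z
    theta = np.arctan2(yy, xx)
    if need_grad:
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12:
            n1sq = 1e-12
        if n2sq < 1e-12:
            n2sq = 1e-12
        fx = b2n * n1x / n1sq; fy = b2n * n1y / n1sq; fz = b2n * n1z / n1sq
        hx = -b2n * n2x / n2sq; hy = -b2n * n2y / n2sq; hz = -b2n * n2z / n2sq
        c = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        d = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        g[i, 0] += coef * fx; g[i, 1] += coef * fy; g[i, 2] += coef * fz
        g[j, 0] += coef * (-(1.0 + c) * fx + d * hx)
        g[j, 1] += coef * (-(1.0 + c) * fy + d * hy)
        g[j, 2] += coef * (-(1.0 + c) * fz + d * hz)
        g[k, 0] += coef * (c * fx - (1.0 + d) * hx)
        g[k, 1] += coef * (c * fy - (1.0 + d) * hy)
        g[k, 2] += coef * (c * fz - (1.0 + d) * hz)
        g[l, 0] += coef * hx; g[l, 1] += coef * hy; g[l, 2] += coef * hz
    return theta


@_njit(cache=True, fastmath=False)
def _dihedral_value(x, i, j, k, l):
    g = np.zeros((1, 3))
    return _dihedral_term(x, i, j, k, l, g, 0.0, False)


@_njit(cache=True, fastmath=False)
def _eval_kernel(x, need_grad,
                 bond_idx, bond_r0, bond_k,
                 angle_idx, angle_t0, angle_k,
                 dihed_idx, dihed_k,
                 rama_phi_idx, rama_psi_idx, rama_ah, rama_ae, sigma,
                 phi0_h, psi0_h, phi0_e, psi0_e,
                 pro_phi_idx, pro_phi0, pro_phi_k,
                 hbond_idx, hb_eps, hb_r0, hb_sigma,
                 rep_idx, rep_eps, rep_cut):
    n = x.shape[0]
    g = np.zeros((n, 3))
    terms = np.zeros(7)   # bond, angle, omega, torsion_map, pro_phi, hbond, repulsion

    for b in range(bond_idx.shape[0]):
        i = bond_idx[b, 0]; j = bond_idx[b, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[b]
        terms[0] += bond_k[b] * dr * dr
        if need_grad:
            cc = 2.0 * bond_k[b] * dr / r
            g[i, 0] += cc * dx; g[i, 1] += cc * dy; g[i, 2] += cc * dz
            g[j, 0] -= cc * dx; g[j, 1] -= cc * dy; g[j, 2] -= cc * dz

    for t in range(angle_idx.shape[0]):
        ia = angle_idx[t, 0]; ja = angle_idx[t, 1]; ka = angle_idx[t, 2]
        ux = x[ia, 0] - x[ja, 0]; uy = x[ia, 1] - x[ja, 1]; uz = x[ia, 2] - x[ja, 2]
        vx = x[ka, 0] - x[ja, 0]; vy = x[ka, 1] - x[ja, 1]; vz = x[ka, 2] - x[ja, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dt = theta - angle_t0[t]
        terms[1] += angle_k[t] * dt * dt
        if need_grad:
            st = np.sqrt(max(1.0 - ct * ct, 1e-12))
            cu = 1.0 / (nu * st); cv = 1.0 / (nv * st)
            dux = (ct * ux / nu - vx / nv) * cu
            duy = (ct * uy / nu - vy / nv) * cu
            duz = (ct * uz / nu - vz / nv) * cu
            dvx = (ct * vx / nv - ux / nu) * cv
            dvy = (ct * vy / nv - uy / nu) * cv
            dvz = (ct * vz / nv - uz / nu) * cv
            co = 2.0 * angle_k[t] * dt
            g[ia, 0] += co * dux; g[ia, 1] += co * duy; g[ia, 2] += co * duz
            g[ka, 0] += co * dvx; g[ka, 1] += co * dvy; g[ka, 2] += co * dvz
            g[ja, 0] -= co * (dux + dvx); g[ja, 1] -= co * (duy + dvy); g[ja, 2] -= co * (duz + dvz)

    for t in range(dihed_idx.shape[0]):
        # E = k (1 + cos theta); dE/dtheta = -k sin theta; two-pass: value then grad
        th = _dihedral_value(x, dihed_idx[t, 0], dihed_idx[t, 1], dihed_idx[t, 2], dihed_idx[t, 3])
        terms[2] += dihed_k[t] * (1.0 + np.cos(th))
        if need_grad:
            _dihedral_term(x, dihed_idx[t, 0], dihed_idx[t, 1], dihed_idx[t, 2], dihed_idx[t, 3],
                           g, -dihed_k[t] * np.sin(th), True)

    twopi = 2.0 * np.pi
    for t in range(rama_phi_idx.shape[0]):
        phi = _dihedral_value(x, rama_phi_idx[t, 0], rama_phi_idx[t, 1],
                              rama_phi_idx[t, 2], rama_phi_idx[t, 3])
        psi = _dihedral_value(x, rama_psi_idx[t, 0], rama_psi_idx[t, 1],
                              rama_psi_idx[t, 2], rama_psi_idx[t, 3])
        dE_dphi = 0.0
        dE_dpsi = 0.0
        for w in range(2):
            if w == 0:
                dphi = phi - phi0_h; dpsi = psi - psi0_h; amp = rama_ah[t]
            else:
                dphi = phi - phi0_e; dpsi = psi - psi0_e; amp = rama_ae[t]
            dphi = (dphi + np.pi) % twopi - np.pi
            dpsi = (dpsi + np.pi) % twopi - np.pi
            wgt = np.exp(-(dphi * dphi + dpsi * dpsi) / (2.0 * sigma * sigma))
            terms[3] -= amp * wgt
            dE_dphi += amp * wgt * dphi / (sigma * sigma)
            dE_dpsi += amp * wgt * dpsi / (sigma * sigma)
        if need_grad:
            _dihedral_term(x, rama_phi_idx[t, 0], rama_phi_idx[t, 1],
                           rama_phi_idx[t, 2], rama_phi_idx[t, 3], g, dE_dphi, True)
            _dihedral_term(x, rama_psi_idx[t, 0], rama_psi_idx[t, 1],
                           rama_psi_idx[t, 2], rama_psi_idx[t, 3], g, dE_dpsi, True)

    for t in range(pro_phi_idx.shape[0]):
        phi = _dihedral_value(x, pro_phi_idx[t, 0], pro_phi_idx[t, 1],
                              pro_phi_idx[t, 2], pro_phi_idx[t, 3])
        dphi = (phi - pro_phi0[t] + np.pi) % twopi - np.pi
        terms[4] += pro_phi_k[t] * dphi * dphi
        if need_grad:
            _dihedral_term(x, pro_phi_idx[t, 0], pro_phi_idx[t, 1],
                           pro_phi_idx[t, 2], pro_phi_idx[t, 3],
                           g, 2.0 * pro_phi_k[t] * dphi, True)

    for t in range(hbond_idx.shape[0]):
        i = hbond_idx[t, 0]; j = hbond_idx[t, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        wgt = np.exp(-((r - hb_r0) ** 2) / (2.0 * hb_sigma * hb_sigma))
        terms[5] -= hb_eps * wgt
        if need_grad:
            dE_dr = hb_eps * wgt * (r - hb_r0) / (hb_sigma * hb_sigma)
            cc = dE_dr / r
            g[i, 0] += cc * dx; g[i, 1] += cc * dy; g[i, 2] += cc * dz
            g[j, 0] -= cc * dx; g[j, 1] -= cc * dy; g[j, 2] -= cc * dz

    rc2 = rep_cut * rep_cut
    for t in range(rep_idx.shape[0]):
        i = rep_idx[t, 0]; j = rep_idx[t, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2:
            s = 1.0 - r2 / rc2
            terms[6] += rep_eps * s * s
            if need_grad:
                cc = -4.0 * rep_eps * s / rc2
                g[i, 0] += cc * dx; g[i, 1] += cc * dy; g[i, 2] += cc * dz
                g[j, 0] -= cc * dx; g[j, 1] -= cc * dy; g[j, 2] -= cc * dz

    return terms, g


_TERM_NAMES = ("bond", "angle", "omega", "torsion_map", "pro_phi", "hbond", "repulsion")


class EnergyModel:
    """Callable energy/gradient of one (sequence, force field) pair.

    ``backend="numba"`` (the default when numba imports) runs the compiled
    loop kernel; ``backend="numpy"`` runs the vectorised reference path.
    Both compute the same terms — their agreement is a test invariant.
    """

    def __init__(self, top: Topology, backend: str = "auto"):
        self.top = top
        self.ff = top.ff
        if backend == "auto":
            backend = "numba" if _HAVE_NUMBA else "numpy"
        if backend not in ("numba", "numpy"):
            raise ValueError("backend must be 'auto', 'numba' or 'numpy'")
        if backend == "numba" and not _HAVE_NUMBA:
            raise ValueError("numba backend requested but numba is not importable")
        self.backend = backend

    def energy_breakdown(self, x: np.ndarray):
        e, _, breakdown = self._eval(x, need_grad=False)
        return e, breakdown

    def energy(self, x: np.ndarray) -> float:
        return self._eval(x, need_grad=False)[0]

    def energy_and_grad(self, x: np.ndarray):
        e, g, _ = self._eval(x, need_grad=True)
        return e, g

    def _eval(self, x: np.ndarray, need_grad: bool = True):
        if self.backend == "numba":
            return self._eval_numba(x, need_grad)
        return self._eval_numpy(x, need_grad)

    def _eval_numba(self, x: np.ndarray, need_grad: bool):
        top, ff = self.top, self.ff
        terms, g = _eval_kernel(
            np.ascontiguousarray(x, dtype=np.float64), need_grad,
            top.bond_idx, top.bond_r0, top.bond_k,
            top.angle_idx, top.angle_t0, top.angle_k,
            top.dihed_idx, top.dihed_k,
            top.rama_phi_idx, top.rama_psi_idx, top.rama_ah, top.rama_ae,
            np.radians(ff.well_sigma_deg),
            np.radians(HELIX_WELL[0]), np.radians(HELIX_WELL[1]),
            np.radians(EXTENDED_WELL[0]), np.radians(EXTENDED_WELL[1]),
            top.pro_phi_idx, top.pro_phi0, top.pro_phi_k,
            top.hbond_idx, ff.hbond_epsilon, ff.hbond_r0, ff.hbond_sigma,
            top.rep_idx, ff.repulsion_epsilon, ff.repulsion_cutoff,
        )
        breakdown = dict(zip(_TERM_NAMES, (float(t) for t in terms)))
        return float(terms.sum()), (g if need_grad else None), breakdown

    def _eval_numpy(self, x: np.ndarray, need_grad: bool = True):
        top, ff = self.top, self.ff
        g = np.zeros_like(x) if need_grad else None
        breakdown = {}

        # bonds
        i, j = top.bond_idx[:, 0], top.bond_idx[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        dr = r - top.bond_r0
        breakdown["bond"] = float(np.sum(top.bond_k * dr**2))
        if need_grad:
            f = (2.0 * top.bond_k * dr / r)[:, None] * d
            np.add.at(g, i, f)
            np.add.at(g, j, -f)

        # angles
        ai, aj, ak = top.angle_idx[:, 0], top.angle_idx[:, 1], top.angle_idx[:, 2]
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dt = theta - top.angle_t0
        breakdown["angle"] = float(np.sum(top.angle_k * dt**2))
        if need_grad:
            sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 1e-12))
            uhat = u / nu[:, None]
            vhat = v / nv[:, None]
            dthe_du = (cos_t[:, None] * uhat - vhat) / (nu * sin_t)[:, None]
            dthe_dv = (cos_t[:, None] * vhat - uhat) / (nv * sin_t)[:, None]
            coef = (2.0 * top.angle_k * dt)[:, None]
            np.add.at(g, ai, coef * dthe_du)
            np.add.at(g, ak, coef * dthe_dv)
            np.add.at(g, aj, -coef * (dthe_du + dthe_dv))

        # periodic dihedrals (omega + impropers): k (1 + cos theta)
        if len(top.dihed_idx):
            theta_d, grad_d = _dihedral_and_grad(x, top.dihed_idx)
            breakdown["omega"] = float(np.sum(top.dihed_k * (1.0 + np.cos(theta_d))))
            if need_grad:
                coef = (-top.dihed_k * np.sin(theta_d))[:, None, None]
                np.add.at(g, top.dihed_idx.ravel(), (coef * grad_d).reshape(-1, 3))
        else:
            breakdown["omega"] = 0.0

        # (phi, psi) torsion map
        if len(top.rama_phi_idx):
            sig = np.radians(ff.well_sigma_deg)
            phi, gphi = _dihedral_and_grad(x, top.rama_phi_idx)
            psi, gpsi = _dihedral_and_grad(x, top.rama_psi_idx)
            e_rama = 0.0
            dE_dphi = np.zeros_like(phi)
            dE_dpsi = np.zeros_like(psi)
            for (phi0, psi0), amp in (
                (HELIX_WELL, top.rama_ah),
                (EXTENDED_WELL, top.rama_ae),
            ):
                dphi = _wrap_rad(phi - np.radians(phi0))
                dpsi = _wrap_rad(psi - np.radians(psi0))
                w = np.exp(-(dphi**2 + dpsi**2) / (2.0 * sig**2))
                e_rama -= float(np.sum(amp * w))
                dE_dphi += amp * w * dphi / sig**2
                dE_dpsi += amp * w * dpsi / sig**2
            breakdown["torsion_map"] = e_rama
            if need_grad:
                np.add.at(g, top.rama_phi_idx.ravel(),
                          (dE_dphi[:, None, None] * gphi).reshape(-1, 3))
                np.add.at(g, top.rama_psi_idx.ravel(),
                          (dE_dpsi[:, None, None] * gpsi).reshape(-1, 3))
        else:
            breakdown["torsion_map"] = 0.0

        # proline phi restraint
        if len(top.pro_phi_idx):
            phi, gphi = _dihedral_and_grad(x, top.pro_phi_idx)
            dphi = _wrap_rad(phi - top.pro_phi0)
            breakdown["pro_phi"] = float(np.sum(top.pro_phi_k * dphi**2))
            if need_grad:
                coef = (2.0 * top.pro_phi_k * dphi)[:, None, None]
                np.add.at(g, top.pro_phi_idx.ravel(), (coef * gphi).reshape(-1, 3))
        else:
            breakdown["pro_phi"] = 0.0

        # hydrogen-bond wells
        if len(top.hbond_idx):
            i, j = top.hbond_idx[:, 0], top.hbond_idx[:, 1]
            d = x[i] - x[j]
            r = np.linalg.norm(d, axis=1)
            w = np.exp(-((r - ff.hbond_r0) ** 2) / (2.0 * ff.hbond_sigma**2))
            breakdown["hbond"] = float(-ff.hbond_epsilon * np.sum(w))
            if need_grad:
                dE_dr = ff.hbond_epsilon * w * (r - ff.hbond_r0) / ff.hbond_sigma**2
                f = (dE_dr / r)[:, None] * d
                np.add.at(g, i, f)
                np.add.at(g, j, -f)
        else:
            breakdown["hbond"] = 0.0

        # soft-core repulsion
        if len(top.rep_idx):
            i, j = top.rep_idx[:, 0], top.rep_idx[:, 1]
            d = x[i] - x[j]
            r2 = np.einsum("ij,ij->i", d, d)
            rc2 = ff.repulsion_cutoff**2
            inside = r2 < rc2
            breakdown["repulsion"] = 0.0
            if np.any(inside):
                s = 1.0 - r2[inside] / rc2
                breakdown["repulsion"] = float(ff.repulsion_epsilon * np.sum(s**2))
                if need_grad:
                    # dE/dr2 = -2 eps s / rc2 ; dr2/dx_i = 2 d
                    coef = (-4.0 * ff.repulsion_epsilon * s / rc2)[:, None]
                    f = coef * d[inside]
                    np.add.at(g, i[inside], f)
                    np.add.at(g, j[inside], -f)
        else:
            breakdown["repulsion"] = 0.0

        e = float(sum(breakdown.values()))
        return e, g, breakdown
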