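"""Secondary-structure assignment from backbone hydrogen bonds.

Implements the standard hydrogen-bond pattern algorithm (Kabsch–Sander):
an electrostatic N-H···O=C energy with the 27.888 kcal·Å/mol constant and a
-0.5 kcal/mol bond cutoff, n-turn patterns (3/4/5-turn -> G/H/I), bridge
patterns -> E, hydrogen-bonded turn -> T, and a Cα-curvature bend -> S,
with assignment priority H > E > G > I > T > S.  Ensemble-level
forming-tendency profiles report the per-residue frequency of each code.

Amide hydrogens are reconstructed geometrically when absent; proline and
the first residue are never donors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .builder import reconstruct_amide_hydrogens
from .structio import Ensemble, Structure

__all__ = [
    "SS_CODES",
    "SSAssignment",
    "TendencyProfile",
    "hbond_energy",
    "assign_ss",
    "forming_tendency",
]

SS_CODES = ("H", "G", "I", "E", "T", "S", "C")

HB_CONSTANT = 27.888       # kcal*Å/mol  (q1*q2*f)
HB_CUTOFF = -0.5           # kcal/mol: bond declared below this energy
HB_ENERGY_FLOOR = -9.9     # cap for near-contact geometries
CHAIN_BREAK_CN = 2.5       # Å: C(i)-N(i+1) beyond this splits the chain
BEND_ANGLE = 70.0          # degrees of Cα(i-2)-Cα(i)-Cα(i+2) curvature


def _donor_ok(struct: Structure, i: int) -> bool:
    if i == 0 or struct.sequence[i] == "P":
        return False
    H = struct.coords.get("H")
    return H is not None and not np.isnan(H[i]).any()


def hbond_energy(struct: Structure, donor: int, acceptor: int) -> float:
    """Electrostatic H-bond energy (kcal/mol) of N-H(donor) -> C=O(acceptor).

    E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN); a hydrogen bond is
    declared when E < -0.5 kcal/mol.  Self and adjacent pairs
    (|donor - acceptor| < 2) are excluded by rule and raise ValueError,
    as does a donor without an (actual or reconstructable) amide H.
    """
    if abs(donor - acceptor) < 2:
        raise ValueError("no H-bonds within a residue or between direct neighbours")
    if not _donor_ok(struct, donor):
        raise ValueError(f"residue {donor + 1} cannot donate (no amide H)")
    N = struct.coords["N"][donor]
    H = struct.coords["H"][donor]
    C = struct.coords["C"][acceptor]
    O = struct.coords["O"][acceptor]
    r_on = np.linalg.norm(O - N)
    r_ch = np.linalg.norm(C - H)
    r_oh = np.linalg.norm(O - H)
    r_cn = np.linalg.norm(C - N)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return HB_ENERGY_FLOOR
    e = HB_CONSTANT * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return float(max(e, HB_ENERGY_FLOOR))


@dataclass
class SSAssignment:
    """Per-residue codes plus the hydrogen-bond set they derive from."""

    codes: str
    hbonds: Dict[Tuple[int, int], float]   # (donor, acceptor) -> energy

    def __str__(self) -> str:
        return self.codes.replace("C", "-")


def _segments(struct: Structure) -> np.ndarray:
    """Segment id per residue; a C-N distance > 2.5 Å starts a new segment."""
    d = np.linalg.norm(struct.coords["N"][1:] - struct.coords["C"][:-1], axis=1)
    seg = np.zeros(struct.n_residues, dtype=int)
    seg[1:] = np.cumsum(d > CHAIN_BREAK_CN)
    return seg


def assign_ss(struct: Structure) -> SSAssignment:
    """Deterministic secondary-structure assignment of one conformation."""
    struct.validate(check_bonds=False)
    reconstruct_amide_hydrogens(struct)
    L = struct.n_residues
    seg = _segments(struct)

    hbonds: Dict[Tuple[int, int], float] = {}
    for i in range(L):           # donor
        if not _donor_ok(struct, i):
            continue
        for j in range(L):       # acceptor
            if abs(i - j) < 2:
                continue
            e = hbond_energy(struct, i, j)
            if e < HB_CUTOFF:
                hbonds[(i, j)] = e

    def bond(donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in hbonds

    # n-turns: H-bond from residue i+n back to i, within one segment
    turn = {n: np.zeros(L, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(L - n):
            if seg[i] == seg[i + n] and bond(i + n, i):
                turn[n][i] = True

    is_code = {c: np.zeros(L, dtype=bool) for c in SS_CODES}

    # helices from consecutive n-turns: 4-turn -> H, 3-turn -> G, 5-turn -> I
    for n, code in ((4, "H"), (3, "G"), (5, "I")):
        for i in range(1, L - n):
            if turn[n][i - 1] and turn[n][i]:
                is_code[code][i:i + n] = True

    # bridges -> E (standard parallel/antiparallel patterns, |i-j| >= 3)
    for i in range(1, L - 1):
        for j in range(i + 3, L - 1):
            para = (bond(i - 1, j) and bond(j, i + 1)) or (
                bond(j - 1, i) and bond(i, j + 1)
            )
            anti = (bond(i, j) and bond(j, i)) or (
                bond(i - 1, j + 1) and bond(j - 1, i + 1)
            )
            if para or anti:
                is_code["E"][i] = True
                is_code["E"][j] = True

    # hydrogen-bonded turn -> T: interior residues of any n-turn
    for n in (3, 4, 5):
        for i in range(L - n):
            if turn[n][i]:
                is_code["T"][i + 1:i + n] = True

    # bend -> S
    CA = struct.coords["CA"]
    for i in range(2, L - 2):
        u = CA[i] - CA[i - 2]
        v = CA[i + 2] - CA[i]
        cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1.0, 1.0)
        if np.degrees(np.arccos(cosang)) > BEND_ANGLE:
            is_code["S"][i] = True

    codes = []
    for i in range(L):
        assigned = "C"
        for code in ("H", "E", "G", "I", "T", "S"):      # priority order
            if is_code[code][i]:
                assigned = code
                break
        if i in (0, L - 1) and assigned in ("H", "E", "G", "I"):
            # chain termini carry only C/T/S in this pipeline's convention
            assigned = "T" if is_code["T"][i] else ("S" if is_code["S"][i] else "C")
        codes.append(assigned)
    return SSAssignment(codes="".join(codes), hbonds=hbonds)


@dataclass
class TendencyProfile:
    """Per-residue frequency of each secondary-structure code."""

    frequencies: pd.DataFrame   # index: residue number (1-based); columns: SS_CODES

    def to_csv(self, path) -> None:
        self.frequencies.to_csv(path, index_label="residue")


def forming_tendency(ens: Ensemble) -> TendencyProfile:
    """Empirical code frequencies per residue over an ensemble.

    For every residue the frequencies over the full alphabet (including C)
    sum to 1.
    """
    if len(ens) == 0:
        raise ValueError("forming_tendency needs a non-empty ensemble")
    seqs = {m.sequence for m in ens}
    if len(seqs) > 1:
        raise ValueError("mixed sequences in ensemble")
    L = ens[0].n_residues
    counts = np.zeros((L, len(SS_CODES)))
    for m in ens:
        codes = assign_ss(m).codes
        for i, c in enumerate(codes):
            counts[i, SS_CODES.index(c)] += 1
    freq = counts / len(ens)
    df = pd.DataFrame(freq, columns=list(SS_CODES), index=np.arange(1, L + 1))
    return TendencyProfile(frequencies=df)
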