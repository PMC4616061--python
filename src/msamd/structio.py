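"""Peptide conformations, ensembles and PDB/FASTA input-output.

The in-memory model is deliberately backbone-level: every analysis in the
pipeline (Cα/backbone RMSD, phi/psi stereochemistry, hydrogen-bond based
secondary structure) needs only N, CA, C, O plus the amide H, which is
reconstructed geometrically when an input file lacks protons.  Structures
read from an all-atom PDB additionally keep their full heavy-atom records so
heavy-atom RMSD stays available for such inputs.

File formats go through biotite (PDB with MODEL/ENDMDL handling, FASTA);
ensemble provenance (seeds, convergence flags, simulated time), which PDB
cannot carry, lives in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb
import biotite.sequence.io.fasta as bfasta
from biotite.sequence import ProteinSequence

__all__ = [
    "Structure",
    "MemberMeta",
    "Ensemble",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "residue_range",
]

BACKBONE = ("N", "CA", "C", "O")
OPTIONAL_ATOMS = ("H", "CB")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

VALID_RESIDUES = set(_ONE_TO_THREE)


@dataclass
class Structure:
    """One peptide conformation: sequence plus per-residue backbone coordinates.

    ``coords`` maps atom name -> (L, 3) array in Å.  N, CA, C, O are
    mandatory and finite; H and CB rows may be NaN where the atom does not
    exist (residue 1 and proline have no amide H).  ``heavy_atoms`` is an
    optional record of all heavy atoms from an input PDB, used only by
    heavy-atom RMSD.
    """

    sequence: str
    coords: dict
    label: str = ""
    potential_energy: Optional[float] = None
    heavy_atoms: Optional[dict] = None

    def __post_init__(self):
        self.sequence = str(self.sequence).upper()
        for name in BACKBONE:
            if name not in self.coords:
                raise ValueError(f"missing backbone atom coordinates: {name}")
            self.coords[name] = np.asarray(self.coords[name], dtype=float)
        for name in OPTIONAL_ATOMS:
            if name in self.coords:
                self.coords[name] = np.asarray(self.coords[name], dtype=float)

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def validate(self, check_bonds: bool = True) -> "Structure":
        """Check the structural invariants; returns self for chaining.

        Sequence length >= 3, finite mandatory coordinates of matching
        shape, and (optionally) peptide-bonded consecutive residues with
        C(i)-N(i+1) in (1.0, 2.0) Å.
        """
        L = self.n_residues
        if L < 3:
            raise ValueError(f"sequence too short for analysis: {L} residues (need >= 3)")
        bad = [r for r in self.sequence if r not in VALID_RESIDUES]
        if bad:
            raise ValueError(f"invalid residue code(s): {sorted(set(bad))}")
        for name in BACKBONE:
            arr = self.coords[name]
            if arr.shape != (L, 3):
                raise ValueError(f"{name} coordinates have shape {arr.shape}, expected ({L}, 3)")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite {name} coordinates")
        if check_bonds:
            d = np.linalg.norm(self.coords["N"][1:] - self.coords["C"][:-1], axis=1)
            if np.any((d <= 1.0) | (d >= 2.0)):
                i = int(np.argmax((d <= 1.0) | (d >= 2.0)))
                raise ValueError(
                    f"residues {i + 1}-{i + 2} are not peptide-bonded "
                    f"(C-N distance {d[i]:.3f} Å)"
                )
        return self

    def copy(self) -> "Structure":
        return Structure(
            sequence=self.sequence,
            coords={k: v.copy() for k, v in self.coords.items()},
            label=self.label,
            potential_energy=self.potential_energy,
            heavy_atoms=None if self.heavy_atoms is None else {
                "res_index": list(self.heavy_atoms["res_index"]),
                "name": list(self.heavy_atoms["name"]),
                "coords": self.heavy_atoms["coords"].copy(),
            },
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-transformed copy (used by invariance tests)."""
        out = self.copy()
        for k, v in out.coords.items():
            out.coords[k] = v @ np.asarray(rotation).T + np.asarray(translation)
        if out.heavy_atoms is not None:
            out.heavy_atoms["coords"] = (
                out.heavy_atoms["coords"] @ np.asarray(rotation).T + np.asarray(translation)
            )
        return out


@dataclass
class MemberMeta:
    """Provenance of one ensemble member."""

    seed: Optional[int] = None
    simulated_time_ps: Optional[float] = None
    converged: Optional[bool] = None
    source_stage: str = ""

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulated_time_ps": self.simulated_time_ps,
            "converged": self.converged,
            "source_stage": self.source_stage,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MemberMeta":
        return cls(
            seed=d.get("seed"),
            simulated_time_ps=d.get("simulated_time_ps"),
            converged=d.get("converged"),
            source_stage=d.get("source_stage", ""),
        )


@dataclass
class Ensemble:
    """Ordered collection of same-sequence conformations with provenance."""

    members: List[Structure]
    meta: List[MemberMeta] = field(default_factory=list)

    def __post_init__(self):
        if not self.meta:
            self.meta = [MemberMeta() for _ in self.members]
        if len(self.meta) != len(self.members):
            raise ValueError("meta must have one record per member")
        seqs = {m.sequence for m in self.members}
        if len(seqs) > 1:
            raise ValueError("ensemble members must share one sequence")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __getitem__(self, i: int) -> Structure:
        return self.members[i]

    @property
    def sequence(self) -> str:
        if not self.members:
            raise ValueError("empty ensemble has no sequence")
        return self.members[0].sequence

    def labels(self) -> List[str]:
        return [m.label for m in self.members]

    def subset(self, indices: Iterable[int]) -> "Ensemble":
        idx = list(indices)
        return Ensemble(
            members=[self.members[i] for i in idx],
            meta=[self.meta[i] for i in idx],
        )

    def write_sidecar(self, path: Union[str, Path]) -> None:
        """Write per-member provenance (seed, convergence, ...) as JSON."""
        payload = {
            "n_members": len(self),
            "labels": self.labels(),
            "meta": [m.to_dict() for m in self.meta],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def read_sidecar(self, path: Union[str, Path]) -> None:
        payload = json.loads(Path(path).read_text())
        if payload["n_members"] != len(self):
            raise ValueError("sidecar does not match ensemble size")
        self.meta = [MemberMeta.from_dict(d) for d in payload["meta"]]
        for m, lab in zip(self.members, payload["labels"]):
            m.label = lab


def residue_range(
    struct_or_length: Union[Structure, int],
    spec: Union[str, Tuple[int, int]],
) -> np.ndarray:
    """0-based index set for a 1-based inclusive residue interval.

    ``spec`` is either a "start-stop" string (the report style, e.g.
    "4-34") or a (start, stop) tuple, both 1-based inclusive.
    """
    length = struct_or_length.n_residues if isinstance(struct_or_length, Structure) else int(struct_or_length)
    if isinstance(spec, str):
        parts = spec.replace("–", "-").split("-")
        if len(parts) != 2:
            raise ValueError(f"cannot parse residue interval {spec!r}")
        start, stop = int(parts[0]), int(parts[1])
    else:
        start, stop = int(spec[0]), int(spec[1])
    if start < 1 or stop > length or start > stop:
        raise ValueError(f"interval {start}-{stop} out of range for length {length}")
    return np.arange(start - 1, stop)


# ---------------------------------------------------------------------------
# PDB / FASTA
# ---------------------------------------------------------------------------

def _structure_from_atom_array(arr: bst.AtomArray, label: str) -> Structure:
    arr = arr[bst.filter_amino_acids(arr) | (arr.res_name == "UNK")]
    if arr.array_length() == 0:
        raise ValueError("no amino-acid ATOM records found")
    # residue order = first appearance of (chain, res_id)
    keys = list(dict.fromkeys(zip(arr.chain_id, arr.res_id)))
    L = len(keys)
    seq_chars = []
    coords = {name: np.full((L, 3), np.nan) for name in BACKBONE + OPTIONAL_ATOMS}
    heavy_res, heavy_name, heavy_xyz = [], [], []
    for ridx, (ch, rid) in enumerate(keys):
        mask = (arr.chain_id == ch) & (arr.res_id == rid)
        res = arr[mask]
        res3 = res.res_name[0]
        seq_chars.append(_THREE_TO_ONE.get(res3, "X"))
        names = list(res.atom_name)
        for name in BACKBONE + OPTIONAL_ATOMS:
            want = name if name != "H" else None
            if name == "H":
                for cand in ("H", "HN", "H1"):
                    if cand in names:
                        want = cand
                        break
                if want is None:
                    continue
            if want in names:
                coords[name][ridx] = res.coord[names.index(want)]
        for j, nm in enumerate(names):
            if not nm.startswith("H") and res.element[j] != "H":
                heavy_res.append(ridx)
                heavy_name.append(nm)
                heavy_xyz.append(res.coord[j])
        missing = [n for n in BACKBONE if np.isnan(coords[n][ridx]).any()]
        if missing:
            raise ValueError(
                f"residue {ridx + 1} ({res3}) lacks backbone atom(s): {', '.join(missing)}"
            )
    struct = Structure(
        sequence="".join(seq_chars),
        coords=coords,
        label=label,
        heavy_atoms={
            "res_index": heavy_res,
            "name": heavy_name,
            "coords": np.asarray(heavy_xyz, dtype=float),
        },
    )
    return struct


def read_pdb(path: Union[str, Path], model_policy: str = "first") -> Union[Structure, Ensemble]:
    """Read a PDB file into a Structure (``model_policy="first"``) or an
    Ensemble mapping MODEL blocks to members (``model_policy="all"``).
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    path = Path(path)
    pdb_file = bpdb.PDBFile.read(str(path))
    n_models = pdb_file.get_model_count()
    if n_models == 0:
        raise ValueError(f"{path}: no models / ATOM records found")
    stem = path.stem
    if model_policy == "first":
        arr = pdb_file.get_structure(model=1)
        return _structure_from_atom_array(arr, label=stem)
    members = []
    for i in range(1, n_models + 1):
        arr = pdb_file.get_structure(model=i)
        members.append(_structure_from_atom_array(arr, label=f"{stem}_{i}"))
    return Ensemble(members=members)


def _atom_array_from_structure(struct: Structure) -> bst.AtomArray:
    rows = []
    for ridx in range(struct.n_residues):
        for name in ("N", "CA", "C", "O", "CB", "H"):
            arr = struct.coords.get(name)
            if arr is None or np.isnan(arr[ridx]).any():
                continue
            rows.append((ridx, name, arr[ridx]))
    atoms = bst.AtomArray(len(rows))
    atoms.coord = np.asarray([r[2] for r in rows], dtype=np.float32)
    atoms.chain_id = np.asarray(["A"] * len(rows))
    atoms.res_id = np.asarray([r[0] + 1 for r in rows])
    atoms.res_name = np.asarray([_ONE_TO_THREE[struct.sequence[r[0]]] for r in rows])
    atoms.atom_name = np.asarray([r[1] for r in rows])
    atoms.element = np.asarray([r[1][0] for r in rows])
    atoms.hetero = np.zeros(len(rows), dtype=bool)
    return atoms


def write_pdb(obj: Union[Structure, Ensemble], path: Union[str, Path]) -> None:
    """Write a Structure (single model, no MODEL records) or an Ensemble
    (one MODEL/ENDMDL block per member) as a standard PDB file."""
    pdb_file = bpdb.PDBFile()
    if isinstance(obj, Structure):
        pdb_file.set_structure(_atom_array_from_structure(obj))
    else:
        if len(obj) == 0:
            raise ValueError("cannot write an empty ensemble")
        arrays = [_atom_array_from_structure(m) for m in obj.members]
        stack = bst.stack(arrays)
        pdb_file.set_structure(stack)
    if not pdb_file.lines or pdb_file.lines[-1].strip() != "END":
        pdb_file.lines.append("END")
    pdb_file.write(str(path))


def read_fasta(path: Union[str, Path]) -> str:
    """Sequence (one-letter codes) of the first FASTA record."""
    fasta = bfasta.FastaFile.read(str(path))
    for _, seq in fasta.items():
        seq = str(seq).strip().upper()
        if not seq:
            continue
        return seq
    raise ValueError(f"{path}: no sequence records")
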