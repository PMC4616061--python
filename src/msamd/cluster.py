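"""Stages 2-3 of screening: nearest-neighbour RMSD clustering.

Greedy peak-picking NN clustering: repeatedly take the unassigned member
with the most unassigned neighbours within the RMSD threshold (ties by
lowest index), form a cluster from it plus those neighbours, remove them,
repeat.  "Within" the threshold is inclusive (<=).  The largest cluster is
what the screening keeps; its central structure is the member minimising
the summed RMSD to its clustermates.

Stage 3 repeats the procedure with terminal residues excluded from the
RMSD and a finer threshold, so terminal flexibility stops splitting
otherwise-identical folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .geometry import _region_indices, _selection_coords, kabsch_superpose
from .structio import Ensemble

__all__ = [
    "ClusterResult",
    "rmsd_matrix",
    "nn_cluster",
    "central_structure",
    "recluster_excluding_termini",
    "termini_excluded_region",
]


def rmsd_matrix(
    ens: Ensemble,
    region: Optional[Sequence[int]] = None,
    selection: str = "backbone",
) -> np.ndarray:
    """Symmetric pairwise Kabsch-RMSD matrix (Å) over an ensemble.

    ``selection`` is "CA" or "backbone" (N, CA, C, O); ``region`` a 0-based
    residue index set.
    """
    if len(ens) == 0:
        raise ValueError("rmsd_matrix needs a non-empty ensemble")
    if selection == "CA":
        atoms = ("CA",)
    elif selection == "backbone":
        atoms = ("N", "CA", "C", "O")
    else:
        raise ValueError("selection must be 'CA' or 'backbone'")
    L = ens[0].n_residues
    idx = _region_indices(L, region)
    pts = [_selection_coords(m, atoms, idx) for m in ens]
    n = len(ens)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(pts[i], pts[j]).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


@dataclass
class ClusterResult:
    """Partition of an ensemble by pairwise RMSD.

    ``assignment[i]`` is the cluster id of member i; ids are 0..k-1 in
    decreasing cluster-size order (ties by lowest contained member index).
    """

    assignment: np.ndarray
    threshold: float
    matrix: np.ndarray
    region: Optional[np.ndarray] = None
    labels: List[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return int(self.assignment.max()) + 1 if len(self.assignment) else 0

    @property
    def n_clusters_nonsingleton(self) -> int:
        sizes = np.bincount(self.assignment)
        return int(np.sum(sizes > 1))

    def members_of(self, cluster_id: int) -> np.ndarray:
        return np.where(self.assignment == cluster_id)[0]

    @property
    def largest_cluster(self) -> np.ndarray:
        """Member indices of the largest cluster (cluster id 0 by ordering)."""
        return self.members_of(0)

    @property
    def central_structure(self) -> int:
        """Index of the central member of the largest cluster."""
        return central_structure(self.largest_cluster, self.matrix)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment)

    def to_frame(self) -> pd.DataFrame:
        central = {c: central_structure(self.members_of(c), self.matrix)
                   for c in range(self.n_clusters)}
        return pd.DataFrame({
            "member": np.arange(len(self.assignment)),
            "label": self.labels if self.labels else [str(i) for i in range(len(self.assignment))],
            "cluster": self.assignment,
            "is_central": [central[c] == i for i, c in enumerate(self.assignment)],
        })


def nn_cluster(matrix: np.ndarray, threshold: float) -> ClusterResult:
    """Greedy peak-picking nearest-neighbour clustering of an RMSD matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    n = matrix.shape[0]
    within = matrix <= threshold
    np.fill_diagonal(within, False)
    unassigned = np.ones(n, dtype=bool)
    raw = np.full(n, -1, dtype=int)
    cid = 0
    while unassigned.any():
        counts = (within & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        pick = int(np.argmax(counts))          # ties -> lowest index
        members = np.where(within[pick] & unassigned)[0]
        group = np.concatenate(([pick], members))
        raw[group] = cid
        unassigned[group] = False
        cid += 1
    # relabel by decreasing size, ties by lowest member index
    sizes = np.bincount(raw)
    first_member = [int(np.where(raw == c)[0][0]) for c in range(cid)]
    order = sorted(range(cid), key=lambda c: (-sizes[c], first_member[c]))
    remap = {old: new for new, old in enumerate(order)}
    assignment = np.array([remap[c] for c in raw], dtype=int)
    return ClusterResult(assignment=assignment, threshold=float(threshold), matrix=matrix)


def central_structure(cluster_members: Sequence[int], matrix: np.ndarray) -> int:
    """Member of the cluster minimising the summed RMSD to its clustermates.

    Ties broken by lowest member index; a singleton is its own centre.
    """
    members = np.asarray(list(cluster_members), dtype=int)
    if members.size == 0:
        raise ValueError("empty cluster has no central structure")
    sub = matrix[np.ix_(members, members)]
    sums = sub.sum(axis=1)
    return int(members[int(np.argmin(sums))])


def termini_excluded_region(length: int, n_terminal: int = 1, c_terminal: int = 1,
                            region: Optional[Sequence[int]] = None) -> np.ndarray:
    """Residue index set with the first/last residues dropped.

    ``region`` (0-based) overrides the default full range before exclusion,
    for per-target regions like the ones used for long-tailed miniproteins.
    """
    base = np.arange(length) if region is None else np.asarray(sorted(region), dtype=int)
    if n_terminal + c_terminal >= len(base):
        raise ValueError("termini exclusion leaves no residues")
    out = base[n_terminal:len(base) - c_terminal if c_terminal else len(base)]
    if len(out) < 3:
        raise ValueError("termini exclusion leaves fewer than 3 residues")
    return out


def recluster_excluding_termini(
    ens: Ensemble,
    threshold: float,
    n_terminal: int = 1,
    c_terminal: int = 1,
    selection: str = "backbone",
    region: Optional[Sequence[int]] = None,
) -> ClusterResult:
    """Stage-3 clustering: same NN procedure on the termini-reduced region."""
    if len(ens) == 0:
        raise ValueError("recluster needs a non-empty ensemble")
    reduced = termini_excluded_region(ens[0].n_residues, n_terminal, c_terminal, region)
    mat = rmsd_matrix(ens, region=reduced, selection=selection)
    result = nn_cluster(mat, threshold)
    result.region = reduced
    result.labels = ens.labels()
    return result
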