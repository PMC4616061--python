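"""Stage-1 screening: stereochemical quality via Ramachandran regions.

Each structure is scored by the fraction of its interior residues whose
(phi, psi) pair falls in the most-favored regions of a region map; the
quality filter keeps structures whose fraction strictly exceeds a threshold
(">" matches the reported "more than 90%/80%" rules).

The shipped default map is a documented rectangle-union approximation of
the classic core regions (alpha, beta, left-handed alpha); it can be
overridden from a small YAML file so a different favored-region definition
slots in without code changes.  Glycine, whose accessible map is far wider,
is scored as always-favored under the default map; proline is scored on the
general map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
import yaml

from .geometry import dihedral
from .structio import Ensemble, Structure

__all__ = [
    "Rect",
    "RegionMap",
    "default_region_map",
    "QualityRecord",
    "phi_psi",
    "favored_fraction",
    "quality_filter",
]

MOST_FAVORED = "most_favored"
ADDITIONAL = "additional_allowed"
GENEROUS = "generously_allowed"
DISALLOWED = "disallowed"
LABELS = (MOST_FAVORED, ADDITIONAL, GENEROUS, DISALLOWED)


def _wrap(angle: float) -> float:
    """Wrap to (-180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [phi_lo, phi_hi] x [psi_lo, psi_hi] (degrees)."""

    label: str
    phi_lo: float
    phi_hi: float
    psi_lo: float
    psi_hi: float

    def contains(self, phi: float, psi: float) -> bool:
        return self.phi_lo <= phi <= self.phi_hi and self.psi_lo <= psi <= self.psi_hi


@dataclass
class RegionMap:
    """Total labelled coverage of the (phi, psi) torus.

    Rectangles are checked in order; the first hit wins; anything unmatched
    is ``disallowed``, so every angle pair maps to exactly one label.
    ``residue_maps`` optionally overrides the rectangles for specific
    one-letter codes (the default map sends glycine to an all-favored
    sub-map).
    """

    rects: List[Rect]
    residue_maps: dict = field(default_factory=dict)
    provenance: str = ""

    def label(self, phi: float, psi: float, residue: Optional[str] = None) -> str:
        rects = self.rects
        if residue is not None and residue.upper() in self.residue_maps:
            rects = self.residue_maps[residue.upper()]
        phi = _wrap(phi)
        psi = _wrap(psi)
        for rect in rects:
            if rect.contains(phi, psi):
                return rect.label
        # the beta strip wraps across psi = 180; a point at psi slightly
        # below -180 after wrapping was already handled by _wrap
        return DISALLOWED

    def to_yaml(self, path: Union[str, Path]) -> None:
        def dump(rects):
            return [
                {"label": r.label, "phi": [r.phi_lo, r.phi_hi], "psi": [r.psi_lo, r.psi_hi]}
                for r in rects
            ]
        payload = {
            "provenance": self.provenance,
            "rects": dump(self.rects),
            "residue_maps": {k: dump(v) for k, v in self.residue_maps.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RegionMap":
        payload = yaml.safe_load(Path(path).read_text())

        def load(items):
            rects = []
            for d in items:
                if d["label"] not in LABELS:
                    raise ValueError(f"unknown region label {d['label']!r}")
                rects.append(Rect(d["label"], d["phi"][0], d["phi"][1], d["psi"][0], d["psi"][1]))
            return rects

        return cls(
            rects=load(payload["rects"]),
            residue_maps={k: load(v) for k, v in payload.get("residue_maps", {}).items()},
            provenance=payload.get("provenance", ""),
        )


def default_region_map() -> RegionMap:
    """The shipped rectangle-union map of the classic core regions."""
    rects = [
        Rect(MOST_FAVORED, -100.0, -30.0, -67.0, -7.0),        # alpha core
        Rect(MOST_FAVORED, -180.0, -45.0, 90.0, 180.0),        # beta core
        Rect(MOST_FAVORED, -180.0, -45.0, -180.0, -170.0),     # beta wrap-around strip
        Rect(ADDITIONAL, 30.0, 100.0, -20.0, 80.0),            # left-handed alpha
    ]
    everything = [Rect(MOST_FAVORED, -180.0, 180.0, -180.0, 180.0)]
    return RegionMap(
        rects=rects,
        residue_maps={"G": everything},
        provenance="built-in rectangle-union core-region approximation",
    )


@dataclass(frozen=True)
class QualityRecord:
    """Per-structure stereochemical score."""

    label: str
    n_scored: int
    favored_count: int

    @property
    def favored_fraction(self) -> float:
        return self.favored_count / self.n_scored


def phi_psi(struct: Structure) -> List[Tuple[float, float]]:
    """(phi, psi) in degrees for interior residues 2..L-1.

    phi is undefined at residue 1 and psi at residue L, so terminal
    residues are excluded; the returned list has L-2 pairs.
    """
    L = struct.n_residues
    if L < 3:
        raise ValueError("phi/psi needs at least 3 residues")
    N, CA, C = struct.coords["N"], struct.coords["CA"], struct.coords["C"]
    out = []
    for i in range(1, L - 1):
        phi = dihedral(C[i - 1], N[i], CA[i], C[i])
        psi = dihedral(N[i], CA[i], C[i], N[i + 1])
        out.append((phi, psi))
    return out


def favored_fraction(struct: Structure, region_map: Optional[RegionMap] = None) -> QualityRecord:
    """Fraction of scored (interior) residues in most-favored regions."""
    if region_map is None:
        region_map = default_region_map()
    pairs = phi_psi(struct)
    favored = 0
    for i, (phi, psi) in enumerate(pairs, start=1):
        if region_map.label(phi, psi, residue=struct.sequence[i]) == MOST_FAVORED:
            favored += 1
    return QualityRecord(label=struct.label, n_scored=len(pairs), favored_count=favored)


def quality_filter(
    ens: Ensemble,
    region_map: Optional[RegionMap] = None,
    min_fraction: float = 0.8,
    top_fraction: Optional[float] = None,
) -> Tuple[Ensemble, List[QualityRecord]]:
    """Keep members whose favored fraction strictly exceeds ``min_fraction``.

    Order is preserved.  If ``top_fraction`` is given the threshold rule is
    replaced by keeping the best ``top_fraction`` of members by favored
    fraction (ties at the boundary resolved by member order) — an optional
    mode for "first k%"-style selection.
    Returns the filtered ensemble plus the per-member quality records.
    """
    if len(ens) == 0:
        raise ValueError("quality_filter needs a non-empty ensemble")
    if region_map is None:
        region_map = default_region_map()
    records = [favored_fraction(m, region_map) for m in ens]
    if top_fraction is not None:
        k = int(round(top_fraction * len(ens)))
        order = sorted(range(len(ens)), key=lambda i: (-records[i].favored_fraction, i))
        keep = sorted(order[:k])
    else:
        keep = [i for i, r in enumerate(records) if r.favored_fraction > min_fraction]
    return ens.subset(keep), records
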