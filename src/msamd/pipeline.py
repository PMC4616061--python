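"""Campaign orchestration and the three-step empirical screening.

A campaign builds one extended chain, minimizes it once, then launches N
independently seeded (anneal -> production) replicas; the converged final
structures form the sampled ensemble.  Screening then runs:

  stage 1  Ramachandran quality filter (favored fraction > threshold)
  stage 2  NN clustering at a coarse RMSD threshold, keep the largest cluster
  stage 3  re-cluster with terminal residues excluded at a finer threshold,
           keep the largest cluster; its central structure represents the
           prediction

The ScreeningReport reproduces the bookkeeping such campaigns are judged
by: per-stage input/output counts and percentages (2-decimal, half-up),
plus RMSD-to-reference summaries (counts below cutoffs, minimum).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import ramachandran as _rama
from .geometry import ca_rmsd
from .simulator import (
    AnnealingSchedule,
    ConvergenceCriterion,
    ToyForceField,
    anneal,
    build_extended,
    minimize,
    production,
)
from .structio import Ensemble, MemberMeta, Structure, residue_range, write_pdb

__all__ = [
    "CampaignConfig",
    "StageRecord",
    "ScreeningReport",
    "round_percentage",
    "run_campaign",
    "screen",
    "rmsd_summary",
    "campaign_report",
    "PRESETS",
    "preset_config",
]


def round_percentage(output_count: int, input_count: int) -> float:
    """100 * output/input rounded to 2 decimals, half-up (report convention)."""
    if input_count <= 0:
        return 0.0
    pct = Decimal(100 * output_count) / Decimal(input_count)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CampaignConfig:
    """Everything one campaign needs: sequence, schedule, seeds, thresholds."""

    sequence: str
    n_replicas: int = 50
    root_seed: int = 0
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule.desk)
    criterion: ConvergenceCriterion = field(default_factory=ConvergenceCriterion.desk)
    forcefield: ToyForceField = field(default_factory=ToyForceField)
    favored_fraction_min: float = 0.8
    stage2_rmsd: float = 1.5
    stage3_rmsd: float = 1.0
    exclude_n_terminal: int = 1
    exclude_c_terminal: int = 1
    cluster_selection: str = "backbone"
    region: Optional[str] = None            # "start-stop", 1-based inclusive
    reference: Optional[Structure] = None
    rmsd_cutoffs: Tuple[float, ...] = (1.0, 2.0, 3.0)
    region_map: Optional[_rama.RegionMap] = None

    def __post_init__(self):
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.stage2_rmsd <= 0 or self.stage3_rmsd <= 0:
            raise ValueError("cluster thresholds must be > 0")
        if self.stage3_rmsd >= self.stage2_rmsd:
            raise ValueError("stage3 threshold must be finer than stage2")

    def region_indices(self) -> Optional[np.ndarray]:
        if self.region is None:
            return None
        return residue_range(len(self.sequence), self.region)


@dataclass
class StageRecord:
    name: str
    input_count: int
    output_count: int
    threshold: float

    @property
    def percentage(self) -> float:
        return round_percentage(self.output_count, self.input_count)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_count": self.input_count,
            "output_count": self.output_count,
            "threshold": self.threshold,
            "percentage": self.percentage,
        }


@dataclass
class ScreeningReport:
    """Stage-by-stage bookkeeping of one screening run."""

    stages: List[StageRecord] = field(default_factory=list)
    emptied_at_stage: Optional[str] = None
    cluster_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    central_structure_label: Optional[str] = None
    rmsd_summary: Optional[pd.DataFrame] = None

    def add_stage(self, name: str, input_count: int, output_count: int,
                  threshold: float) -> StageRecord:
        if self.stages and input_count != self.stages[-1].output_count:
            raise ValueError(
                f"stage {name}: input {input_count} != previous output "
                f"{self.stages[-1].output_count}"
            )
        rec = StageRecord(name, input_count, output_count, threshold)
        self.stages.append(rec)
        return rec

    def to_dict(self) -> dict:
        return {
            "stages": [s.to_dict() for s in self.stages],
            "emptied_at_stage": self.emptied_at_stage,
            "cluster_counts": self.cluster_counts,
            "central_structure_label": self.central_structure_label,
            "rmsd_summary": None if self.rmsd_summary is None
            else self.rmsd_summary.to_dict(orient="records"),
        }

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def verify_arithmetic(self) -> None:
        """Re-check count chaining and percentage recomputation."""
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.input_count != prev.output_count:
                raise AssertionError("stage counts are not chained")
        for s in self.stages:
            if s.percentage != round_percentage(s.output_count, s.input_count):
                raise AssertionError("percentage does not recompute from counts")


# ---------------------------------------------------------------------------
# campaign
# ---------------------------------------------------------------------------

def _replica_seeds(root_seed: int, n: int) -> List[Tuple[int, int]]:
    """Per-replica (anneal, production) seed pairs below 2**31."""
    ss = np.random.SeedSequence(root_seed)
    return [tuple(int(s) % (2**31) for s in child.generate_state(2))
            for child in ss.spawn(n)]


def _run_one_replica(args):
    mini, schedule, criterion, ff, seeds, index = args
    s_ann, s_prod = seeds
    annealed = anneal(mini, schedule, seed=s_ann, ff=ff)
    res = production(annealed, schedule, criterion, seed=s_prod, ff=ff)
    total_ps = schedule.anneal_ps + res.simulated_ps
    return index, res, total_ps


def run_campaign(config: CampaignConfig, n_jobs: int = 1) -> Ensemble:
    """Run the full multi-replica campaign; returns the converged ensemble.

    All replicas start from the same minimized extended structure with
    distinct derived seeds.  Non-converged replicas contribute no structure
    but are still recorded in the ensemble metadata (as entries of the
    campaign log; the returned ensemble holds converged members only).
    ``n_jobs > 1`` runs replicas in separate processes with identical
    results to the sequential mode.
    """
    ext = build_extended(config.sequence)
    mini = minimize(ext, ff=config.forcefield)
    seeds = _replica_seeds(config.root_seed, config.n_replicas)
    jobs = [(mini, config.schedule, config.criterion, config.forcefield,
             seeds[i], i) for i in range(config.n_replicas)]
    if n_jobs > 1:
        from concurrent.futures import ProcessPoolExecutor
        with ProcessPoolExecutor(max_workers=n_jobs) as pool:
            results = list(pool.map(_run_one_replica, jobs))
        results.sort(key=lambda r: r[0])
    else:
        results = [_run_one_replica(j) for j in jobs]

    members: List[Structure] = []
    meta: List[MemberMeta] = []
    for index, res, total_ps in results:
        if res.structure is None:
            continue
        res.structure.label = f"replica_{index:04d}"
        members.append(res.structure)
        meta.append(MemberMeta(seed=seeds[index][0],
                               simulated_time_ps=total_ps,
                               converged=True, source_stage="production"))
    if not members:
        return Ensemble(members=[], meta=[])
    return Ensemble(members=members, meta=meta)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen(ens: Ensemble, config: CampaignConfig) -> Tuple[Ensemble, ScreeningReport]:
    """Three-step screening; returns (final ensemble, report)."""
    if len(ens) == 0:
        raise ValueError("screen needs a non-empty ensemble")
    report = ScreeningReport()

    # stage 1: stereochemical quality
    survivors, _records = _rama.quality_filter(
        ens, config.region_map, min_fraction=config.favored_fraction_min)
    report.add_stage("quality_filter", len(ens), len(survivors),
                     config.favored_fraction_min)
    if len(survivors) == 0:
        report.emptied_at_stage = "quality_filter"
        return survivors, report

    # stage 2: coarse NN clustering, keep largest cluster
    mat2 = _cluster.rmsd_matrix(survivors, region=config.region_indices(),
                                selection=config.cluster_selection)
    res2 = _cluster.nn_cluster(mat2, config.stage2_rmsd)
    res2.labels = survivors.labels()
    keep2 = res2.largest_cluster
    report.cluster_counts["stage2"] = {
        "clusters": res2.n_clusters,
        "clusters_nonsingleton": res2.n_clusters_nonsingleton,
    }
    stage2 = survivors.subset(keep2)
    report.add_stage("nn_cluster", len(survivors), len(stage2), config.stage2_rmsd)
    if len(stage2) == 0:  # unreachable: a cluster always has >= 1 member
        report.emptied_at_stage = "nn_cluster"
        return stage2, report

    # stage 3: termini-excluded re-clustering at the finer threshold
    res3 = _cluster.recluster_excluding_termini(
        stage2, config.stage3_rmsd,
        n_terminal=config.exclude_n_terminal,
        c_terminal=config.exclude_c_terminal,
        selection=config.cluster_selection,
        region=config.region_indices(),
    )
    keep3 = res3.largest_cluster
    report.cluster_counts["stage3"] = {
        "clusters": res3.n_clusters,
        "clusters_nonsingleton": res3.n_clusters_nonsingleton,
    }
    final = stage2.subset(keep3)
    report.add_stage("recluster_excluding_termini", len(stage2), len(final),
                     config.stage3_rmsd)
    central = res3.central_structure
    report.central_structure_label = stage2[central].label

    if config.reference is not None and len(final):
        report.rmsd_summary = rmsd_summary(
            final, config.reference, region=config.region_indices(),
            cutoffs=config.rmsd_cutoffs)
    return final, report


def rmsd_summary(
    ens: Ensemble,
    reference: Structure,
    region: Optional[Sequence[int]] = None,
    cutoffs: Sequence[float] = (),
) -> pd.DataFrame:
    """Cα-RMSD-to-reference table: per cutoff the count and percentage of
    members below it, plus the minimum RMSD and its member label."""
    if len(ens) == 0:
        raise ValueError("rmsd_summary needs a non-empty ensemble")
    rmsds = np.array([ca_rmsd(m, reference, region=region) for m in ens])
    rows = []
    for cut in cutoffs:
        count = int(np.sum(rmsds < cut))
        rows.append({"metric": f"ca_rmsd_below_{cut:g}A", "value": count,
                     "percentage": round_percentage(count, len(ens))})
    imin = int(np.argmin(rmsds))
    rows.append({"metric": "min_ca_rmsd_A", "value": float(rmsds[imin]),
                 "percentage": None})
    rows.append({"metric": "min_ca_rmsd_member", "value": ens[imin].label,
                 "percentage": None})
    return pd.DataFrame(rows)


def campaign_report(
    ens: Ensemble,
    report: ScreeningReport,
    final: Ensemble,
    outdir: Union[str, Path],
    reference: Optional[Structure] = None,
    region: Optional[Sequence[int]] = None,
) -> Dict[str, Path]:
    """Write the campaign artifacts: JSON report, CSV tables, PDBs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    paths["report"] = outdir / "screening_report.json"
    report.to_json(paths["report"])

    if len(ens):
        energies = np.array([m.potential_energy for m in ens
                             if m.potential_energy is not None])
        if len(energies):
            counts, edges = np.histogram(energies, bins=20)
            pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                          "count": counts}).to_csv(
                outdir / "energy_distribution.csv", index=False)
            paths["energy_distribution"] = outdir / "energy_distribution.csv"
        if reference is not None:
            rmsds = [ca_rmsd(m, reference, region=region) for m in ens]
            counts, edges = np.histogram(rmsds, bins=20)
            pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                          "count": counts}).to_csv(
                outdir / "rmsd_distribution.csv", index=False)
            paths["rmsd_distribution"] = outdir / "rmsd_distribution.csv"
        from .secstruct import forming_tendency
        forming_tendency(ens).to_csv(outdir / "ss_tendency.csv")
        paths["ss_tendency"] = outdir / "ss_tendency.csv"
        paths["sidecar"] = outdir / "ensemble_meta.json"
        ens.write_sidecar(paths["sidecar"])

    if len(final):
        paths["final_ensemble"] = outdir / "final_cluster.pdb"
        write_pdb(final, paths["final_ensemble"])
        if report.central_structure_label is not None:
            labels = final.labels()
            if report.central_structure_label in labels:
                central = final[labels.index(report.central_structure_label)]
                paths["central_structure"] = outdir / "central_structure.pdb"
                write_pdb(central, paths["central_structure"])
    return paths


# ---------------------------------------------------------------------------
# per-target presets (sequence, thresholds, regions)
# ---------------------------------------------------------------------------

PRESETS: Dict[str, dict] = {
    "ALPHA1": dict(
        sequence="ELLKKLLEELKG",
        favored_fraction_min=0.9, stage2_rmsd=1.5, stage3_rmsd=1.0,
        region="1-12",
    ),
    "TRPCAGE": dict(
        sequence="NLYIQWLKDGGPSSGRPPPS",
        favored_fraction_min=0.8, stage2_rmsd=3.0, stage3_rmsd=2.4,
        region="1-20",
    ),
    "POLYALA": dict(
        sequence="AAAAAAAAAAA",
        favored_fraction_min=0.8, stage2_rmsd=1.5, stage3_rmsd=1.0,
        region="1-11",
    ),
    "CHIGNOLIN": dict(
        sequence="GYDPETGTWG",
        favored_fraction_min=0.8, stage2_rmsd=1.5, stage3_rmsd=1.0,
        region="1-10",
    ),
    "UBQ_HAIRPIN": dict(
        sequence="MQIFVKTLDGKTITLEV",
        favored_fraction_min=0.8, stage2_rmsd=1.5, stage3_rmsd=1.0,
        region="1-17",
    ),
    "ERD": dict(
        sequence="XDPMTCEQAMASCEHTMCGYCQGPLYMTCIGITTDPECGLP",
        favored_fraction_min=0.8, stage2_rmsd=3.0, stage3_rmsd=2.4,
        region="4-34",
    ),
    "GAB": dict(
        sequence="TIDQWLLKNAKEDAIAELKKAGITSDFYFNAINKAKTVEEVNALKNEILKAHA",
        favored_fraction_min=0.8, stage2_rmsd=3.0, stage3_rmsd=2.4,
        region="9-52",
    ),
}


def preset_config(name: str, **overrides) -> CampaignConfig:
    """CampaignConfig for a named benchmark target, with overrides."""
    key = name.upper()
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    params = dict(PRESETS[key])
    params.update(overrides)
    return CampaignConfig(**params)
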