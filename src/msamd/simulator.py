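"""Annealing/production engine: the sampling half of the MSA-MD protocol.

One replica runs: extended build -> two-stage minimization -> simulated
annealing (heat 10->500 K, hold, cool ->0 K; Langevin/BAOAB, 1 fs) ->
production MD at 300 K (velocity-Verlet with a weak-coupling thermostat,
2 fs) that terminates when the per-window standard deviation of the
mass-weighted backbone RMSD against the production's starting structure
drops below a threshold.  A replica that never converges within the maximum
time yields no structure.

Times are ps internally (step sizes given in fs), energies kcal/mol,
temperatures K.  Everything stochastic is driven by one seed per call.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import minimize as scipy_minimize

from .builder import build_extended, build_ideal_helix, build_from_torsions  # noqa: F401 (module surface)
from .forcefield import (
    EnergyModel,
    Topology,
    ToyForceField,
    coords_to_structure,
    structure_to_coords,
)
from .geometry import kabsch_superpose
from .structio import Structure

__all__ = [
    "AnnealingSchedule",
    "ConvergenceCriterion",
    "ToyForceField",
    "build_extended",
    "build_ideal_helix",
    "build_from_torsions",
    "minimize",
    "anneal",
    "production",
    "ProductionResult",
    "potential_energy",
    "mean_kinetic_temperature",
]

KCAL_TO_INTERNAL = 418.4          # kcal/mol -> amu Å^2 / ps^2
KB = 0.0019872041                 # kcal/mol/K
KB_INT = KB * KCAL_TO_INTERNAL    # amu Å^2 / ps^2 / K


@dataclass(frozen=True)
class AnnealingSchedule:
    """Temperature program and production settings of one replica.

    Defaults are the protocol-scale values (50/30/70 ps annealing at 1 fs,
    10 ns production cap at 2 fs); :meth:`desk` gives the scaled-down
    program used for desk-scale campaigns.
    """

    T_start: float = 10.0          # K
    T_peak: float = 500.0          # K
    heat_ps: float = 50.0
    hold_ps: float = 30.0
    T_end: float = 0.0             # K
    cool_ps: float = 70.0
    anneal_dt_fs: float = 1.0
    production_T: float = 300.0    # K
    production_dt_fs: float = 2.0
    max_production_ps: float = 10000.0
    thermostat_tau_ps: float = 1.0     # weak-coupling time constant
    langevin_gamma: float = 2.0        # ps^-1, annealing friction

    def __post_init__(self):
        if self.heat_ps <= 0 or self.cool_ps <= 0 or self.hold_ps < 0:
            raise ValueError("annealing segment durations must be positive")
        if min(self.T_start, self.T_peak, self.T_end, self.production_T) < 0:
            raise ValueError("temperatures must be >= 0 K")

    @property
    def anneal_ps(self) -> float:
        return self.heat_ps + self.hold_ps + self.cool_ps

    def temperature(self, t_ps: float) -> float:
        """Piecewise-linear T(t) over the annealing program."""
        t = float(np.clip(t_ps, 0.0, self.anneal_ps))
        if t <= self.heat_ps:
            return self.T_start + (self.T_peak - self.T_start) * t / self.heat_ps
        if t <= self.heat_ps + self.hold_ps:
            return self.T_peak
        tc = t - self.heat_ps - self.hold_ps
        return self.T_peak + (self.T_end - self.T_peak) * tc / self.cool_ps

    @classmethod
    def desk(cls, max_production_ps: float = 1000.0) -> "AnnealingSchedule":
        """Scaled-down program: 5/3/7 ps annealing, 1 ns production cap."""
        return cls(heat_ps=5.0, hold_ps=3.0, cool_ps=7.0,
                   max_production_ps=max_production_ps)

    def scaled(self, factor: float) -> "AnnealingSchedule":
        """Shrink (or stretch) all durations by ``factor``."""
        return replace(
            self,
            heat_ps=self.heat_ps * factor,
            hold_ps=self.hold_ps * factor,
            cool_ps=self.cool_ps * factor,
            max_production_ps=self.max_production_ps * factor,
        )


@dataclass(frozen=True)
class ConvergenceCriterion:
    """Windowed RMSD-fluctuation termination rule for production MD.

    Every ``window_ps`` the sample standard deviation of the mass-weighted
    backbone RMSD (sampled each ``sample_interval_ps`` against the
    production's initial structure) is compared with ``std_threshold``;
    below it the trajectory stops and its final structure is kept.
    """

    window_ps: float = 500.0
    std_threshold: float = 0.2     # Å
    sample_interval_ps: float = 10.0

    def __post_init__(self):
        if not (self.window_ps > self.sample_interval_ps > 0):
            raise ValueError("need window_ps > sample_interval_ps > 0")
        if self.std_threshold < 0:
            raise ValueError("std_threshold must be >= 0")

    @classmethod
    def desk(cls) -> "ConvergenceCriterion":
        return cls(window_ps=50.0, std_threshold=0.2, sample_interval_ps=1.0)


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize(
    struct: Structure,
    ff: Optional[ToyForceField] = None,
    stage_plan: Tuple[str, ...] = ("fixed_backbone", "all"),
    sd_steps: int = 1000,
    cg_steps: int = 1000,
) -> Structure:
    """Two-stage minimization: steepest descent then conjugate gradient.

    ``stage_plan`` entries are "fixed_backbone" (N/CA/C/O frozen; only the
    amide hydrogens move — the stage degenerates gracefully when no free
    atoms exist) or "all".  The final energy never exceeds the initial one.
    """
    top = Topology(struct.sequence, ff)
    model = EnergyModel(top)
    x = structure_to_coords(struct, top)
    e0 = model.energy(x)
    if not np.isfinite(e0):
        raise ValueError(f"non-finite starting energy ({e0}); atoms may overlap exactly")

    for stage in stage_plan:
        if stage == "fixed_backbone":
            free = ~top.backbone_mask
        elif stage == "all":
            free = np.ones(top.n_atoms, dtype=bool)
        else:
            raise ValueError(f"unknown minimization stage {stage!r}")
        if not free.any():
            continue
        x = _descend(model, x, free, sd_steps, cg_steps)

    e_final = model.energy(x)
    out = coords_to_structure(x, top, label=struct.label or "minimized",
                              potential_energy=e_final)
    return out


def _descend(model: EnergyModel, x: np.ndarray, free: np.ndarray,
             sd_steps: int, cg_steps: int) -> np.ndarray:
    x = x.copy()
    fidx = np.where(free)[0]
    # steepest descent with backtracking
    step = 1e-3
    e, g = model.energy_and_grad(x)
    for _ in range(sd_steps):
        direction = np.zeros_like(x)
        direction[fidx] = -g[fidx]
        gnorm = np.linalg.norm(direction)
        if gnorm < 1e-10:
            break
        trial = x + step * direction / gnorm
        e_t = model.energy(trial)
        if e_t < e:
            x = trial
            e, g = model.energy_and_grad(x)
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    # conjugate gradient on the free coordinates
    if cg_steps > 0 and len(fidx):
        x0_free = x[fidx].ravel()

        def fun(v):
            xt = x.copy()
            xt[fidx] = v.reshape(-1, 3)
            e_t, g_t = model.energy_and_grad(xt)
            return e_t, g_t[fidx].ravel()

        res = scipy_minimize(fun, x0_free, jac=True, method="CG",
                             options={"maxiter": cg_steps})
        if res.fun <= e:     # CG line searches guarantee this, keep defensive
            x[fidx] = res.x.reshape(-1, 3)
    return x


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def _init_velocities(rng: np.random.Generator, masses: np.ndarray, T: float) -> np.ndarray:
    if T <= 0:
        return np.zeros((len(masses), 3))
    sigma = np.sqrt(KB_INT * T / masses)
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def _check_finite(x: np.ndarray, dt_fs: float, where: str) -> None:
    if not np.isfinite(x).all():
        raise FloatingPointError(
            f"non-finite coordinates during {where}; the {dt_fs} fs step is too "
            f"large for this system — reduce the step size"
        )


def anneal(
    struct: Structure,
    schedule: Optional[AnnealingSchedule] = None,
    seed: int = 0,
    ff: Optional[ToyForceField] = None,
) -> Structure:
    """Simulated-annealing run under the piecewise-linear T(t) program.

    Langevin (BAOAB) dynamics at the annealing step size; deterministic
    given ``seed``.  Returns the final (cooled) structure with its
    potential energy attached.
    """
    schedule = schedule or AnnealingSchedule()
    top = Topology(struct.sequence, ff)
    model = EnergyModel(top)
    x = structure_to_coords(struct, top)
    rng = np.random.default_rng(seed)
    m = top.masses[:, None]
    dt = schedule.anneal_dt_fs * 1e-3          # ps
    n_steps = int(round(schedule.anneal_ps / dt))
    gamma = schedule.langevin_gamma
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)

    v = _init_velocities(rng, top.masses, schedule.T_start)
    e, g = model.energy_and_grad(x)
    f = -g * KCAL_TO_INTERNAL
    for step in range(n_steps):
        T_t = schedule.temperature((step + 0.5) * dt)
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        sigma = np.sqrt(KB_INT * max(T_t, 0.0) / top.masses)[:, None]
        v = c1 * v + c2 * sigma * rng.normal(size=v.shape)
        x += 0.5 * dt * v
        e, g = model.energy_and_grad(x)
        f = -g * KCAL_TO_INTERNAL
        v += 0.5 * dt * f / m
        if step % 500 == 0:
            _check_finite(x, schedule.anneal_dt_fs, "annealing")
    _check_finite(x, schedule.anneal_dt_fs, "annealing")
    return coords_to_structure(x, top, label=struct.label or "annealed",
                               potential_energy=model.energy(x))


@dataclass
class ProductionResult:
    """Outcome of one production run; iterable as (structure, converged, ps)."""

    structure: Optional[Structure]
    converged: bool
    simulated_ps: float
    rmsd_samples: Optional[np.ndarray] = None
    window_stds: Optional[List[float]] = None

    def __iter__(self):
        return iter((self.structure, self.converged, self.simulated_ps))


def production(
    struct: Structure,
    schedule: Optional[AnnealingSchedule] = None,
    criterion: Optional[ConvergenceCriterion] = None,
    seed: int = 0,
    ff: Optional[ToyForceField] = None,
) -> ProductionResult:
    """Production MD at 300 K with the RMSD-fluctuation termination rule.

    Velocity-Verlet with weak-coupling (exponential relaxation of the
    kinetic energy toward the target temperature).  The RMSD reference is
    the production's initial structure (the post-annealing conformation).
    A run that reaches ``max_production_ps`` without meeting the criterion
    returns ``structure=None, converged=False``.
    """
    schedule = schedule or AnnealingSchedule()
    criterion = criterion or ConvergenceCriterion()
    top = Topology(struct.sequence, ff)
    model = EnergyModel(top)
    x = structure_to_coords(struct, top)
    rng = np.random.default_rng(seed)
    m = top.masses[:, None]
    dt = schedule.production_dt_fs * 1e-3
    tau = schedule.thermostat_tau_ps
    T0 = schedule.production_T
    ndof = 3 * top.n_atoms

    bb = np.where(top.backbone_mask)[0]
    bb_masses = top.masses[bb]
    ref_bb = x[bb].copy()

    def monitor_rmsd() -> float:
        return kabsch_superpose(x[bb], ref_bb, weights=bb_masses).rmsd

    v = _init_velocities(rng, top.masses, T0)
    e, g = model.energy_and_grad(x)
    f = -g * KCAL_TO_INTERNAL

    sample_every = max(1, int(round(criterion.sample_interval_ps / dt)))
    window_steps = max(sample_every, int(round(criterion.window_ps / dt)))
    max_steps = int(round(schedule.max_production_ps / dt))

    samples: List[float] = []
    window: List[float] = []
    stds: List[float] = []
    converged = False
    step = 0
    while step < max_steps:
        step += 1
        v += 0.5 * dt * f / m
        x += dt * v
        e, g = model.energy_and_grad(x)
        f = -g * KCAL_TO_INTERNAL
        v += 0.5 * dt * f / m
        # weak coupling: rescale toward T0
        ke_int = 0.5 * float(np.sum(top.masses[:, None] * v * v))
        T_inst = 2.0 * ke_int / (ndof * KB_INT)
        if T_inst > 0:
            lam = np.sqrt(max(1.0 + dt / tau * (T0 / T_inst - 1.0), 0.0))
            v *= lam
        if step % sample_every == 0:
            _check_finite(x, schedule.production_dt_fs, "production")
            r = monitor_rmsd()
            samples.append(r)
            window.append(r)
        if step % window_steps == 0 and len(window) >= 2:
            std = float(np.std(window, ddof=1))
            stds.append(std)
            window = []
            if std < criterion.std_threshold:
                converged = True
                break

    simulated_ps = step * dt
    if converged:
        out = coords_to_structure(x, top, label=struct.label or "production",
                                  potential_energy=model.energy(x))
    else:
        out = None
    return ProductionResult(structure=out, converged=converged,
                            simulated_ps=simulated_ps,
                            rmsd_samples=np.asarray(samples), window_stds=stds)


def mean_kinetic_temperature(
    struct: Structure,
    T: float = 300.0,
    ps: float = 50.0,
    seed: int = 0,
    ff: Optional[ToyForceField] = None,
    dt_fs: float = 1.0,
    gamma: float = 2.0,
    burn_in_ps: float = 5.0,
) -> float:
    """Time-averaged kinetic temperature of a constant-T Langevin run.

    Thermostat diagnostic: under Langevin dynamics the mean kinetic energy
    per degree of freedom is kB*T/2 for any potential, so the returned
    value should match ``T`` closely.
    """
    top = Topology(struct.sequence, ff)
    model = EnergyModel(top)
    x = structure_to_coords(struct, top)
    rng = np.random.default_rng(seed)
    m = top.masses[:, None]
    dt = dt_fs * 1e-3
    n_steps = int(round(ps / dt))
    burn = int(round(burn_in_ps / dt))
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sigma = np.sqrt(KB_INT * T / top.masses)[:, None]
    ndof = 3 * top.n_atoms
    v = _init_velocities(rng, top.masses, T)
    e, g = model.energy_and_grad(x)
    f = -g * KCAL_TO_INTERNAL
    acc = 0.0
    count = 0
    for step in range(n_steps):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * sigma * rng.normal(size=v.shape)
        x += 0.5 * dt * v
        e, g = model.energy_and_grad(x)
        f = -g * KCAL_TO_INTERNAL
        v += 0.5 * dt * f / m
        if step >= burn:
            ke_int = 0.5 * float(np.sum(top.masses[:, None] * v * v))
            acc += 2.0 * ke_int / (ndof * KB_INT)
            count += 1
    return acc / max(count, 1)


def potential_energy(struct: Structure, ff: Optional[ToyForceField] = None,
                     breakdown: bool = False):
    """Potential energy (kcal/mol) of a conformation; optionally per-term."""
    top = Topology(struct.sequence, ff)
    model = EnergyModel(top)
    x = structure_to_coords(struct, top)
    e, parts = model.energy_breakdown(x)
    return (e, parts) if breakdown else e
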