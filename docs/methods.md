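# Methods

This note documents the models and procedures implemented in `msamd`, the
parameters that matter, the numerical choices behind them, and the limits
of what the coarse-grained simulator can show.

## 1. Data model

A `Structure` is backbone-level: per residue the N, CA, C, O coordinates
(Å), optionally the amide H and CB. Every analysis in the pipeline — Cα /
backbone RMSD, φ/ψ stereochemistry, hydrogen-bond secondary structure —
needs only these atoms. Structures read from an all-atom PDB additionally
retain their heavy-atom records so heavy-atom RMSD remains available for
such inputs; simulator output is backbone-only and reports heavy-atom RMSD
as unavailable. Invariants enforced at validation: finite mandatory
coordinates, length ≥ 3, and consecutive residues peptide-bonded with
C(i)–N(i+1) ∈ (1.0, 2.0) Å.

Amide hydrogens missing from an input are reconstructed geometrically: H
on the N along the in-plane bisector opposite the C(i−1)–N–CA angle at
1.01 Å — standard practice for structures deposited without protons.
Residue 1 and prolines carry no amide H and are never hydrogen-bond
donors.

Residue numbering in user-facing intervals ("4-34") is 1-based inclusive,
matching the convention of structure-prediction reports; internally all
index sets are 0-based.

Ensemble provenance (seed, simulated time, convergence flag, stage) lives
in a JSON sidecar because the PDB format has no fields for it.

## 2. Superposition and RMSD

Kabsch superposition via SVD of the (optionally weighted) covariance
matrix with the determinant sign fix, so the optimal rotation is always
proper — a reflection is never used even when it would fit better (tested
against brute-force rotation sampling and an independent quaternion
oracle). For degenerate point sets (perfect planarity, tied singular
values) any optimal rotation is acceptable; only the RMSD value is
contract-bearing.

Two RMSD flavours mirror their two uses: the production-convergence
monitor uses **mass-weighted backbone** RMSD (N/CA/C/O weighted by atomic
mass), while analysis RMSDs are **unweighted Cα** for distributions and
reference comparisons and **backbone** for clustering. The convergence
statistic is the sample (n−1) standard deviation of the windowed RMSD
series; population vs sample is not fixed by convention anywhere, so the
(n−1) form was chosen and the 0.2 Å threshold is configurable to absorb
the difference.

## 3. Ramachandran quality filter

No canonical favored-region map is bundled with the screening literature,
so the package ships a documented rectangle-union approximation of the
classic core regions, overridable from YAML:

| region | φ (deg) | ψ (deg) | label |
|---|---|---|---|
| α core | [−100, −30] | [−67, −7] | most_favored |
| β core | [−180, −45] | [90, 180] ∪ [−180, −170] | most_favored |
| left-handed α | [30, 100] | [−20, 80] | additional_allowed |
| elsewhere | — | — | disallowed |

Rectangles are checked in order, the map is periodic on the torus, and
every (φ, ψ) receives exactly one label. Glycine — whose accessible map is
far wider than the general one — is scored as always-favored; proline is
scored on the general map (its φ is restrained near −65° by the builder
and force field anyway); pre-proline residues get no special treatment.
These choices make the stage-1 filter deterministic and testable without
an external stereochemistry program; fixtures used in tests are built
inside (or outside) these rectangles by construction.

The filter keeps members whose favored fraction **strictly exceeds** the
threshold ("more than 90 %" style rules). An alternative top-k% mode
(keep the best fifth of the ensemble by favored fraction) exists behind
`top_fraction=` for "first 20 %"-style selection; the fraction-threshold
rule is the default because the worked screening chains are all stated
through it. Per-target thresholds (90 % vs 80 %) look empirical rather
than principled; they are plain config values with no inference.

## 4. Secondary structure

The standard hydrogen-bond pattern algorithm: electrostatic N–H···O=C
energy `E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol, bond
declared below −0.5 kcal/mol, energies floored at −9.9 for near-contact
geometries. Self and adjacent pairs (|i−j| < 2) are excluded. n-turn
patterns give helices (two consecutive 4-turns → H over four residues;
3-turns → G; 5-turns → I), parallel/antiparallel bridge patterns give E,
turn interiors give T, and Cα(i−2)–Cα(i)–Cα(i+2) curvature above 70°
gives S. Priority H > E > G > I > T > S > C. π-helix and strand are
implemented even though helical benchmark profiles rarely show them, so
β-targets remain analyzable. One deliberate convention of this pipeline:
chain termini only ever carry C/T/S (a pattern-derived helix/strand code
at residue 1 or L is demoted), which keeps terminal flexibility out of
the tendency profiles. A defensive chain-break rule (C–N > 2.5 Å splits
the turn/helix pattern search) exists although the simulator never
produces breaks.

Forming-tendency profiles are plain empirical per-residue code
frequencies over an ensemble; for every residue the frequencies over the
full alphabet (including coil) sum to 1.

## 5. Nearest-neighbour clustering

The exact NN variant used by external clustering tools is not specified
anywhere usable, so the package implements deterministic **greedy
peak-picking**: repeatedly select the unassigned member with the most
unassigned neighbours within the threshold (ties by lowest index), form a
cluster from it plus those neighbours, remove, repeat. "Within" is
inclusive (≤). Cluster ids are ordered by decreasing size (ties by lowest
member index), so "keep the largest cluster" is id 0; an exactly tied
largest cluster resolves to the one containing the lowest member index.
On well-separated block matrices the partition coincides with
single-linkage connected components (a test oracle); on ambiguous
geometries the greedy partition is simply what it is — deterministic and
reproducible. Both cluster totals (with and without singletons) are
reported because conventions differ on whether singletons count as
clusters.

Stage 2 clusters on backbone RMSD over the configured region; stage 3
repeats the procedure with terminal residues excluded (default: first and
last residue; per-target overrides via the region config) at the finer
threshold. Config validation enforces stage3 < stage2, the coarse→fine
pattern (1.5→1.0, 3.0→2.4 Å) of the benchmark chains.

## 6. The coarse-grained simulator

The all-atom force field and implicit solvent of a production MD engine
are out of scope. The `ToyForceField` is a declared stand-in whose job is
to give the campaign machinery a landscape with the right *shape*:
sequence-dependent helix/extended competition, cooperative backbone
hydrogen bonding, excluded volume, and stiff ideal bonded geometry.

Terms (energies kcal/mol, lengths Å):

* **Bonds** k(r−r₀)², k = 300 (100 for N–H), Engh–Huber-style ideal
  lengths; **angles** k(θ−θ₀)², k = 80 (30 for H).
* **ω restraint** k(1+cos ω), k = 20, about every peptide bond — the
  trans-keeping role of a backbone chirality restraint at high
  temperature. Impropers (k = 15) keep carbonyl O and amide H planar.
* **φ/ψ torsion map**: per interior residue a sum of two Gaussian wells
  on the torus, at the α-helical basin (−57, −47) and the
  extended/β basin (−140, 150), width σ = 32°. Well depths come from a
  per-residue-type table: strong helix formers (A, E, L, K: 3.0 vs 0.8)
  through intermediates to near-flat glycine (0.4/0.4); proline gets a
  harmonic φ restraint near −65° instead of a free φ. "X" is treated as
  alanine-like.
* **H-bonds**: Gaussian well of depth 1.5 on the O(i)···H(i+3/i+4)
  distance, optimum 2.0 Å, width 0.35 Å — the i→i+4/i+3 geometry of
  α/3₁₀ helices.
* **Excluded volume**: soft-core quartic ε(1−(r/r_c)²)² between heavy
  atoms ≥ 2 residues apart, r_c = 2.7 Å, ε = 50 — finite (never
  singular) at full overlap, so a clashed input yields a large energy
  and a usable gradient instead of an error. No nonbonded cutoff beyond
  r_c is needed at ≤ ~60 residues.

All gradients are analytic and checked against central finite differences
(relative 1e-4) in the test suite. The energy is evaluated by a numba
kernel; a vectorised numpy path computes identical numbers (agreement to
1e-9 is itself a test) and serves as the fallback when numba is absent.

**Integrators.** Annealing uses Langevin dynamics with BAOAB splitting
(friction 2 ps⁻¹) — robust thermostatting across the 10→500→0 K ramp,
which is piecewise linear because only its endpoints and durations are
meaningful. Production uses velocity-Verlet with weak-coupling velocity
rescaling (time constant 1.0 ps) toward 300 K, the exponential-relaxation
thermostat conventional for production runs. Mean kinetic temperature
under the Langevin integrator matches the target within a few percent
(equipartition diagnostic). Units: kcal/mol, Å, ps, amu;
1 kcal/mol = 418.4 amu·Å²/ps².

**Seeding.** Each replica derives all its draws (initial velocities,
Langevin noise) from one root seed via `SeedSequence` spawning, so any
replica is bit-reproducible in isolation and the campaign is
reproducible end to end; the optional process-parallel mode produces
outputs identical to the sequential mode because seeds are assigned per
replica, not per worker.

**Problem sizes.** The protocol-scale schedule (50/30/70 ps annealing,
10–20 ns production cap, 500 ps convergence windows) is available but
pointless for the toy potential, which relaxes orders of magnitude faster
than an all-atom system. Desk-scale defaults — 5/3/7 ps annealing, 50 ps
windows sampled every 1 ps, 1 ns cap, 30–50 replicas — were chosen as the
sizes at which campaign statistics (convergence fractions, cluster
structure) are already stable for ≤ 20-residue peptides, and are what the
tests and the acceptance script use.

## 7. Campaign and screening orchestration

`run_campaign` builds the extended chain (φ = ψ = 180°) once, minimizes it
once (two stages — backbone frozen, then all atoms free; in the
backbone-only model stage 1 moves only the hydrogens and degenerates
gracefully when nothing is free — each stage 1000 steepest-descent steps
then 1000 conjugate-gradient steps, energy never increasing), and runs
the replicas. Only converged replicas contribute members; a campaign in
which nothing converges returns an empty ensemble explicitly. The
production RMSD reference is the post-annealing structure (a global
reference, not per-window), the more stringent reading of
"relative to the initial structure"; each trajectory extends
window-by-window up to the cap.

Screening percentages are reported with 2-decimal half-up rounding —
the convention that reproduces every printed benchmark percentage
exactly — and the report object re-verifies that stage counts chain
(stage k input = stage k−1 output) and that every percentage recomputes
from its counts. Stage-2 percentages are of the stage-2 input (the
convention all worked chains follow); both denominators are in the
report. The screening-only entry point accepts any multi-model PDB, so
the screening stack works on ensembles from real MD engines without the
toy simulator.

## 8. Synthetic fixtures

`msamd.synthetic` builds ensembles with known composition (noisy ideal
helices + noisy extended decoys). Noise is applied in **torsion space**
(φ/ψ ~ N(basin, 3.5°), giving ≈ 0.3 Å Cα dispersion) rather than
Cartesian space, so bonded geometry stays ideal and every member
satisfies the peptide-bond invariant; Cartesian jitter of equivalent
magnitude would corrupt bond lengths faster than it perturbs the fold.
These fixtures are synthetic by construction and labelled as such.

## 9. What passing desk-scale tests does and does not show

The toy potential is helix-biased by design, so polyalanine-style
campaigns demonstrate that the machinery — annealing schedules, the
STD-of-RMSD terminator, screening, central-structure selection — behaves
correctly and reproducibly, not that the potential predicts real folds.
β-hairpin targets will not fold under it (all-atom force fields
themselves struggle there), absolute energies are not comparable to any
all-atom scale, and solvent, side-chain packing and salt bridges are
absent entirely. Conclusions about real peptides require plugging a real
engine's ensembles into the screening-only entry point.

## 10. Known limitations

* No mmCIF, heteroatoms, alternate locations or occupancies; PDB and
  FASTA only.
* Heavy-atom RMSD requires all-atom input; backbone-only structures
  report it as unavailable rather than silently approximating.
* The greedy NN partition is one of several defensible NN variants;
  cluster *memberships* near the threshold boundary are
  algorithm-specific even though the largest-cluster semantics are
  stable.
* The bend (S) definition uses the standard 70° Cα-curvature rule; no
  β-bulge subtleties beyond the plain bridge patterns.
* Percentage rounding is half-up, which can differ from banker's
  rounding in the last digit.
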