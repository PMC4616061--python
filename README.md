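# msamd

Conformational-space search for peptides and miniproteins by **multiple
simulated-annealing molecular dynamics (MSA-MD)** with empirical
post-screening — plus a coarse-grained backbone simulator that makes the
whole pipeline runnable on a desk.

## The problem and the strategy

Predicting a small peptide's fold from its sequence with plain MD is hard:
a single trajectory gets stuck in local minima long before it visits the
native basin. The MSA-MD strategy attacks this with breadth instead of
length. From one minimized, fully extended chain it launches many
independent simulated-annealing trajectories (heat 10→500 K in 50 ps, hold
30 ps, cool to 0 K in 70 ps; 1 fs steps) that differ only in their random
initial velocities, each followed by production MD at 300 K (2 fs steps,
weak-coupling thermostat). A production run terminates when it stops
moving: every 500 ps the standard deviation of the mass-weighted backbone
RMSD against the run's starting structure is computed, and an STD below
0.2 Å ends the run and keeps its final structure; a run that never settles
within the time cap contributes nothing.

The resulting ensemble (hundreds to a thousand structures) is distilled to
one near-native cluster by three screening steps:

1. **Stereochemical quality** — keep structures whose fraction of interior
   residues in the most-favored Ramachandran regions exceeds a threshold
   (e.g. > 90 %).
2. **Nearest-neighbour RMSD clustering** at a coarse threshold (e.g.
   1.5 Å backbone RMSD); keep the largest cluster.
3. **Termini-excluded re-clustering** at a finer threshold (e.g. 1.0 Å)
   with the flexible terminal residues removed from the RMSD; keep the
   largest cluster. Its *central structure* — the member with the minimal
   summed RMSD to its clustermates — is the prediction.

Every similarity in the pipeline is a Kabsch least-squares superposition
followed by RMSD, `RMSD = sqrt((1/n) Σᵢ ‖R xᵢ + t − yᵢ‖²)` minimized over
proper rotations R and translations t, optionally mass-weighted or
restricted to a residue region (the `4–34`-style intervals used for
long-tailed miniproteins). Secondary structure is assigned from backbone
hydrogen bonds with the standard electrostatic energy
`E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol and the
H/G/I/E/T/S pattern rules.

The all-atom force field of a production engine is out of scope here; in
its place ships a documented coarse-grained backbone potential
(sequence-biased φ/ψ wells, backbone H-bond wells, excluded volume, trans
peptide restraint) whose purpose is to exercise the full
sampling-and-screening machinery realistically at desk scale. See
`docs/methods.md` for the model, its parameters and its limits.

## Worked example

A small desk-scale campaign on Ala₁₁, screened against itself:

```python
from msamd import CampaignConfig, run_campaign, screen, build_ideal_helix, ca_rmsd

cfg = CampaignConfig(sequence="AAAAAAAAAAA", n_replicas=10, root_seed=1)
ens = run_campaign(cfg)
print(f"{len(ens)} of {cfg.n_replicas} replicas converged")

final, report = screen(ens, cfg)
for s in report.stages:
    print(f"{s.name}: {s.input_count} -> {s.output_count} ({s.percentage}%)")

helix = build_ideal_helix(cfg.sequence)
central = final[final.labels().index(report.central_structure_label)]
print(f"central structure: {report.central_structure_label}, "
      f"Ca RMSD to ideal helix = {ca_rmsd(central, helix):.3f} A")
```

prints

```
10 of 10 replicas converged
quality_filter: 10 -> 10 (100.0%)
nn_cluster: 10 -> 10 (100.0%)
recluster_excluding_termini: 10 -> 10 (100.0%)
central structure: replica_0004, Ca RMSD to ideal helix = 0.436 A
```

All ten annealing replicas fold the alanine chain into the helical basin
(the quality filter and both clusterings keep everything, so the stage
percentages are 100 %), and the representative picked by the screening
sits 0.44 Å from the ideal α-helix built at (φ, ψ) = (−57°, −47°).

The same machinery is available from the shell: `msamd run --sequence …`,
`msamd screen --ensemble multi_model.pdb …` (screening-only, for ensembles
produced by a real MD engine) and `msamd analyze --ensemble … --reference …`.

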