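# aggkin

Aggregation-kinetics analysis for coarse-grained multi-peptide trajectories.

The package analyses trajectories of short amyloidogenic peptides (default:
20 copies of GNNQQNY, five backbone atoms plus one side-chain bead per
residue) and provides:

- **cg_model** — domain types (Topology / Frame / Trajectory), PDB and DCD
  I/O, unit conversions (molar concentration of a periodic box, integration
  steps to wall time), minimum-image geometry.
- **structure_metrics** — backbone dihedrals, Ramachandran beta-state
  classification (configurable phi/psi windows), DSSP-style Kabsch–Sander
  hydrogen-bond energies, side-chain contact counts.
- **sheet_clustering** — per-frame strand-attachment graphs (two peptides
  attach when they share ≥ 2 accepted hydrogen bonds and both pass the
  ≥ 3-beta-residue rule), cluster partitions as connected components,
  parallel/antiparallel strand orientation, polymorph classification
  (two-sheet vs three-plus-sheet vs disordered).
- **kinetics** — frame-to-frame lineage tracking, kinetic event
  classification (monomer addition/loss, oligomer fusion/fragmentation,
  direct monomers↔oligomer events), per-size creation/destruction rates,
  binned event totals, cumulative sigmoidal size curves with logistic
  lag-time fits, nucleation/reversibility episode detection, energy-trace
  alignment, and (n_hbonds, n_contacts) structure maps.
- **thermo** — occupancy statistics, free-energy profiles F = −kT ln P over
  aggregate size and beta-residue count, critical-nucleus extraction with
  plateau ranges, and a classical-nucleation-theory model
  (ΔG(n) = −n kT ln S + θ n^(2/3)) with closed-form stationary point and
  least-squares fitting (a small-system caveat is always attached for
  ≤ 20-monomer systems).
- **synthetic_data** — self-verified ideal beta sheets and random-coil
  fixtures, scripted aggregation scenarios with exact ground truth, and an
  exact Gillespie aggregation simulator, including a detailed-balance mode
  whose equilibrium matches a prescribed free-energy profile (used for
  parameter-recovery tests).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, bookkeeping round-trips, free-energy parameter recovery,
fixture self-verification, CNT/sigmoid internal consistency).

## Command line

```sh
aggkin synth ideal-sheet --n 5 --orientation parallel --out out/
aggkin synth coil --n 20 --out out/
aggkin synth kmc --preset paper-like --seed 7 --out out/
aggkin synth scripted --scenario growth --n 20 --out out/

aggkin analyze  --topology top.pdb --trajectory traj.pdb --out out/
aggkin kinetics --topology top.pdb --trajectory traj.pdb \
                --energies energies.csv --out out/
aggkin thermo   --topology top.pdb --trajectory traj.pdb --out out/
aggkin report   --topology top.pdb --trajectory traj.pdb --out out/
```

All criteria are configurable through a YAML config (`--config run.yaml`);
every default actually used is echoed at INFO level.  Exit codes: 0 ok,
2 bad input, 3 bad configuration.  Energy CSVs need columns
`time, E_total` (plus optional components; extra columns are ignored).

Note: the per-frame `beta_fraction` is this package's own dihedral-window
measure, not a STRIDE assignment — do not compare it directly with
STRIDE-derived secondary-structure percentages.

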