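# recharge

Refinement of lipid partial charges by thermodynamic reweighting, together
with the trajectory observables used to diagnose and validate neutral-lipid
models:

- **topology** — read/validate/rewrite per-atom charges in GROMACS-dialect
  `.itp` files, with equivalence groups, frozen atoms and net-charge
  constraints declared in a sidecar TOML.
- **reweight** — importance reweighting of a fixed sampled ensemble to
  perturbed charges: weighted means, blocked confidence intervals, Kish
  effective sample size, and covariance-formula charge-gradients of
  observables.
- **optimize** — the iterative parameterization engine: per-cycle
  regularized projected-gradient minimization of a CI-weighted
  least-squares target mismatch, with hard per-cycle caps on charge moves
  (presets `C36-c`: 0.005 e, `C36-p`: 0.02 e) and confidence-interval
  overlap as the stopping rule.
- **interfacial** — mechanical (Kirkwood-Irving) surface/interfacial
  tension from pressure-tensor diagonals, running/blocking averages with
  Student-t CIs, water content inside an oil core, and hydration-plateau
  equilibration detection.
- **profiles** — lateral density profiles along the bilayer normal
  (0.07 nm bins), Boltzmann-inversion free-energy profiles, flip-flop
  barrier extraction and replica aggregation.
- **dipoles** — fragment dipole moments under alternative charge sets and
  the distribution of dipole-modulus changes (0.01 D bins, Gaussian fits).
- **toys** — a self-contained Metropolis sampler for small charged LJ
  fluids (emitting energies, exact charge-derivatives and virial pressure
  tensors), plus generators for noisy tension series and
  planted-PMF particle distributions. These stand in for the MD engine in
  all tests; real MD output is consumed via `.xvg`/GRO/CSV readers.

## CLI

All commands write CSV tables plus a JSON report with a provenance block
(resolved parameters, config hash, seed, library versions).

```sh
recharge tension --xvg pressure.xvg --lz 12 --block-ns 100
recharge hydration --frames traj.csv --oil TOG --water SOL
recharge profile --frames traj.gro --atomname P --bin-nm 0.07
recharge pmf --frames traj.csv --atomname C2 --zmin -3 --zmax 3
recharge dipole --frames traj.csv --fragments frags.json \
    --q-old old.csv --q-new new.csv --bin-d 0.01
recharge charges molecule.itp --config groups.toml --diff other.itp
recharge toysim --n-pos 8 --n-neg 8 --q 0.15 --steps 20000 --seed 1
recharge optimize --targets targets.toml --preset C36-c --sampler toy
```

`targets.toml` mirrors the training-table columns:

```toml
[[targets]]
system = "TOG"
property = "IT"      # IT | ST | density
exp_mean = 30.6      # mN/m or g/cm^3
ci95 = 2.4
scale = 0.040
obs_key = "tension"
```

## Conventions and units

Distances nm, energies kJ/mol (PMFs reported in kcal/mol), charges in e,
pressures bar, tensions mN/m (1 bar·nm = 0.1 mN/m), dipoles Debye
(1 e·Å ≈ 4.8032 D), temperature default 298.15 K. PMFs are anchored at
their minimum; bins with zero density are masked, not zero. Flip-flop
barriers default to the midplane-minus-minimum convention.
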