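# episkin

A multiscale cell-centre model of desquamation in the interfollicular
epidermis. A per-cell mass-action model of adhesion-protein degradation —
a corneodesmosome-cleaving protease, its inhibitor, and a vertical pH
gradient regulating their interaction — is coupled to a 3D
overlapping-spheres tissue simulation on a laterally periodic box. Surface
cells feel a constant vertical removal force; cells (and clumps of cells)
that lose contact with the main tissue body desquamate. The balance of
basal stem-cell proliferation against chemistry-gated removal produces a
homeostatic corneum thickness, and reducing the inhibitor pool (the
disease scenario) thins the tissue.

## Layout

- `src/episkin/kinetics.py` — pH profile, pH-dependent rate constants, the
  six-species dimensionless ODE system, quasi-equilibrium initial
  conditions, time-rescaled rates for the tissue clock, a
  single-migrating-cell solver, a vectorised implicit integrator for the
  tissue, and concentration-estimation utilities.
- `src/episkin/mechanics.py` — overlapping-spheres forces (exponential
  adhesion + logarithmic repulsion), division rotational force, basal
  membrane interaction, proliferation lineage, overdamped updates.
- `src/episkin/desquamation.py` — surface-cell grid, removal force,
  main-body connectivity, culling of detached cells.
- `src/episkin/coupling.py` — the per-step bridge (height → pH → rates →
  per-cell chemistry → adhesion scaling → mechanics → removal), tissue
  initialisation and realisation runner.
- `src/episkin/experiments.py` — steady-state thickness, velocity/turnover
  statistics, free-enzyme totals, inhibitor and recovery sweeps with
  linear/quadratic fits.
- `src/episkin/io_cli/` — YAML configuration, CSV/JSON writers, test
  fixtures, and the `episkin` command-line interface.

Units: lengths in cell diameters (CD), times in hours, forces in uN,
concentrations in molar. The drag coefficient is quoted per micrometre
(0.1 uN.hr/um); one CD corresponds to 100 um, which reproduces the
documented ~1.4-hr free removal time under the 5-uN removal force.

## CLI

```sh
# subcellular model for one migrating cell
episkin single-cell --v-xi 0.05 --duration 480 --e-t 1e-10 --i-t 1e-10 --out traj.csv

# coupled tissue simulation (YAML config optional; defaults mirror the
# published parameter table)
episkin run --seed 1 --realisations 2 --outdir results/

# scenario sweeps and summary statistics
episkin sweep-inhibitor --fractions 0,0.5,1 --outdir results/
episkin sweep-recovery --fractions 0,0.5,1 --outdir results/
episkin analyze --seed 1

# deterministic toy states
episkin fixtures mini-tissue --seed 0 --out fixture.csv
```

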