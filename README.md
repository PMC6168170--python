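# tslandscape

Transition-state analysis of cell-differentiation dynamics: stochastic
simulation, probabilistic (Waddington-style) landscapes, fixed-point
classification and parameter sweeps, and Freidlin–Wentzell minimum-action
transition paths.

Two model systems are implemented end to end:

* **Toy system** — a 2-D bistable SDE whose drift decomposes exactly into the
  negative gradient of a quartic double-well potential plus an orthogonal
  "curl" component of strength `c`, with isotropic noise `sigma`.
* **Developmental network** — a four-species birth–death network
  (Nanog `N`, Oct4-Sox2 `O`, Fgf4 `F`, Gata6 `G`) with Hill-type production
  propensities and first-order degradation, driven by an external LIF
  concentration `L`. It is simulated exactly (Gillespie SSA) and through its
  chemical-Langevin approximation.

## Layout

| module | contents |
| --- | --- |
| `tslandscape.models` | potentials, drifts, propensities, stoichiometry, noise covariance, packaged parameter sets |
| `tslandscape.simulate` | Euler–Maruyama, Gillespie SSA, chemical Langevin, parameter ramps, seeded ensembles, box sampling |
| `tslandscape.landscape` | histogram densities, `-ln P` potentials, marginals, mode detection, ensemble variance time-series |
| `tslandscape.fixedpoints` | multistart root finding, symbolic/finite-difference Jacobians, stability classification, branch-tracked parameter sweeps |
| `tslandscape.action` | discretized Freidlin–Wentzell action with exact gradients, minimum-action-path optimization, reference uphill paths, path comparison |
| `tslandscape.experiments` | one recipe per figure-level analysis (`fig1_landscape` … `fig8_dev_transitory`), output bundles, test fixtures |
| `tslandscape.cli` | the `tslandscape` command-line interface |
| `tslandscape.io` | CSV/HDF5 serialization of trajectories, ensembles, grids and paths |

## Parameter sets

Two parameter sets for the developmental network ship with the package
(`tslandscape/params/`):

* `paper-printed` — the literal parse of the published rate table. This set
  is structurally monostable (only the Gata6-high state exists) and is
  retained for provenance.
* `calibrated` — the repository default. Derived from the printed set by a
  structural calibration (documented in the YAML header) that enforces the
  reported fixed-point picture: a stable stem-cell state at N ≈ 60–100 whose
  Nanog level and stability grow with `L`, an always-unstable low-N/low-G
  transition saddle whose positive eigenvalue grows with `L`, and an
  L-independent differentiated state at high Gata6.

Both are selectable everywhere via `--param-set` / `param_set=`.

## CLI

```sh
tslandscape recipe fig7_L_sweep --scale desk --seed 1 --out out/fig7
tslandscape recipe fig8_dev_transitory --scale desk --out out/fig8
tslandscape map --model toy --from well+ --to well- --seed 1 --out out/map
tslandscape fixedpoints --model dev -L 50
tslandscape sweep --values 0,50,100,150,200 --out out/sweep
tslandscape simulate --model dev-ssa --t-end 500 -L 0 --out out/sim
tslandscape fixtures --seed 0 --out fixtures/
```

`tslandscape recipe --help` lists all eight recipes. Every recipe runs at
`--scale desk` (reduced ensembles, minutes) or `--scale full` (published
ensemble sizes). Stochastic summary checks at desk scale use widened
Monte-Carlo tolerances.

## Reproducibility

Every ensemble member `i` derives its RNG stream from
`SeedSequence(entropy=base_seed, spawn_key=(i,))`; batched and per-member
execution paths are bit-identical, and recipes re-run with the same seed
reproduce deterministic outputs byte-for-byte.
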