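"""Named end-to-end recipes reproducing each figure-level analysis.

Every recipe runs at ``full`` scale (the published ensemble sizes) and at a
reduced ``desk`` scale used by the test-suite and the acceptance script;
desk-scale Monte-Carlo checks use correspondingly widened tolerances.
Outputs are bundled into a directory with a provenance record (package
version, config hash, seeds) sufficient to re-run the recipe.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from tslandscape import io as tsio
from tslandscape import landscape as tsl
from tslandscape.action import (
    dev_sde_model,
    minimize_action,
    path_separation,
    point_to_polyline_distance,
    toy_sde_model,
    toy_uphill_reference_path,
    DiscretizedPath,
)
from tslandscape.fixedpoints import (
    dev_fixed_points,
    dev_L_sweep,
    find_fixed_points,
    sweep_to_frame,
)
from tslandscape.models import (
    DEV_LABELS,
    TOY_LABELS,
    DevParams,
    ToyParams,
    dev_network,
    load_params,
    toy_drift,
    toy_fixed_x1_roots,
)
from tslandscape.simulate import (
    Ensemble,
    ParameterSchedule,
    SimConfig,
    cle_ensemble,
    euler_maruyama,
    run_ensemble,
    sample_box,
    ssa_gillespie,
    toy_em_drift,
    toy_ensemble,
)

__all__ = ["RECIPES", "ExperimentRecipe", "OutputBundle", "run_recipe", "make_fixtures",
           "STEM_BOX", "dev_branch_states"]

#: initial-condition box for stem-like cells, order (N, O, F, G)
STEM_BOX = ((60.0, 100.0), (0.0, 12.0), (90.0, 130.0), (0.0, 16.0))

#: inferred sampling boxes for the plateau experiments (flagged in the docs)
PLATEAU_HIGH_N = ((60.0, 100.0), (60.0, 100.0), (10.0, 50.0), (60.0, 100.0))
PLATEAU_LOW_N = ((20.0, 50.0), (60.0, 100.0), (60.0, 100.0), (60.0, 100.0))


@dataclass(frozen=True)
class ExperimentRecipe:
    """A named, config-driven figure-level experiment."""

    recipe_id: str
    runner: Callable
    description: str


@dataclass
class OutputBundle:
    """Provenance + file inventory + summary statistics of one recipe run."""

    outdir: Path
    provenance: dict
    files: list
    summary: dict

    def write(self) -> None:
        self.outdir.mkdir(parents=True, exist_ok=True)
        tsio.write_json(self.provenance, self.outdir / "provenance.json")
        tsio.write_json(self.summary, self.outdir / "summary.json")


def _dev_params(param_set: str) -> DevParams:
    return load_params(param_set)


def dev_branch_states(params: DevParams, seed: int = 0) -> dict:
    """Stem / transition / differentiated fixed points at the params' L."""
    fps = dev_fixed_points(params, n_starts=120, seed=seed)
    stable = [fp for fp in fps if fp.classification == "stable"]
    saddles = [fp for fp in fps if fp.classification == "saddle"]
    out = {}
    if stable:
        stem = max(stable, key=lambda fp: fp.location[0])
        diff = max(stable, key=lambda fp: fp.location[3])
        if stem is not diff:
            out["stem-cell"] = stem
            out["differentiated"] = diff
    if saddles:
        out["transition"] = min(saddles, key=lambda fp: fp.location[0] + fp.location[3])
    return out


# --------------------------------------------------------------------------
# Toy-model recipes
# --------------------------------------------------------------------------

def _toy_stationary_samples(params, n_members, t_end, base_seed, dt=2e-3,
                            record=0.05, burn_in=10.0):
    cfg = SimConfig(t_end=t_end, dt=dt, record_interval=record, seed=0)
    x0 = np.array([1.0, 0.0])
    ens = toy_ensemble(params, x0, None, cfg, n=n_members, base_seed=base_seed,
                       burn_in=burn_in)
    return ens


def rcp_fig1_landscape(outdir, scale, seed, param_set, ov):
    params = load_params("toy-default")
    n = ov.get("n_members", 60 if scale == "desk" else 200)
    t_end = ov.get("t_end", 400.0 if scale == "desk" else 1000.0)
    ens = _toy_stationary_samples(params, n, t_end, seed)
    bins = ov.get("bins", 21)
    grid = tsl.histogram_density(ens, TOY_LABELS, bins=bins,
                                 ranges=[(-2.1, 2.1), (-2.1, 2.1)])
    modes = tsl.find_modes(grid)
    files = [tsio.write_json(modes, outdir / "modes.json"),
             (outdir / "landscape.csv")]
    grid.to_frame().to_csv(outdir / "landscape.csv", index=False)

    model = toy_sde_model(params)
    roots = toy_fixed_x1_roots(params)
    lo, mid, hi = roots
    fwd = minimize_action(model, [hi, 0.0], [lo, 0.0], M=80,
                          T_grid=(10.0, 20.0, 40.0), seed=seed)
    rev = minimize_action(model, [lo, 0.0], [hi, 0.0], M=80,
                          T_grid=(10.0, 20.0, 40.0), seed=seed)
    files.append(tsio.path_to_csv(fwd.path, outdir / "map_forward.csv",
                                  {"action": fwd.action}))
    files.append(tsio.path_to_csv(rev.path, outdir / "map_reverse.csv",
                                  {"action": rev.action}))
    summary = {
        "n_modes": len(modes),
        "mode_locations": [m["location"] for m in modes[:2]],
        "action_forward": fwd.action,
        "action_reverse": rev.action,
    }
    return files, summary


def rcp_fig2_saddle_escape(outdir, scale, seed, param_set, ov):
    base = load_params("toy-default")
    n = ov.get("n_members", 20 if scale == "desk" else 100)
    rows = []
    summary = {}
    files = []
    for alpha in (0.4, 1.6):
        # alpha/lam held at the default ratio 2
        params = base.replace(alpha=alpha, lam=alpha / 2.0)
        cfg = SimConfig(t_end=8.0, dt=1e-3, record_interval=0.02, seed=0)
        ens = toy_ensemble(params, np.zeros(2), None, cfg, n=n,
                           base_seed=seed + int(10 * alpha))
        for i in range(min(n, 10)):
            df = pd.DataFrame(ens.states[i], columns=list(TOY_LABELS))
            df.insert(0, "time", ens.times)
            df.insert(0, "member", i)
            df.insert(0, "alpha", alpha)
            rows.append(df)
        summary[f"positive_eigenvalue_alpha_{alpha}"] = 2.0 * alpha
        summary[f"final_abs_x1_mean_alpha_{alpha}"] = float(
            np.abs(ens.states[:, -1, 0]).mean())
    pd.concat(rows).to_csv(outdir / "trajectories.csv", index=False)
    files.append(outdir / "trajectories.csv")
    return files, summary


def toy_transitory_ensemble(n=500, base_seed=0, t_end=8.0, dt=1e-3,
                            record=0.02, burn_in=3.0) -> Ensemble:
    """The beta-ramp ensemble: beta = t - 0.5 on [0, 1], then held at 0.5.

    The ensemble is equilibrated at beta = -0.5 for ``burn_in`` time units
    before the ramp and followed to ``t_end`` so that it re-equilibrates in
    the single remaining well.
    """
    params = load_params("toy-default")
    sched = ParameterSchedule.linear("beta", -0.5, 0.5, 1.0)
    cfg = SimConfig(t_end=t_end, dt=dt, record_interval=record, seed=0)
    x1s = toy_fixed_x1_roots(params.replace(beta=-0.5))
    x0 = np.array([float(x1s.max()), 0.0])
    return toy_ensemble(params, x0, sched, cfg, n=n, base_seed=base_seed,
                        burn_in=burn_in)


def rcp_fig3_toy_transitory(outdir, scale, seed, param_set, ov):
    n = ov.get("n_members", 500 if scale == "desk" else 5000)
    ens = toy_transitory_ensemble(n=n, base_seed=seed)
    var = tsl.variance_timeseries(ens)
    var.to_csv(outdir / "variance.csv", index=False)
    files = [outdir / "variance.csv"]

    params = load_params("toy-default")
    marg_rows = []
    for beta in (-0.5, 0.0, 0.5):
        stat = _toy_stationary_samples(params.replace(beta=beta), 30, 80.0,
                                       seed + int(10 * (beta + 1)))
        m = tsl.marginalize(stat, "x1", bins=60, ranges=(-2.0, 2.0))
        df = m.to_frame()
        df.insert(0, "beta", beta)
        df["n_modes"] = len(tsl.find_modes(m))
        marg_rows.append(df)
    pd.concat(marg_rows).to_csv(outdir / "marginals.csv", index=False)
    files.append(outdir / "marginals.csv")

    v1 = var["var_x1"].to_numpy()
    v2 = var["var_x2"].to_numpy()
    summary = {
        "var_x1_start": float(v1[0]), "var_x1_max": float(v1.max()),
        "var_x1_end": float(v1[-1]),
        "var_x1_peak_time": float(var["time"][int(np.argmax(v1))]),
        "interior_peak": bool(v1.max() > v1[0] and v1.max() > v1[-1]),
        "var_x2_ratio": float(v2.max() / v2.min()),
    }
    return files, summary


# --------------------------------------------------------------------------
# Developmental-model recipes
# --------------------------------------------------------------------------

def _ssa_runner(params):
    net = dev_network(params)

    def run_one(x0, schedule, cfg):
        return ssa_gillespie(net, x0, schedule, cfg)

    return run_one


def dev_landscape_ensemble(params, n, t_end, base_seed, record=None) -> Ensemble:
    """SSA ensemble from the stem box used for the static-landscape estimate."""
    record = record or t_end
    cfg = SimConfig(t_end=t_end, dt=min(1.0, record), record_interval=record, seed=0)
    x0 = lambda rng, m: sample_box(STEM_BOX, m, rng, integer=True)
    return run_ensemble(_ssa_runner(params), x0, None, cfg, n=n,
                        base_seed=base_seed, model_id="dev")


def rcp_fig4_dev_landscape(outdir, scale, seed, param_set, ov):
    params = _dev_params(param_set).replace(L=50.0)
    n = ov.get("n_members", 600 if scale == "desk" else 5000)
    t_end = ov.get("t_end", 600.0 if scale == "desk" else 1000.0)
    ens = dev_landscape_ensemble(params, n, t_end, seed)
    finals = ens.states[:, -1, :]
    df = pd.DataFrame(finals, columns=list(DEV_LABELS))
    df.to_csv(outdir / "final_states.csv", index=False)
    # Gata6 on the x-axis, Nanog on the y-axis as in the published landscape
    grid = tsl.histogram_density(finals[:, [3, 0]], ("G", "N"),
                                 bins=ov.get("bins", (13, 12)),
                                 ranges=[(0.0, 130.0), (0.0, 120.0)])
    grid.to_frame().to_csv(outdir / "landscape.csv", index=False)
    modes = tsl.find_modes(grid, min_mass=0.01)
    summary = {
        "n_modes": len(modes),
        "mode_locations": [m["location"] for m in modes[:3]],
        "fraction_differentiated": float((finals[:, 3] > 50).mean()),
    }
    files = [outdir / "final_states.csv", outdir / "landscape.csv",
             tsio.write_json(modes, outdir / "modes.json")]
    return files, summary


def rcp_fig5_differentiation_paths(outdir, scale, seed, param_set, ov):
    params = _dev_params(param_set)
    k = ov.get("n_tracked", 5 if scale == "desk" else 20)
    n_rev = ov.get("n_reverse", 200)
    t_end = ov.get("t_end", 1500.0 if scale == "desk" else 3000.0)
    cfg = SimConfig(t_end=t_end, dt=1.0, record_interval=10.0, seed=0)
    branches = dev_branch_states(params.replace(L=50.0), seed=seed)
    files = []
    summary = {}

    def save(tag, ens):
        frames = []
        for i in range(ens.n_members if tag == "B" else min(ens.n_members, k)):
            df = pd.DataFrame(ens.states[i], columns=list(DEV_LABELS))
            df.insert(0, "time", ens.times)
            df.insert(0, "cell", i)
            frames.append(df)
        p = outdir / f"trajectories_{tag}.csv"
        pd.concat(frames).to_csv(p, index=False)
        files.append(p)

    # A: stem-box cells, LIF withdrawn (L = 0)
    run = _ssa_runner(params.replace(L=0.0))
    x0 = lambda rng, m: sample_box(STEM_BOX, m, rng, integer=True)
    ens = run_ensemble(run, x0, None, cfg, n=k, base_seed=seed)
    save("A", ens)
    summary["A_fraction_differentiated"] = float((ens.states[:, -1, 3] > 50).mean())

    # B: differentiated cells put back into L = 200
    run = _ssa_runner(params.replace(L=200.0))
    x0_diff = np.round(branches["differentiated"].location)
    ens = run_ensemble(run, x0_diff, None, cfg, n=n_rev, base_seed=seed + 1)
    save("B", ens)
    summary["B_fraction_regained_stem"] = float(
        ((ens.states[:, -1, 0] > 40) & (ens.states[:, -1, 3] < 20)).mean())

    # C / D: plateau regions, L = 0
    run = _ssa_runner(params.replace(L=0.0))
    for tag, box in (("C", PLATEAU_HIGH_N), ("D", PLATEAU_LOW_N)):
        x0 = lambda rng, m, box=box: sample_box(box, m, rng, integer=True)
        ens = run_ensemble(run, x0, None, cfg, n=k, base_seed=seed + ord(tag))
        save(tag, ens)
        summary[f"{tag}_fraction_differentiated"] = float(
            (ens.states[:, -1, 3] > 50).mean())

    # E: cells released at the transition state, L = 50
    run = _ssa_runner(params.replace(L=50.0))
    trans = branches["transition"].location
    amp = ov.get("transition_jitter", 2.0)

    def x0_trans(rng, m):
        pts = trans[None, :] + rng.normal(scale=amp, size=(m, 4))
        return np.clip(np.round(pts), 0, None)

    ens = run_ensemble(run, x0_trans, None, cfg, n=max(k, 10), base_seed=seed + 5)
    save("E", ens)
    finals = ens.states[:, -1, :]
    summary["E_fraction_differentiated"] = float((finals[:, 3] > 50).mean())
    summary["E_fraction_stem"] = float((finals[:, 0] > 40).mean())
    return files, summary


def rcp_fig6_maps(outdir, scale, seed, param_set, ov):
    params = _dev_params(param_set).replace(L=50.0)
    branches = dev_branch_states(params, seed=seed)
    stem = branches["stem-cell"].location
    diff = branches["differentiated"].location
    trans = branches["transition"].location
    model = dev_sde_model(params)
    M = ov.get("M", 80 if scale == "desk" else 160)
    T_grid = ov.get("T_grid", (600.0, 1200.0, 2400.0))
    maxiter = ov.get("maxiter", 6000)
    fwd = minimize_action(model, stem, diff, M=M, T_grid=T_grid, via=trans,
                          seed=seed, nonnegative=True, maxiter=maxiter)
    rev = minimize_action(model, diff, stem, M=M, T_grid=T_grid, via=trans,
                          seed=seed + 1, nonnegative=True, maxiter=maxiter)
    files = [
        tsio.path_to_csv(fwd.path, outdir / "map_forward.csv",
                         {"action": fwd.action, "converged": fwd.converged}),
        tsio.path_to_csv(rev.path, outdir / "map_reverse.csv",
                         {"action": rev.action, "converged": rev.converged}),
    ]
    sep = path_separation(fwd.path, rev.path)
    d_fwd = float(np.linalg.norm(fwd.path.states - trans, axis=1).min())
    d_rev = float(np.linalg.norm(rev.path.states - trans, axis=1).min())
    summary = {
        "action_forward": fwd.action, "action_reverse": rev.action,
        "path_separation": sep,
        "forward_min_distance_to_transition": d_fwd,
        "reverse_min_distance_to_transition": d_rev,
    }
    return files, summary


def rcp_fig7_L_sweep(outdir, scale, seed, param_set, ov):
    params = _dev_params(param_set)
    if "L_values" in ov:
        Ls = np.asarray(ov["L_values"], dtype=float)
    else:
        Ls = np.arange(0.0, 201.0, 25.0 if scale == "desk" else 10.0)
    branches = dev_L_sweep(params, Ls, seed=seed)
    df = sweep_to_frame(branches)
    df.to_csv(outdir / "sweep.csv", index=False)
    named = {k: v for k, v in branches.items()
             if k in ("stem-cell", "transition", "differentiated")}
    summary = {
        "n_branches": len(named),
        "L_values": list(map(float, Ls)),
    }
    for name, fps in named.items():
        summary[f"{name}_n_points"] = len(fps)
        summary[f"{name}_max_re_eigenvalues"] = [fp.max_real_eigenvalue for fp in fps]
    if "stem-cell" in named:
        summary["stem_nanog"] = [float(fp.location[0]) for fp in named["stem-cell"]]
    return [outdir / "sweep.csv"], summary


def dev_transitory_ensemble(params, n=1000, base_seed=0, T_ramp=1500.0,
                            t_end=3000.0, record=25.0) -> Ensemble:
    """The LIF-withdrawal ensemble: L = 150 (1 - t/T_ramp), held at 0 after.

    Starts at the stem-cell fixed point for L = 150.  The published formula
    corresponds to T_ramp = 1; the repository default stretches the ramp so
    it is slow relative to the relaxation time 1/kd (both are configurable).
    """
    p150 = params.replace(L=150.0)
    branches = dev_branch_states(p150)
    x0 = np.round(branches["stem-cell"].location)
    sched = ParameterSchedule.linear("L", 150.0, 0.0, T_ramp)
    cfg = SimConfig(t_end=t_end, dt=1.0, record_interval=record, seed=0)
    return run_ensemble(_ssa_runner(params), x0, sched, cfg, n=n,
                        base_seed=base_seed, model_id="dev")


def rcp_fig8_dev_transitory(outdir, scale, seed, param_set, ov):
    params = _dev_params(param_set)
    n = ov.get("n_members", 300 if scale == "desk" else 10000)
    T_ramp = ov.get("T_ramp", 1500.0)
    t_end = ov.get("t_end", 3000.0)
    ens = dev_transitory_ensemble(params, n=n, base_seed=seed, T_ramp=T_ramp,
                                  t_end=t_end)
    var = tsl.variance_timeseries(ens)
    var.to_csv(outdir / "variance.csv", index=False)
    summary = {}
    for lab in ("N", "G"):
        v = var[f"var_{lab}"].to_numpy()
        summary[f"var_{lab}_start"] = float(v[0])
        summary[f"var_{lab}_max"] = float(v.max())
        summary[f"var_{lab}_end"] = float(v[-1])
        summary[f"var_{lab}_interior_peak"] = bool(
            v.max() > v[0] and v.max() > v[-1])
    summary["fraction_differentiated_end"] = float(
        (ens.states[:, -1, 3] > 50).mean())
    return [outdir / "variance.csv"], summary


RECIPES = {
    "fig1_landscape": ExperimentRecipe(
        "fig1_landscape", rcp_fig1_landscape,
        "Toy stationary histogram, modes and forward/reverse MAPs"),
    "fig2_saddle_escape": ExperimentRecipe(
        "fig2_saddle_escape", rcp_fig2_saddle_escape,
        "Trajectories leaving the toy saddle for small/large positive eigenvalue"),
    "fig3_toy_transitory": ExperimentRecipe(
        "fig3_toy_transitory", rcp_fig3_toy_transitory,
        "Toy beta-ramp ensemble variance and stationary marginals"),
    "fig4_dev_landscape": ExperimentRecipe(
        "fig4_dev_landscape", rcp_fig4_dev_landscape,
        "Developmental probabilistic landscape at L = 50"),
    "fig5_differentiation_paths": ExperimentRecipe(
        "fig5_differentiation_paths", rcp_fig5_differentiation_paths,
        "Differentiation / reprogramming / plateau trajectory experiments"),
    "fig6_maps": ExperimentRecipe(
        "fig6_maps", rcp_fig6_maps,
        "Forward and reverse minimum action paths of the developmental model"),
    "fig7_L_sweep": ExperimentRecipe(
        "fig7_L_sweep", rcp_fig7_L_sweep,
        "Branch-tracked fixed points and eigenvalues over LIF concentration"),
    "fig8_dev_transitory": ExperimentRecipe(
        "fig8_dev_transitory", rcp_fig8_dev_transitory,
        "Developmental LIF-ramp ensemble variance"),
}


def run_recipe(recipe_id: str, outdir, scale: str = "desk", seed: int = 0,
               param_set: str = "calibrated", overrides: Optional[dict] = None
               ) -> OutputBundle:
    """Execute a named recipe and write its output bundle."""
    if recipe_id not in RECIPES:
        raise KeyError(
            f"unknown recipe {recipe_id!r}; choose from {sorted(RECIPES)}")
    if scale not in ("desk", "full"):
        raise ValueError("scale must be 'desk' or 'full'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ov = dict(overrides or {})
    files, summary = RECIPES[recipe_id].runner(outdir, scale, seed, param_set, ov)
    config = {"recipe": recipe_id, "scale": scale, "seed": seed,
              "param_set": param_set, "overrides": ov}
    from tslandscape import __version__ as _pkg_version

    bundle = OutputBundle(
        outdir=outdir,
        provenance={
            "package_version": _pkg_version,
            "config": config,
            "config_hash": tsio.config_hash(config),
        },
        files=[str(f) for f in files],
        summary=summary,
    )
    bundle.write()
    return bundle


def make_fixtures(outdir, seed: int = 0) -> list:
    """Generate the small deterministic datasets used by the test-suite."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = load_params("toy-default")
    files = []

    cfg = SimConfig(t_end=2.0, dt=1e-3, record_interval=0.01, seed=seed)
    traj = euler_maruyama(toy_em_drift(params), params.sigma, [1.0, 0.0], None, cfg)
    files.append(tsio.trajectory_to_csv(traj, outdir / "toy_trajectory.csv"))

    cfg = SimConfig(t_end=1.0, dt=1e-3, record_interval=0.05, seed=0)
    ens = toy_ensemble(params, [1.0, 0.0], None, cfg, n=20, base_seed=seed)
    files.append(tsio.ensemble_to_hdf5(ens, outdir / "toy_ensemble.h5"))

    dev = load_params("calibrated")
    cfg = SimConfig(t_end=50.0, dt=1.0, record_interval=1.0, seed=seed)
    run = ssa_gillespie(dev_network(dev), [70, 6, 111, 1], None, cfg)
    files.append(tsio.trajectory_to_csv(run, outdir / "ssa_small.csv"))

    line = DiscretizedPath(
        np.linspace([1.0, 0.0], [-1.0, 0.0], 10), duration=10.0,
        labels=TOY_LABELS)
    files.append(tsio.path_to_csv(line, outdir / "path_small.csv"))
    return files
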