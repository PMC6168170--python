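"""Fixed-point location, Jacobian eigenanalysis and parameter sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import sympy as sp
from scipy.optimize import root as scipy_root
from scipy.stats import qmc

from tslandscape.models import DEV_LABELS, DevParams, dev_drift, dev_drift_sympy

__all__ = [
    "FixedPoint",
    "find_fixed_points",
    "jacobian_at",
    "lambdify_jacobian",
    "classify_fixed_point",
    "marginal_directions",
    "sweep_parameter",
    "toy_critical_points",
    "dev_L_sweep",
    "dev_fixed_points",
    "label_dev_branches",
    "sweep_to_frame",
]

#: |Re(eigenvalue)| below this counts as a marginal direction
MARGINAL_TOL = 1e-8


@dataclass
class FixedPoint:
    """A root of the drift with its local linearization."""

    location: np.ndarray
    labels: tuple
    eigenvalues: np.ndarray
    classification: str
    residual_norm: float
    context: dict = field(default_factory=dict)
    branch: str = "unlabeled"

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=complex)

    @property
    def max_real_eigenvalue(self) -> float:
        return float(self.eigenvalues.real.max())

    @property
    def n_marginal(self) -> int:
        return marginal_directions(self.eigenvalues)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        loc = ", ".join(f"{l}={v:.4g}" for l, v in zip(self.labels, self.location))
        return f"FixedPoint({loc}; {self.classification}; maxRe={self.max_real_eigenvalue:.3g})"


def classify_fixed_point(eigenvalues, tol: float = MARGINAL_TOL) -> str:
    """``stable`` (all Re < -tol), ``saddle`` (any Re > tol), else ``marginal``."""
    ev = np.asarray(eigenvalues, dtype=complex)
    if ev.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    re = ev.real
    if np.any(re > tol):
        return "saddle"
    if np.all(re < -tol):
        return "stable"
    return "marginal"


def marginal_directions(eigenvalues, tol: float = MARGINAL_TOL) -> int:
    """Number of eigenvalues with |Re| <= tol."""
    re = np.asarray(eigenvalues, dtype=complex).real
    return int(np.sum(np.abs(re) <= tol))


def lambdify_jacobian(drift_sympy):
    """Compile the symbolic Jacobian of a (Matrix, symbols) drift pair."""
    f, syms = drift_sympy
    J = f.jacobian(sp.Matrix(syms))
    fn = sp.lambdify(syms, J, modules="numpy")

    def jac(x):
        return np.asarray(fn(*np.asarray(x, dtype=float)), dtype=float)

    return jac


def jacobian_at(
    drift,
    point,
    method: str = "central-difference",
    step: float = 1e-6,
    drift_sympy=None,
) -> np.ndarray:
    """Jacobian of the drift at ``point``.

    ``method="symbolic"`` differentiates the provided sympy drift exactly;
    ``method="central-difference"`` uses step ``step * (1 + |x_j|)`` per
    coordinate.
    """
    x = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite evaluation point {x}")
    if method == "symbolic":
        if drift_sympy is None:
            raise ValueError("symbolic Jacobian requires drift_sympy=(Matrix, symbols)")
        J = lambdify_jacobian(drift_sympy)(x)
    elif method == "central-difference":
        d = x.size
        J = np.empty((d, d))
        for j in range(d):
            h = step * (1.0 + abs(x[j]))
            e = np.zeros(d)
            e[j] = h
            J[:, j] = (np.asarray(drift(x + e)) - np.asarray(drift(x - e))) / (2 * h)
    else:
        raise ValueError(f"unknown Jacobian method {method!r}")
    if not np.all(np.isfinite(J)):
        raise FloatingPointError(f"non-finite Jacobian at {x}")
    return J


def find_fixed_points(
    drift: Callable,
    box: Sequence,
    n_starts: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    jac: Optional[Callable] = None,
    nonnegative: bool = False,
    extra_starts=None,
    dedup_radius: float = 1e-4,
) -> list:
    """Multistart root finding for ``drift(x) = 0`` inside an axis-aligned box.

    Starts are a seeded Latin-hypercube over ``box`` (list of (low, high)
    pairs) plus any ``extra_starts``.  Roots are deduplicated with radius
    ``dedup_radius * (1 + |x|)`` and re-validated against the drift; an empty
    list (not an exception) is returned when nothing converges.

    With ``nonnegative=True`` the solver works on ``drift(|x|)`` so searches
    may cross zero without leaving the model's domain; reported roots are the
    folded non-negative representatives.
    """
    box = [tuple(map(float, b)) for b in box]
    d = len(box)
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    if np.any(lo > hi):
        raise ValueError("invalid search box")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    starts = qmc.scale(sampler.random(max(n_starts, 1)), lo, hi)
    if extra_starts is not None:
        starts = np.vstack([np.asarray(extra_starts, dtype=float).reshape(-1, d), starts])

    if nonnegative:
        def objective(x):
            return np.asarray(drift(np.abs(x)), dtype=float)
    else:
        def objective(x):
            return np.asarray(drift(x), dtype=float)

    found = []
    for x0 in starts:
        sol = scipy_root(objective, x0, method="hybr")
        x = np.abs(sol.x) if nonnegative else sol.x
        res = float(np.linalg.norm(np.asarray(drift(x), dtype=float)))
        if not sol.success or res >= tol:
            # hybr struggles when the Jacobian is singular at the root
            # (e.g. the quartic model's flat transverse direction); retry
            # with Levenberg-Marquardt before giving up on this start.
            sol = scipy_root(objective, x0, method="lm")
            x = np.abs(sol.x) if nonnegative else sol.x
            res = float(np.linalg.norm(np.asarray(drift(x), dtype=float)))
        if res >= tol:
            continue
        margin = 0.05 * (hi - lo)
        if np.any(x < lo - margin) or np.any(x > hi + margin):
            continue  # converged to a root outside the requested box
        scale = 1.0 + np.linalg.norm(x)
        if any(np.linalg.norm(x - y) < dedup_radius * scale for y in found):
            continue
        found.append(x)

    fps = []
    for x in found:
        J = jac(x) if jac is not None else jacobian_at(drift, x)
        ev = np.linalg.eigvals(J)
        fps.append(
            FixedPoint(
                location=x,
                labels=tuple(f"x{i+1}" for i in range(d)),
                eigenvalues=ev,
                classification=classify_fixed_point(ev),
                residual_norm=float(np.linalg.norm(np.asarray(drift(x), dtype=float))),
            )
        )
    fps.sort(key=lambda fp: tuple(fp.location))
    return fps


def toy_critical_points(params=None) -> list:
    """Critical points of the quartic double-well potential, classified.

    All critical points lie on the x2 = 0 axis (the potential is an even
    quartic in x2, so the transverse direction is always a strict minimum
    direction even though its second derivative vanishes there).  The
    in-axis Hessian entry ``12 lam x1^2 - 2 alpha`` therefore decides the
    type: positive -> local minimum, negative -> saddle.

    Returns dicts with ``location``, ``type`` and ``hessian_x1x1``.
    """
    from tslandscape.models import ToyParams, toy_fixed_x1_roots

    params = params or ToyParams()
    out = []
    for x1 in toy_fixed_x1_roots(params):
        h11 = 12 * params.lam * x1**2 - 2 * params.alpha
        kind = "minimum" if h11 > 0 else ("saddle" if h11 < 0 else "degenerate")
        out.append({
            "location": (float(x1), 0.0),
            "type": kind,
            "hessian_x1x1": float(h11),
        })
    return out


# --------------------------------------------------------------------------
# Parameter sweeps with branch tracking
# --------------------------------------------------------------------------

def sweep_parameter(
    drift_factory: Callable[[float], Callable],
    parameter: str,
    values: Sequence[float],
    box: Sequence,
    n_starts: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
    jac_factory: Optional[Callable[[float], Callable]] = None,
    nonnegative: bool = False,
    jump_tol: float = 25.0,
    labels: Optional[tuple] = None,
) -> dict:
    """Locate fixed points at each parameter value and track branches.

    Branches are matched by nearest neighbour in state space with jump
    threshold ``jump_tol``; unmatched points open new (numbered) branches.
    Returns ``{branch_name: [FixedPoint, ...]}`` where each fixed point
    carries ``{parameter: value}`` in its context.  Branch disappearance is
    recorded by the branch simply lacking an entry at that value.
    """
    if len(values) < 2:
        raise ValueError("a sweep needs at least two parameter values")
    branches: dict = {}
    prev_points: list = []  # (branch_name, location)
    counter = 0
    for v in values:
        drift = drift_factory(v)
        jac = jac_factory(v) if jac_factory is not None else None
        extra = [loc for _, loc in prev_points] or None
        fps = find_fixed_points(
            drift, box, n_starts=n_starts, tol=tol, seed=seed, jac=jac,
            nonnegative=nonnegative, extra_starts=extra,
        )
        if labels is not None:
            for fp in fps:
                fp.labels = labels
        assigned = {}
        taken = set()
        for fp in fps:
            best_name, best_dist = None, np.inf
            for name, loc in prev_points:
                if name in taken:
                    continue
                dist = float(np.linalg.norm(fp.location - loc))
                if dist < best_dist:
                    best_name, best_dist = name, dist
            if best_name is not None and best_dist <= jump_tol:
                name = best_name
                taken.add(name)
            else:
                name = f"branch{counter}"
                counter += 1
            fp.branch = name
            fp.context = {parameter: float(v)}
            branches.setdefault(name, []).append(fp)
            assigned[name] = fp.location
        prev_points = [(name, loc) for name, loc in assigned.items()]
    return branches


def label_dev_branches(branches: dict) -> dict:
    """Rename developmental branches to stem-cell / transition / differentiated.

    The stable branch with the highest mean Nanog is the stem cell state, the
    stable branch with the highest mean Gata6 the differentiated state, and
    the branch that is a saddle everywhere the transition state.  Branches
    matching none of these keep their numbered names.
    """
    summary = []
    for name, fps in branches.items():
        mean_loc = np.mean([fp.location for fp in fps], axis=0)
        all_stable = all(fp.classification == "stable" for fp in fps)
        all_saddle = all(fp.classification == "saddle" for fp in fps)
        summary.append((name, mean_loc, all_stable, all_saddle))
    renames = {}
    stable = [(name, loc) for name, loc, st, sd in summary if st]
    saddles = [(name, loc) for name, loc, st, sd in summary if sd]
    if stable:
        stem = max(stable, key=lambda t: t[1][0])
        diff = max(stable, key=lambda t: t[1][3])
        if stem[0] != diff[0]:
            renames[stem[0]] = "stem-cell"
            renames[diff[0]] = "differentiated"
    if saddles:
        trans = min(saddles, key=lambda t: t[1][0] + t[1][3])
        renames[trans[0]] = "transition"
    out = {}
    for name, fps in branches.items():
        new = renames.get(name, name)
        for fp in fps:
            fp.branch = new
        out[new] = fps
    return out


def dev_fixed_points(
    params: DevParams,
    box=((0.0, 150.0),) * 4,
    n_starts: int = 200,
    tol: float = 1e-8,
    seed: int = 0,
) -> list:
    """Fixed points of the developmental model at the params' L."""

    def drift(x):
        return dev_drift(x, params)

    jac = lambdify_jacobian(dev_drift_sympy(params))
    anchors = [
        [70, 6, 1 / params.kd, 1],
        [0, 0, 1 / params.kd, 1 / params.kd],
        [40, 2, 1 / params.kd, 1],
    ]
    fps = find_fixed_points(
        drift, box, n_starts=n_starts, tol=tol, seed=seed, jac=jac,
        nonnegative=True, extra_starts=anchors,
    )
    for fp in fps:
        fp.labels = DEV_LABELS
        fp.context = {"L": params.L}
    return fps


def dev_L_sweep(
    params: DevParams,
    L_values: Sequence[float],
    n_starts: int = 120,
    seed: int = 0,
    box=((0.0, 150.0),) * 4,
) -> dict:
    """Branch-tracked fixed points of the developmental model over L."""

    def factory(L):
        p = params.replace(L=float(L))
        return lambda x: dev_drift(x, p)

    def jac_factory(L):
        return lambdify_jacobian(dev_drift_sympy(params.replace(L=float(L))))

    branches = sweep_parameter(
        factory, "L", L_values, box, n_starts=n_starts, seed=seed,
        jac_factory=jac_factory, nonnegative=True, labels=DEV_LABELS,
    )
    return label_dev_branches(branches)


def sweep_to_frame(branches: dict) -> pd.DataFrame:
    """Flatten a sweep result into a tidy table (one row per fixed point)."""
    rows = []
    for name, fps in branches.items():
        for fp in fps:
            row = dict(fp.context)
            row["branch"] = name
            for lab, v in zip(fp.labels, fp.location):
                row[lab] = v
            row["classification"] = fp.classification
            row["residual"] = fp.residual_norm
            row["max_re_eigenvalue"] = fp.max_real_eigenvalue
            for i, ev in enumerate(sorted(fp.eigenvalues, key=lambda z: -z.real)):
                row[f"eig{i}_re"] = ev.real
                row[f"eig{i}_im"] = ev.imag
            rows.append(row)
    df = pd.DataFrame(rows)
    param_col = [c for c in df.columns if c not in
                 {"branch", "classification", "residual", "max_re_eigenvalue"}][0]
    return df.sort_values(["branch", param_col]).reset_index(drop=True)
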