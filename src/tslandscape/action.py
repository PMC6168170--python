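"""Freidlin--Wentzell path actions and minimum-action transition paths.

The action of a discretized path ``phi_0..phi_K`` on a uniform time grid of
total duration ``T`` is the midpoint-rule sum

    S = (dt/2) * sum_i (v_i - f(m_i))^T A(m_i)^{-1} (v_i - f(m_i)),

with ``v_i`` the finite-difference velocity, ``m_i`` the segment midpoint,
``f`` the drift and ``A`` the diffusion matrix.  Both models used here have
diagonal ``A`` (isotropic ``sigma^2 I`` for the toy system, the birth+death
diagonal ``S diag(a) S^T`` for the network), so the quadratic form is a
weighted sum of squares and the exact gradient of the discretized action is
assembled from the drift Jacobian and the gradient of the noise diagonal,
both generated symbolically.

Minimization is quasi-Newton (L-BFGS-B) over the interior points with
endpoints pinned at the fixed points; the total duration is selected by
minimizing over a logarithmic grid of T values, since the true minimum
action path is approached in the long-T limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.optimize import minimize as scipy_minimize

from tslandscape.models import (
    DEV_LABELS,
    TOY_LABELS,
    DevParams,
    ToyParams,
    dev_drift_sympy,
    toy_decomposition,
    toy_drift,
    toy_drift_sympy,
    toy_fixed_x1_roots,
)

__all__ = [
    "DiscretizedPath",
    "ActionResult",
    "SdeModel",
    "toy_sde_model",
    "dev_sde_model",
    "fw_action",
    "minimize_action",
    "toy_uphill_reference_path",
    "path_separation",
    "resample_by_arclength",
    "point_to_polyline_distance",
]

#: minimum number of interior points in an optimizable path
MIN_INTERIOR = 8


@dataclass
class DiscretizedPath:
    """States along a transition path; uniform time grid when duration is set."""

    states: np.ndarray  # (K+1, d) including both endpoints
    duration: Optional[float] = None
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[0] < 2:
            raise ValueError("a path needs at least two states of equal dimension")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("path contains non-finite states")
        if not self.labels:
            self.labels = tuple(f"x{i+1}" for i in range(self.states.shape[1]))

    @property
    def n_segments(self) -> int:
        return self.states.shape[0] - 1

    @property
    def dt(self) -> float:
        if self.duration is None:
            raise ValueError("path has no time parametrization")
        return self.duration / self.n_segments

    @property
    def start(self) -> np.ndarray:
        return self.states[0]

    @property
    def end(self) -> np.ndarray:
        return self.states[-1]

    def arclength(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.states, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class ActionResult:
    """Outcome of a minimum-action-path optimization."""

    path: DiscretizedPath
    action: float
    iterations: int
    converged: bool
    grad_norm: float
    regularization: float
    diagnostics: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# Model adapters with symbolic derivatives
# --------------------------------------------------------------------------

def _lambdify_batch(exprs, syms):
    """Compile a flat list of sympy expressions into f(X:(n,d)) -> (n, len)."""
    fns = [sp.lambdify(syms, e, modules="numpy") for e in exprs]

    def evaluate(X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = [np.broadcast_to(np.asarray(fn(*X.T), dtype=float), X.shape[:1]) for fn in fns]
        return np.stack(cols, axis=-1)

    return evaluate


class SdeModel:
    """Drift + diagonal diffusion with symbolically generated derivatives."""

    def __init__(self, drift_exprs, noise_diag_exprs, syms, labels):
        self.labels = tuple(labels)
        self.dim = len(syms)
        self._f = _lambdify_batch(list(drift_exprs), syms)
        self._d = _lambdify_batch(list(noise_diag_exprs), syms)
        jf = [sp.diff(fk, s) for fk in drift_exprs for s in syms]
        jd = [sp.diff(dk, s) for dk in noise_diag_exprs for s in syms]
        self._jf = _lambdify_batch(jf, syms)
        self._jd = _lambdify_batch(jd, syms)

    def drift(self, X) -> np.ndarray:
        return self._f(X)

    def noise_diag(self, X) -> np.ndarray:
        return self._d(X)

    def drift_jacobian(self, X) -> np.ndarray:
        X = np.atleast_2d(X)
        return self._jf(X).reshape(X.shape[0], self.dim, self.dim)

    def noise_diag_jacobian(self, X) -> np.ndarray:
        X = np.atleast_2d(X)
        return self._jd(X).reshape(X.shape[0], self.dim, self.dim)


def toy_sde_model(params: ToyParams) -> SdeModel:
    """Toy SDE with constant isotropic diffusion sigma^2 I."""
    f, syms = toy_drift_sympy(params)
    s2 = sp.Float(params.sigma**2)
    return SdeModel(list(f), [s2, s2], syms, TOY_LABELS)


def dev_sde_model(params: DevParams) -> SdeModel:
    """Developmental chemical-Langevin SDE; diagonal diffusion a_i + a_{i+4}."""
    f, syms = dev_drift_sympy(params)
    N, O, F, G = syms
    # f_i = a_i - kd*x_i  =>  a_i + a_{i+4} = f_i + 2*kd*x_i
    diag = [sp.simplify(f[i] + 2 * params.kd * syms[i]) for i in range(4)]
    return SdeModel(list(f), diag, syms, DEV_LABELS)


# --------------------------------------------------------------------------
# Action and its gradient
# --------------------------------------------------------------------------

def _effective_noise_diag(model, mids, cond_threshold=1e8):
    """Noise diagonal with the regularization policy applied.

    Adds ``eps = 1e-6 * mean(d)`` at midpoints whose diagonal conditioning
    exceeds ``cond_threshold`` and floors the diagonal at a small positive
    value so stray negative evaluations outside the physical domain cannot
    produce a negative metric.  Returns (d_eff, mask_flat, eps_max).
    """
    d = model.noise_diag(mids)
    mean_d = np.mean(np.abs(d), axis=1, keepdims=True)
    floor = 1e-12 + 1e-9 * mean_d
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.max(np.abs(d), axis=1) / np.maximum(np.min(d, axis=1), 1e-300)
    needs = (cond > cond_threshold) | (np.min(d, axis=1) <= 0)
    eps = np.where(needs, 1e-6 * mean_d[:, 0], 0.0)[:, None]
    d_eff = np.maximum(d + eps, floor)
    clamped = d + eps < floor
    return d_eff, clamped, float(eps.max(initial=0.0))


def fw_action(
    path: DiscretizedPath,
    model: SdeModel,
    return_grad: bool = False,
):
    """Midpoint-rule Freidlin--Wentzell action of a time-parametrized path.

    With ``return_grad=True`` also returns the exact gradient of the
    discretized action with respect to the interior points, shape
    ``(K-1, d)``.
    """
    if path.duration is None:
        raise ValueError("fw_action requires a time-parametrized path")
    phi = path.states
    dt = path.dt
    mids = 0.5 * (phi[:-1] + phi[1:])
    v = np.diff(phi, axis=0) / dt
    f = model.drift(mids)
    d_eff, clamped, eps_max = _effective_noise_diag(model, mids)
    r = v - f
    w = r / d_eff
    S = 0.5 * dt * float(np.sum(r * w))
    if not np.isfinite(S):
        raise FloatingPointError("non-finite action; check path and regularization")
    if not return_grad:
        return S
    Jf = model.drift_jacobian(mids)
    Jd = model.noise_diag_jacobian(mids)
    Jd = np.where(clamped[:, :, None], 0.0, Jd)
    # dS/dphi contributions from each segment to its two endpoints
    jf_term = dt * 0.5 * np.einsum("ikl,ik->il", Jf, w)
    jd_term = 0.25 * dt * np.einsum("ik,ikl->il", (r * r) / (d_eff * d_eff), Jd)
    grad_left = -w - jf_term - jd_term   # d/dphi_i of segment i
    grad_right = w - jf_term - jd_term   # d/dphi_{i+1} of segment i
    grad = grad_left[1:] + grad_right[:-1]
    return S, grad


def action_profile(path: DiscretizedPath, model: SdeModel) -> np.ndarray:
    """Per-segment contributions to the midpoint-rule action (sums to fw_action)."""
    if path.duration is None:
        raise ValueError("action_profile requires a time-parametrized path")
    phi = path.states
    dt = path.dt
    mids = 0.5 * (phi[:-1] + phi[1:])
    v = np.diff(phi, axis=0) / dt
    f = model.drift(mids)
    d_eff, _, _ = _effective_noise_diag(model, mids)
    r = v - f
    return 0.5 * dt * np.sum(r * r / d_eff, axis=1)


def split_at_closest(path: DiscretizedPath, point) -> int:
    """Index of the path state closest to ``point`` (e.g. the saddle)."""
    point = np.asarray(point, dtype=float)
    return int(np.argmin(np.linalg.norm(path.states - point, axis=1)))


def _straight_line(a, b, n_points):
    frac = np.linspace(0.0, 1.0, n_points)[:, None]
    return a[None, :] * (1 - frac) + b[None, :] * frac


def _via_path(a, b, via, n_points):
    half = n_points // 2
    first = _straight_line(a, via, half + 1)
    second = _straight_line(via, b, n_points - half)
    return np.vstack([first[:-1], second])


def minimize_action(
    model: SdeModel,
    x_from,
    x_to,
    M: int = 100,
    T_grid: Sequence[float] = (5.0, 10.0, 20.0, 40.0, 80.0),
    via=None,
    n_starts: int = 1,
    seed: int = 0,
    maxiter: int = 2000,
    gtol_scale: float = 1e-6,
    nonnegative: bool = False,
) -> ActionResult:
    """Minimize the discretized action between two fixed points.

    ``M`` interior points; duration selected as the argmin over ``T_grid``.
    The initial path is a straight line, optionally routed through ``via``
    (e.g. the transition fixed point); additional starts (``n_starts > 1``)
    jitter the initial path with seeded noise.  With ``nonnegative=True``
    interior points are bounded below by zero (copy-number models).
    """
    x_from = np.asarray(x_from, dtype=float)
    x_to = np.asarray(x_to, dtype=float)
    if x_from.shape != x_to.shape:
        raise ValueError("endpoints must share a dimension")
    if np.allclose(x_from, x_to):
        raise ValueError("endpoints coincide; no transition to optimize")
    if M < MIN_INTERIOR:
        raise ValueError(f"need at least {MIN_INTERIOR} interior points, got {M}")
    d = x_from.size
    K = M + 1  # segments
    rng = np.random.default_rng(seed)
    scale = max(np.linalg.norm(x_to - x_from), 1.0)

    inits = []
    base = (_via_path(x_from, x_to, np.asarray(via, dtype=float), M + 2)
            if via is not None else _straight_line(x_from, x_to, M + 2))
    inits.append(base)
    for _ in range(max(0, n_starts - 1)):
        jitter = rng.normal(scale=0.02 * scale, size=(M + 2, d))
        jitter[0] = jitter[-1] = 0.0
        cand = base + jitter
        if nonnegative:
            cand = np.clip(cand, 0.0, None)
        inits.append(cand)

    bounds = None
    if nonnegative:
        bounds = [(0.0, None)] * (M * d)

    best = None
    for T in T_grid:
        for init in inits:
            def objective(z):
                phi = np.vstack([x_from, z.reshape(M, d), x_to])
                S, grad = fw_action(
                    DiscretizedPath(phi, duration=T, labels=model.labels),
                    model, return_grad=True,
                )
                return S, grad.ravel()

            res = scipy_minimize(
                objective, init[1:-1].ravel(), jac=True, method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": maxiter, "maxfun": 4 * maxiter,
                         "ftol": 1e-14, "gtol": 1e-12},
            )
            phi = np.vstack([x_from, res.x.reshape(M, d), x_to])
            pth = DiscretizedPath(phi, duration=T, labels=model.labels)
            S, grad = fw_action(pth, model, return_grad=True)
            if nonnegative:
                # projected gradient: bound-active coordinates pushing
                # outward do not count against convergence
                grad = np.where((phi[1:-1] <= 0.0) & (grad > 0.0), 0.0, grad)
            gnorm = float(np.linalg.norm(grad.ravel(), ord=np.inf))
            _, _, eps_max = _effective_noise_diag(model, 0.5 * (phi[:-1] + phi[1:]))
            cand = ActionResult(
                path=pth, action=float(S), iterations=int(res.nit),
                converged=gnorm < gtol_scale * (1.0 + abs(S)),
                grad_norm=gnorm, regularization=eps_max,
                diagnostics={"T": T, "message": str(res.message), "n_T": len(T_grid)},
            )
            if best is None or cand.action < best.action:
                best = cand
    return best


# --------------------------------------------------------------------------
# Toy reference path and path comparison
# --------------------------------------------------------------------------

def toy_uphill_reference_path(
    params: ToyParams,
    well: str = "+",
    offset: float = 1e-3,
    max_time: float = 500.0,
    rtol: float = 1e-10,
    n_points: int = 400,
) -> DiscretizedPath:
    """Reference transition path: uphill flow then deterministic free fall.

    The uphill segment integrates ``x' = grad U + f_U`` from a small offset
    off the chosen minimum until it converges onto the saddle (the potential
    is non-decreasing along this flow); the downhill segment follows the true
    drift from just past the saddle into the opposite well.
    """
    roots = toy_fixed_x1_roots(params)
    if len(roots) != 3:
        raise ValueError("toy parameters are not bistable; no saddle exists")
    lo, saddle_x1, hi = roots
    x_min = np.array([hi if well == "+" else lo, 0.0])
    x_other = np.array([lo if well == "+" else hi, 0.0])
    saddle = np.array([saddle_x1, 0.0])

    def uphill(t, x):
        g, c = toy_decomposition(x, params)
        return -g + c  # grad U + curl

    # The saddle attracts the uphill flow only along a 1-D stable manifold
    # (the transverse direction is cubically repelling), so shooting from
    # the well generically misses it.  Instead integrate the reversed field
    # backward from the saddle along that stable eigendirection: the wells
    # are attractors of the reversed flow.
    h = 1e-7
    J = np.column_stack([
        (uphill(0.0, saddle + [h, 0.0]) - uphill(0.0, saddle - [h, 0.0])) / (2 * h),
        (uphill(0.0, saddle + [0.0, h]) - uphill(0.0, saddle - [0.0, h])) / (2 * h),
    ])
    evals, evecs = np.linalg.eig(J)
    k = int(np.argmin(evals.real))
    if evals.real[k] >= 0:
        raise RuntimeError("no stable uphill direction at the saddle")
    v = np.real(evecs[:, k])
    if np.dot(v, x_min - saddle) < 0:
        v = -v
    v = v / np.linalg.norm(v)

    def reversed_uphill(t, x):
        return -uphill(t, x)

    def near_min(t, x):
        return np.linalg.norm(x - x_min) - 1e-6

    near_min.terminal = True
    near_min.direction = -1

    x0 = saddle + offset * v
    back = solve_ivp(reversed_uphill, (0.0, max_time), x0, rtol=rtol, atol=1e-12,
                     events=near_min, dense_output=True, max_step=1.0)
    # the transverse coordinate decays only cubically, so accept a loose
    # approach to the well and close the path with the exact endpoints
    if np.linalg.norm(back.y[:, -1] - x_min) > 0.05:
        raise RuntimeError(
            f"uphill flow failed to connect saddle and well within t={max_time}; "
            f"last state {back.y[:, -1]}"
        )
    t_bk = np.linspace(0.0, back.t[-1], n_points)
    seg_up = back.sol(t_bk).T[::-1]  # well -> saddle
    seg_up = np.vstack([x_min, seg_up, saddle])

    def downhill(t, x):
        return toy_drift(x, params)

    def near_target(t, x):
        return np.linalg.norm(x - x_other) - 1e-6

    near_target.terminal = True
    near_target.direction = -1

    x1 = saddle + 1e-4 * (x_other - saddle) / np.linalg.norm(x_other - saddle)
    down = solve_ivp(downhill, (0.0, max_time), x1, rtol=rtol, atol=1e-12,
                     events=near_target, dense_output=True, max_step=1.0)
    t_dn = np.linspace(0.0, down.t[-1], n_points)
    seg_dn = down.sol(t_dn).T

    states = np.vstack([seg_up, seg_dn, [x_other]])
    return DiscretizedPath(states, duration=None, labels=TOY_LABELS)


def resample_by_arclength(path: DiscretizedPath, n_points: int) -> DiscretizedPath:
    """Resample a path to ``n_points`` equally spaced in arc length."""
    s = path.arclength()
    total = s[-1]
    if total == 0:
        states = np.tile(path.states[0], (n_points, 1))
        return DiscretizedPath(states + 0.0, duration=path.duration, labels=path.labels)
    target = np.linspace(0.0, total, n_points)
    cols = [np.interp(target, s, path.states[:, j]) for j in range(path.states.shape[1])]
    return DiscretizedPath(np.column_stack(cols), duration=path.duration, labels=path.labels)


def point_to_polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest segment of a polyline."""
    points = np.atleast_2d(points)
    a = poly[:-1]
    b = poly[1:]
    ab = b - a  # (m, d)
    denom = np.einsum("md,md->m", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]  # (n, m, d)
    t = np.clip(np.einsum("nmd,md->nm", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - proj, axis=2)
    return dist.min(axis=1)


def path_separation(path_a: DiscretizedPath, path_b: DiscretizedPath, n_points: int = 256) -> float:
    """Symmetric separation of two paths after arc-length resampling.

    The maximum over either path's resampled points of the distance to the
    other path's polyline (a symmetric, parametrization-free Hausdorff-style
    measure).
    """
    if path_a.states.shape[1] != path_b.states.shape[1]:
        raise ValueError("paths must share a state dimension")
    ra = resample_by_arclength(path_a, n_points).states
    rb = resample_by_arclength(path_b, n_points).states
    d_ab = point_to_polyline_distance(ra, rb).max()
    d_ba = point_to_polyline_distance(rb, ra).max()
    return float(max(d_ab, d_ba))
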