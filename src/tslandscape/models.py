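"""Model definitions: drifts, potentials, propensities and noise structure.

Two systems are implemented:

* a two-dimensional bistable SDE whose drift decomposes exactly into the
  negative gradient of a quartic potential plus an orthogonal "curl"
  component scaled by a constant ``c``;
* a four-species birth--death network (Nanog ``N``, Oct4-Sox2 ``O``,
  Fgf4 ``F``, Gata6 ``G``) driven by an external LIF concentration ``L``,
  with eight reactions (one birth and one first-order death per species).

Everything here is a pure function of a state and a parameter set; the
stochastic machinery lives in :mod:`tslandscape.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import sympy as sp
import yaml

__all__ = [
    "DimensionError",
    "ToyParams",
    "DevParams",
    "StateVector",
    "ReactionNetwork",
    "toy_potential",
    "toy_decomposition",
    "toy_drift",
    "toy_drift_sympy",
    "toy_fixed_x1_roots",
    "dev_propensities",
    "dev_stoichiometry",
    "dev_drift",
    "dev_noise_covariance",
    "dev_network",
    "dev_drift_sympy",
    "load_params",
    "TOY_LABELS",
    "DEV_LABELS",
]

TOY_LABELS = ("x1", "x2")
DEV_LABELS = ("N", "O", "F", "G")


class DimensionError(ValueError):
    """State has the wrong number of coordinates for the requested model."""


def _check_dim(x: np.ndarray, d: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[-1:] != (d,):
        raise DimensionError(f"expected {d} coordinates, got shape {x.shape}")
    return x


@dataclass(frozen=True)
class ToyParams:
    """Parameters of the 2-D bistable SDE.

    ``alpha`` sets the depth of the quadratic well, ``lam`` the quartic
    confinement, ``beta`` tilts the potential along ``x1``, ``c`` scales the
    orthogonal curl component and ``sigma`` the isotropic noise amplitude.
    """

    alpha: float = 0.5
    lam: float = 0.25
    beta: float = -0.05
    c: float = 0.5
    sigma: float = 0.4

    def __post_init__(self) -> None:
        vals = [self.alpha, self.lam, self.beta, self.c, self.sigma]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all toy parameters must be finite")
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")

    def replace(self, **kw) -> "ToyParams":
        return replace(self, **kw)


_DEV_RATE_NAMES = tuple(f"k{i}" for i in range(15)) + ("kd",)


@dataclass(frozen=True)
class DevParams:
    """Kinetic constants of the four-gene network plus the LIF level ``L``.

    Two canonical sets ship with the package (see :func:`load_params`):

    * ``"paper-printed"`` -- the literal parse of the published table;
    * ``"calibrated"`` -- the repository default, rescaled so that the model
      exhibits the reported stem / transition / differentiated fixed-point
      structure at copy numbers of order 10--100 for every L in [0, 200].
    """

    k0: float = 0.005
    k1: float = 0.01
    k2: float = 0.42
    k3: float = 1.0
    k4: float = 0.1
    k5: float = 0.00135
    k6: float = 0.01
    k7: float = 0.01
    k8: float = 1.0
    k9: float = 1.0
    k10: float = 0.01
    k11: float = 0.05
    k12: float = 0.004
    k13: float = 0.005
    k14: float = 0.01
    kd: float = 0.009
    L: float = 50.0

    def __post_init__(self) -> None:
        for name in _DEV_RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"rate constant {name} must be finite and >= 0, got {v}")
        if not np.isfinite(self.L) or self.L < 0:
            raise ValueError(f"L must be finite and >= 0, got {self.L}")

    def replace(self, **kw) -> "DevParams":
        return replace(self, **kw)

    def rates(self) -> dict:
        return {name: getattr(self, name) for name in _DEV_RATE_NAMES}


@dataclass(frozen=True)
class StateVector:
    """A labeled point in phase space."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.labels) != self.values.shape[-1]:
            raise DimensionError(
                f"{len(self.labels)} labels but {self.values.shape[-1]} values"
            )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def __len__(self) -> int:
        return len(self.labels)


def _values(point) -> np.ndarray:
    if isinstance(point, StateVector):
        return point.values
    return np.asarray(point, dtype=float)


# --------------------------------------------------------------------------
# 2-D bistable toy system
# --------------------------------------------------------------------------

def toy_potential(point, params: ToyParams = ToyParams()):
    """Quartic double-well potential lam*(x1^4 + x2^4) - alpha*x1^2 + beta*x1."""
    x = _check_dim(_values(point), 2)
    x1, x2 = x[..., 0], x[..., 1]
    return params.lam * (x1**4 + x2**4) - params.alpha * x1**2 + params.beta * x1


def toy_decomposition(point, params: ToyParams = ToyParams()):
    """Split the toy drift into (negative-gradient, curl) parts.

    The gradient part is ``-grad U``; the curl part is the orthogonal field
    ``c * [4 lam x2^3, 2 alpha x1 - 4 lam x1^3 - beta]``.  Their dot product
    vanishes identically.
    """
    x = _check_dim(_values(point), 2)
    x1, x2 = x[..., 0], x[..., 1]
    g1 = 2 * params.alpha * x1 - 4 * params.lam * x1**3 - params.beta
    g2 = -4 * params.lam * x2**3
    grad_part = np.stack([g1, g2], axis=-1)
    curl_part = params.c * np.stack([-g2, g1], axis=-1)
    return grad_part, curl_part


def toy_drift(point, params: ToyParams = ToyParams()):
    """Deterministic drift of the toy SDE: gradient plus curl component."""
    grad_part, curl_part = toy_decomposition(point, params)
    return grad_part + curl_part


def toy_drift_sympy(params: ToyParams = ToyParams()):
    """Symbolic drift as (sympy Matrix, (x1, x2)); used for exact Jacobians."""
    x1, x2 = sp.symbols("x1 x2", real=True)
    g1 = 2 * params.alpha * x1 - 4 * params.lam * x1**3 - params.beta
    g2 = -4 * params.lam * x2**3
    f = sp.Matrix([g1 - params.c * g2, params.c * g1 + g2])
    return f, (x1, x2)


def toy_fixed_x1_roots(params: ToyParams = ToyParams()) -> np.ndarray:
    """Real roots of 2*alpha*x1 - 4*lam*x1^3 - beta = 0 (the x2=0 fixed points)."""
    roots = np.roots([-4 * params.lam, 0.0, 2 * params.alpha, -params.beta])
    return np.sort(roots[np.abs(roots.imag) < 1e-10].real)


# --------------------------------------------------------------------------
# Four-gene developmental network
# --------------------------------------------------------------------------

def dev_propensities(state, params: DevParams):
    """The eight reaction propensities [a1..a8] at a (batch of) state(s).

    a1..a4 are the Hill-type production rates of N, O, F, G; a5..a8 are the
    first-order degradations kd*{N,O,F,G}.  Negative state coordinates raise
    a ``ValueError``.
    """
    x = _check_dim(_values(state), 4)
    if np.any(x < 0):
        raise ValueError("developmental state coordinates must be non-negative")
    N, O, F, G = x[..., 0], x[..., 1], x[..., 2], x[..., 3]
    p = params
    a1 = (p.k0 * O * (p.k1 + p.k2 * N**2 + p.k0 * O + p.k3 * p.L)) / (
        1.0 + p.k0 * O * (p.k2 * N**2 + p.k0 * O + p.k3 * p.L + p.k4 * F**2)
        + p.k5 * O * G**2
    )
    a2 = (p.k6 + p.k7 * O) / (1.0 + p.k7 * O + p.k8 * G**2)
    a3 = (p.k9 + p.k10 * O) / (1.0 + p.k10 * O)
    a4 = (p.k11 + p.k12 * G**2 + p.k14 * O) / (
        1.0 + p.k12 * G**2 + p.k13 * N**2 + p.k14 * O
    )
    ones = np.ones_like(N)
    return np.stack(
        [a1 * ones, a2 * ones, a3 * ones, a4 * ones,
         p.kd * N, p.kd * O, p.kd * F, p.kd * G], axis=-1,
    )


def dev_stoichiometry() -> np.ndarray:
    """4x8 integer stoichiometry: +1 in column i, -1 in column i+4 for row i."""
    S = np.zeros((4, 8), dtype=int)
    for i in range(4):
        S[i, i] = 1
        S[i, i + 4] = -1
    return S


def dev_drift(state, params: DevParams):
    """Deterministic rate equations S.a(state): birth minus death per species."""
    a = dev_propensities(state, params)
    return a[..., :4] - a[..., 4:]


def dev_noise_covariance(state, params: DevParams):
    """Diffusion matrix S.diag(a).S^T; diagonal with entries a_i + a_{i+4}."""
    a = dev_propensities(state, params)
    d = a[..., :4] + a[..., 4:]
    out = np.zeros(d.shape + (4,))
    idx = np.arange(4)
    out[..., idx, idx] = d
    return out


def dev_drift_sympy(params: DevParams):
    """Symbolic rate equations as (sympy Matrix, (N, O, F, G))."""
    N, O, F, G = syms = sp.symbols("N O F G", nonnegative=True)
    p = params
    a1 = (p.k0 * O * (p.k1 + p.k2 * N**2 + p.k0 * O + p.k3 * p.L)) / (
        1 + p.k0 * O * (p.k2 * N**2 + p.k0 * O + p.k3 * p.L + p.k4 * F**2)
        + p.k5 * O * G**2
    )
    a2 = (p.k6 + p.k7 * O) / (1 + p.k7 * O + p.k8 * G**2)
    a3 = (p.k9 + p.k10 * O) / (1 + p.k10 * O)
    a4 = (p.k11 + p.k12 * G**2 + p.k14 * O) / (
        1 + p.k12 * G**2 + p.k13 * N**2 + p.k14 * O
    )
    f = sp.Matrix([a1 - p.kd * N, a2 - p.kd * O, a3 - p.kd * F, a4 - p.kd * G])
    return f, syms


@dataclass(frozen=True)
class ReactionNetwork:
    """A reaction network: species labels, propensity evaluator, stoichiometry."""

    species: tuple
    propensities: Callable[[np.ndarray], np.ndarray]
    stoichiometry: np.ndarray
    params: object = None

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]

    def drift(self, state) -> np.ndarray:
        a = self.propensities(np.asarray(state, dtype=float))
        return a @ self.stoichiometry.T

    def noise_diagonal(self, state) -> np.ndarray:
        a = self.propensities(np.asarray(state, dtype=float))
        return a[..., :4] + a[..., 4:]


def dev_network(params: DevParams) -> ReactionNetwork:
    """Bundle the developmental model into a :class:`ReactionNetwork`."""
    return ReactionNetwork(
        species=DEV_LABELS,
        propensities=lambda x: dev_propensities(x, params),
        stoichiometry=dev_stoichiometry(),
        params=params,
    )


# --------------------------------------------------------------------------
# Packaged parameter sets
# --------------------------------------------------------------------------

_PARAM_FILES = {
    "toy-default": "toy_default.yaml",
    "paper-printed": "dev_printed.yaml",
    "calibrated": "dev_calibrated.yaml",
}


def load_params(name: str):
    """Load a packaged parameter set by name.

    ``"toy-default"`` returns a :class:`ToyParams`; ``"paper-printed"`` and
    ``"calibrated"`` return :class:`DevParams`.
    """
    try:
        fname = _PARAM_FILES[name]
    except KeyError:
        raise KeyError(f"unknown parameter set {name!r}; choose from {sorted(_PARAM_FILES)}")
    text = resources.files("tslandscape.params").joinpath(fname).read_text()
    data = yaml.safe_load(text)
    data.pop("provenance", None)
    if name == "toy-default":
        return ToyParams(**data)
    return DevParams(**data)
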