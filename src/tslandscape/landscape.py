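"""Empirical probability landscapes: histograms, -ln(P) potentials, marginals.

The potential assigned to a bin is ``-ln(P + pseudocount)``; empty bins are
capped at the finite plateau ``-ln(pseudocount)``.  The default pseudocount
is ``0.5 / n_samples`` (Jeffreys-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandscapeGrid",
    "histogram_density",
    "potential_from_density",
    "marginalize",
    "variance_timeseries",
    "find_modes",
    "total_variation",
]


@dataclass
class LandscapeGrid:
    """Binned empirical density and its negative-log potential."""

    axes: tuple
    edges: tuple  # tuple of 1-D strictly increasing edge arrays
    counts: np.ndarray
    mass: np.ndarray
    potential: Optional[np.ndarray] = None
    pseudocount: Optional[float] = None
    n_samples: int = 0
    n_overflow: int = 0

    def __post_init__(self) -> None:
        self.axes = tuple(self.axes)
        self.edges = tuple(np.asarray(e, dtype=float) for e in self.edges)
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")
        total = self.mass.sum()
        if self.counts.sum() > 0 and abs(total - 1.0) > 1e-12:
            raise ValueError(f"probability mass sums to {total}, expected 1")

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def centers(self, axis=None) -> np.ndarray:
        if axis is None:
            return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)
        i = axis if isinstance(axis, int) else self.axes.index(axis)
        e = self.edges[i]
        return 0.5 * (e[1:] + e[:-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: bin centers per axis, mass and potential."""
        grids = np.meshgrid(*self.centers(), indexing="ij")
        data = {ax: g.ravel() for ax, g in zip(self.axes, grids)}
        data["mass"] = self.mass.ravel()
        if self.potential is not None:
            data["potential"] = self.potential.ravel()
        return pd.DataFrame(data)


def _resolve_samples(samples, axes):
    """Extract an (n, d) array for the requested axes from samples/ensembles."""
    from tslandscape.simulate import Ensemble, Trajectory

    if isinstance(samples, (Ensemble, Trajectory)):
        labels = samples.labels
        cols = [labels.index(a) for a in axes]
        arr = samples.states[..., cols].reshape(-1, len(cols))
        return arr
    arr = np.asarray(samples, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[1] != len(axes):
        raise ValueError(f"samples have {arr.shape[1]} columns, expected {len(axes)}")
    return arr


def _make_edges(arr, bins, ranges):
    d = arr.shape[1]
    if isinstance(bins, int):
        bins = (bins,) * d
    edges = []
    for j in range(d):
        if ranges is not None and ranges[j] is not None:
            lo, hi = map(float, ranges[j])
        else:
            lo, hi = np.percentile(arr[:, j], [1.0, 99.0])
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
        if not lo < hi:
            raise ValueError(f"degenerate bin range ({lo}, {hi}) on axis {j}")
        edges.append(np.linspace(lo, hi, bins[j] + 1))
    return edges


def histogram_density(
    samples,
    axes: Sequence[str],
    bins=60,
    ranges=None,
    pseudocount: Optional[float] = None,
) -> LandscapeGrid:
    """Normalized histogram of samples over the chosen axes.

    ``samples`` may be an array, a :class:`~tslandscape.simulate.Trajectory`
    or an :class:`~tslandscape.simulate.Ensemble`.  Bin ranges default to the
    1st--99th percentile of the data per axis; out-of-range samples are
    counted in ``n_overflow``.  The returned grid already carries the
    ``-ln(P + pseudocount)`` potential.
    """
    axes = tuple(axes)
    arr = _resolve_samples(samples, axes)
    if arr.shape[0] == 0:
        raise ValueError("cannot build a landscape from an empty sample set")
    edges = _make_edges(arr, bins, ranges)
    counts, _ = np.histogramdd(arr, bins=edges)
    n_in = int(counts.sum())
    n_over = arr.shape[0] - n_in
    if n_in == 0:
        raise ValueError("all samples fall outside the requested bin ranges")
    mass = counts / n_in
    grid = LandscapeGrid(
        axes=axes, edges=tuple(edges), counts=counts, mass=mass,
        n_samples=arr.shape[0], n_overflow=n_over,
    )
    if pseudocount is None:
        pseudocount = 0.5 / n_in
    return potential_from_density(grid, pseudocount)


def potential_from_density(grid: LandscapeGrid, pseudocount: float) -> LandscapeGrid:
    """Attach the potential ``-ln(P + pseudocount)`` to a normalized grid."""
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    if pseudocount == 0 and np.any(grid.mass == 0):
        raise ValueError("pseudocount must be positive when empty bins exist")
    potential = -np.log(grid.mass + pseudocount)
    return replace(grid, potential=potential, pseudocount=pseudocount)


def marginalize(grid_or_samples, axis: str, bins=60, ranges=None):
    """Normalized 1-D marginal along ``axis``.

    Accepts a :class:`LandscapeGrid` (summing out the other axes on its own
    edges) or raw samples/ensembles (direct 1-D histogram).
    """
    if isinstance(grid_or_samples, LandscapeGrid):
        grid = grid_or_samples
        if axis not in grid.axes:
            raise ValueError(f"unknown axis {axis!r}; grid has {grid.axes}")
        i = grid.axes.index(axis)
        other = tuple(j for j in range(grid.ndim) if j != i)
        counts = grid.counts.sum(axis=other) if other else grid.counts.copy()
        mass = counts / counts.sum()
        out = LandscapeGrid(
            axes=(axis,), edges=(grid.edges[i],), counts=counts, mass=mass,
            n_samples=grid.n_samples, n_overflow=grid.n_overflow,
        )
        pc = grid.pseudocount if grid.pseudocount is not None else 0.5 / max(counts.sum(), 1)
        return potential_from_density(out, pc)
    return histogram_density(grid_or_samples, (axis,), bins=bins, ranges=[ranges] if ranges is not None else None)


def variance_timeseries(ensemble) -> pd.DataFrame:
    """Unbiased (n-1) cross-member variance of every variable at every time."""
    if ensemble.n_members < 2:
        raise ValueError("variance needs at least two ensemble members")
    var = ensemble.states.var(axis=0, ddof=1)
    df = pd.DataFrame(var, columns=[f"var_{lab}" for lab in ensemble.labels])
    df.insert(0, "time", ensemble.times)
    return df


def find_modes(grid: LandscapeGrid, min_mass: float = 0.01) -> list:
    """Local maxima of the binned mass (strictly above all neighbours).

    A bin is a mode if it exceeds every neighbour in the 3^d - 1 stencil and
    carries at least ``min_mass`` of the total probability.  Returns a list of
    dicts with bin index, center coordinates and mass.
    """
    mass = grid.mass
    d = mass.ndim
    padded = np.pad(mass, 1, mode="constant", constant_values=-np.inf)
    is_max = np.ones_like(mass, dtype=bool)
    for offset in np.ndindex(*(3,) * d):
        if all(o == 1 for o in offset):
            continue
        sl = tuple(slice(o, o + s) for o, s in zip(offset, mass.shape))
        is_max &= mass > padded[sl]
    is_max &= mass >= min_mass
    centers = grid.centers()
    modes = []
    for idx in np.argwhere(is_max):
        modes.append({
            "index": tuple(int(i) for i in idx),
            "location": tuple(float(centers[j][i]) for j, i in enumerate(idx)),
            "mass": float(mass[tuple(idx)]),
        })
    modes.sort(key=lambda m: -m["mass"])
    return modes


def total_variation(a: LandscapeGrid, b: LandscapeGrid) -> float:
    """Total-variation distance between two grids on identical edges."""
    if a.mass.shape != b.mass.shape:
        raise ValueError("grids must share a common binning")
    for ea, eb in zip(a.edges, b.edges):
        if ea.shape != eb.shape or not np.allclose(ea, eb):
            raise ValueError("grids must share identical bin edges")
    return 0.5 * float(np.abs(a.mass - b.mass).sum())
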