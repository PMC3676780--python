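"""Reaction-diffusion chemical fields coupled to agent positions.

Cells act as moving point sources (or sinks) for an extracellular attractant
S and, optionally, consume a nutrient F::

    dS/dt = Ds * Lap(S) + gamma * sum_i delta(x - x_i) - mu * S
    dF/dt = Df * Lap(F) - k * sum_i delta(x - x_i)

(the attractant loss term is first-order decay -mu*S).  A consumed-signal
variant has cells consuming S itself (gamma < 0 effect) with S(x, 0) = 1,
which produces a travelling band that chases the receding signal front.

Numerics: delta sources are spread onto the lattice with bilinear
(cloud-in-cell) weights, which conserve deposited mass exactly and form a
transpose pair with bilinear interpolation of the field back to cell
positions.  Diffusion uses an implicit backward-Euler step -- alternating
direction (ADI) in 2-D, one tridiagonal solve per axis -- which conserves
mass to round-off under periodic or no-flux boundaries; reactions are applied
pointwise afterwards.  Negative concentrations (possible under strong
consumption) are clamped to zero with a warning.

``run_pattern_scenario`` wires the agent simulator to the field solver with
first-order splitting on a shared time step and runs the canonical
pattern-formation scenarios: attractant-secreting cells in liquid
(network/aggregate formation), a swarm ring with nutrient consumption, the
consumed-signal travelling band, and surface spiral streams (omega > 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.sparse import identity as sp_identity
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import factorized

from .agents import AgentParams, _internal_propagator

__all__ = [
    "FieldGrid",
    "deposit",
    "interpolate",
    "step_field",
    "run_pattern_scenario",
    "PatternResult",
    "SCENARIOS",
]


def _laplacian_1d(n: int, dx: float, bc: str) -> lil_matrix:
    L = lil_matrix((n, n))
    for i in range(n):
        L[i, i] = -2.0
        if i > 0:
            L[i, i - 1] = 1.0
        if i < n - 1:
            L[i, i + 1] = 1.0
    if bc == "periodic":
        L[0, n - 1] += 1.0
        L[n - 1, 0] += 1.0
    elif bc == "noflux":
        L[0, 0] = -1.0
        L[n - 1, n - 1] = -1.0
    else:
        raise ValueError("bc must be 'periodic' or 'noflux'")
    return L / dx**2


@dataclass
class FieldGrid:
    """Rectangular lattice holding attractant S and optional nutrient F.

    shape: nodes per dimension (1- or 2-tuple); dx: spacing (um);
    D_s/D_f: diffusivities (um^2/s); gamma: per-cell attractant
    secretion rate (>0) or signal consumption rate in the consumed-signal
    variant; k: per-cell nutrient consumption rate; mu: attractant decay
    rate (1/s); bc: 'periodic' or 'noflux'.
    """

    shape: tuple[int, ...]
    dx: float
    D_s: float = 100.0
    D_f: float = 100.0
    gamma: float = 0.0
    k: float = 0.0
    mu: float = 0.0
    bc: str = "periodic"
    consumed_signal: bool = False
    S: np.ndarray = field(default=None)
    F: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) not in (1, 2):
            raise ValueError("grids are 1-D or 2-D")
        if self.S is None:
            self.S = np.zeros(self.shape)
        else:
            self.S = np.asarray(self.S, float).reshape(self.shape).copy()
        if self.F is not None:
            self.F = np.asarray(self.F, float).reshape(self.shape).copy()
        if self.bc not in ("periodic", "noflux"):
            raise ValueError("bc must be 'periodic' or 'noflux'")
        self._solvers: dict = {}

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def extent(self) -> np.ndarray:
        """Physical box lengths (um); node i sits at x = i*dx."""
        if self.bc == "periodic":
            return np.array([n * self.dx for n in self.shape])
        return np.array([(n - 1) * self.dx for n in self.shape])

    def node_volume(self) -> float:
        return self.dx**self.ndim

    def total_mass(self, which: str = "S") -> float:
        arr = self.S if which == "S" else self.F
        return float(arr.sum() * self.node_volume())

    def _solver(self, axis: int, D: float, dt: float):
        key = (axis, D, round(dt, 15))
        if key not in self._solvers:
            n = self.shape[axis]
            L = _laplacian_1d(n, self.dx, self.bc)
            A = (sp_identity(n) - dt * D * L).tocsc()
            self._solvers[key] = factorized(A)
        return self._solvers[key]


def _cic_weights(positions: np.ndarray, grid: FieldGrid):
    """Cloud-in-cell node indices and weights for each position.

    Returns (idx, w): idx has shape (n, 2**ndim, ndim), w (n, 2**ndim),
    with weights summing to 1 per position.
    """
    x = np.atleast_2d(np.asarray(positions, float))
    ndim = grid.ndim
    if x.shape[1] != ndim:
        raise ValueError("position dimensionality does not match grid")
    ext = grid.extent
    if grid.bc == "periodic":
        x = np.mod(x, ext)
    else:
        if np.any(x < -1e-9) or np.any(x > ext + 1e-9):
            raise ValueError("cell outside domain")
        x = np.clip(x, 0.0, ext)
    g = x / grid.dx
    i0 = np.floor(g).astype(int)
    frac = g - i0
    n = x.shape[0]
    corners = np.array(
        [[(b >> d) & 1 for d in range(ndim)] for b in range(2**ndim)]
    )  # (2**ndim, ndim)
    idx = i0[:, None, :] + corners[None, :, :]
    w = np.ones((n, 2**ndim))
    for d in range(ndim):
        fd = frac[:, d]
        w *= np.where(corners[None, :, d] == 1, fd[:, None], 1.0 - fd[:, None])
    for d in range(ndim):
        nd = grid.shape[d]
        if grid.bc == "periodic":
            idx[:, :, d] %= nd
        else:
            idx[:, :, d] = np.clip(idx[:, :, d], 0, nd - 1)
    return idx, w


def deposit(positions: np.ndarray, grid: FieldGrid) -> np.ndarray:
    """Spread unit mass per cell onto grid nodes (cloud-in-cell).

    Returns a source *density* field: its integral (sum * dx^ndim) equals the
    cell count exactly.
    """
    idx, w = _cic_weights(positions, grid)
    src = np.zeros(grid.shape)
    flat = np.ravel_multi_index(
        tuple(idx[:, :, d].ravel() for d in range(grid.ndim)), grid.shape
    )
    np.add.at(src.ravel(), flat, w.ravel())
    return src / grid.node_volume()


def interpolate(field_values: np.ndarray, positions: np.ndarray, grid: FieldGrid) -> np.ndarray:
    """Sample a node field at cell positions with the same bilinear weights
    used by :func:`deposit` (the two operations are a transpose pair)."""
    idx, w = _cic_weights(positions, grid)
    flat = np.ravel_multi_index(
        tuple(idx[:, :, d].ravel() for d in range(grid.ndim)), grid.shape
    )
    vals = np.asarray(field_values).ravel()[flat].reshape(w.shape)
    return np.sum(vals * w, axis=1)


def _diffuse(grid: FieldGrid, arr: np.ndarray, D: float, dt: float) -> np.ndarray:
    if D == 0.0 or dt == 0.0:
        return arr
    if grid.ndim == 1:
        return grid._solver(0, D, dt)(arr)
    # ADI: implicit solve along each axis in turn
    out = grid._solver(0, D, dt)(arr)            # columns: axis 0
    out = grid._solver(1, D, dt)(out.T).T        # rows: axis 1
    return out


def step_field(grid: FieldGrid, source_density: np.ndarray | None, dt: float) -> None:
    """Advance the chemical fields by one operator-split step, in place.

    Diffusion (implicit, mass-conserving) then pointwise reaction:
    secretion + decay for S (or consumption of S in the consumed-signal
    variant) and consumption for F.  NaN/inf aborts; negativity is clamped
    to zero with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    S = _diffuse(grid, grid.S, grid.D_s, dt)
    if grid.consumed_signal:
        # constant per-cell sink: dS/dt = -gamma * sum_i delta(x - x_i)
        if source_density is not None and grid.gamma != 0.0:
            S = S - grid.gamma * source_density * dt
    else:
        if grid.mu > 0.0:
            decay = math.exp(-grid.mu * dt)
            src = 0.0 if source_density is None else grid.gamma * source_density
            # exact pointwise update of dS/dt = src - mu*S over the step
            S = S * decay + src * (1.0 - decay) / grid.mu
        elif source_density is not None and grid.gamma != 0.0:
            S = S + grid.gamma * source_density * dt
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("field solver produced non-finite values")
    if np.any(S < 0):
        warnings.warn("negative concentration clamped to zero", stacklevel=2)
        S = np.maximum(S, 0.0)
    grid.S = S
    if grid.F is not None:
        F = _diffuse(grid, grid.F, grid.D_f, dt)
        if source_density is not None and grid.k != 0.0:
            F = F - grid.k * source_density * dt
        if np.any(F < 0):
            F = np.maximum(F, 0.0)
        grid.F = F


# ---------------------------------------------------------------------------
# coupled agents + fields scenarios
# ---------------------------------------------------------------------------


@dataclass
class PatternResult:
    """Outputs of a coupled agents+fields run."""

    times: np.ndarray                 # snapshot times (s)
    density: np.ndarray               # binned cell density per snapshot
    signal: np.ndarray                # S field per snapshot
    positions: np.ndarray             # cell positions at snapshots
    density_variance: np.ndarray      # variance of binned density over time
    mean_position: np.ndarray         # population mean position per snapshot
    params: AgentParams
    grid: FieldGrid


def _bin_density(x: np.ndarray, grid: FieldGrid) -> np.ndarray:
    ext = grid.extent
    if grid.ndim == 1:
        h, _ = np.histogram(x[:, 0], bins=grid.shape[0], range=(0, ext[0]))
        return h.astype(float)
    h, _, _ = np.histogram2d(
        x[:, 0], x[:, 1], bins=grid.shape, range=[(0, ext[0]), (0, ext[1])]
    )
    return h


def simulate_coupled(
    params: AgentParams,
    grid: FieldGrid,
    n_cells: int,
    t_end: float,
    dt: float,
    seed: int | None = 0,
    x0: np.ndarray | None = None,
    n_snapshots: int = 20,
    bc_cells: str = "periodic",
) -> PatternResult:
    """Run agents and fields together on a shared dt (first-order splitting).

    Per step: interpolate S at cell positions -> internal update -> turn
    decision and move -> deposit cells -> field step.
    """
    if dt > params.t_e / 5.0 + 1e-12:
        raise ValueError("dt must be <= t_e/5")
    rng = np.random.default_rng(seed)
    N = params.dim
    if grid.ndim != N:
        raise ValueError("grid and agent dimensionality differ")
    ext = grid.extent
    if x0 is None:
        x = rng.uniform(0.0, ext, size=(n_cells, N))
    else:
        x = np.array(x0, float).reshape(n_cells, N).copy()
    if N == 1:
        heading = np.where(rng.random(n_cells) < 0.5, 1.0, -1.0)
    else:
        heading = rng.uniform(0.0, 2.0 * math.pi, n_cells)
    y = np.zeros((2, n_cells))
    s_at = interpolate(grid.S, x, grid)
    y[1] = np.asarray(params.G(s_at), float)  # start adapted

    E, g = _internal_propagator(params, dt)
    n_steps = int(round(t_end / dt))
    snap_idx = np.unique(
        np.linspace(0, n_steps, n_snapshots + 1).round().astype(int)
    )
    times, density, signal, pos_snaps, var, meanpos = [], [], [], [], [], []

    def record(step: int) -> None:
        times.append(step * dt)
        d = _bin_density(x, grid)
        density.append(d)
        signal.append(grid.S.copy())
        pos_snaps.append(x.copy())
        var.append(float(np.var(d)))
        meanpos.append(x.mean(axis=0).copy())

    record(0)
    lam0, gam0, s0 = params.lambda0, params.gamma0, params.s0
    for k in range(n_steps):
        s_at = interpolate(grid.S, x, grid)
        drive = np.asarray(params.G(s_at), float)
        y = E @ y + np.multiply.outer(g, drive)
        lam = lam0 * (1.0 - y[0] / (gam0 + np.abs(y[0])))
        u_turn = rng.random(n_cells)
        u_dir = rng.random(n_cells)
        turned = u_turn < -np.expm1(-lam * dt)
        if np.any(turned):
            if N == 1:
                heading[turned] = np.where(u_dir[turned] < 0.5, 1.0, -1.0)
            else:
                heading[turned] = u_dir[turned] * (2.0 * math.pi)
        if N == 1:
            x[:, 0] += heading * s0 * dt
        else:
            heading = heading - params.omega * dt
            x[:, 0] += s0 * np.cos(heading) * dt
            x[:, 1] += s0 * np.sin(heading) * dt
        if bc_cells == "periodic":
            x %= ext
        else:
            for d in range(N):
                over = x[:, d] > ext[d]
                under = x[:, d] < 0.0
                x[over, d] = 2.0 * ext[d] - x[over, d]
                x[under, d] = -x[under, d]
                if N == 1:
                    heading[over | under] *= -1.0
                elif d == 0:
                    heading[over | under] = math.pi - heading[over | under]
                else:
                    heading[over | under] = -heading[over | under]
        src = deposit(x, grid)
        step_field(grid, src, dt)
        if k + 1 in snap_idx:
            record(k + 1)

    return PatternResult(
        times=np.array(times),
        density=np.array(density),
        signal=np.array(signal),
        positions=np.array(pos_snaps),
        density_variance=np.array(var),
        mean_position=np.array(meanpos),
        params=params,
        grid=grid,
    )


def _scenario_liquid(seed, *, gamma=5.0, n_cells=3000, t_end=300.0):
    """Attractant-secreting cells in liquid: aggregation from a uniform lawn.

    The secretion rate is set well inside the chemotactic instability region
    of the linearised system (growth rate sigma(k) = k^2 * (chi*n0*gamma /
    (D_s*k^2 + mu) - D_n) > 0 with ~18 s e-folding at the domain-scale mode),
    so aggregates emerge from shot noise within the run; gamma = 0 is the
    stable control.
    """
    params = AgentParams(dim=2, gamma0=0.1)
    grid = FieldGrid(
        shape=(50, 50), dx=20.0, D_s=100.0, gamma=gamma, mu=0.01, bc="periodic"
    )
    return simulate_coupled(
        params, grid, n_cells=n_cells, t_end=t_end, dt=0.02, seed=seed
    )


def _scenario_swarm_ring(seed, *, n_cells=3000, t_end=300.0):
    """Inoculum consuming nutrient and secreting attractant: expanding ring."""
    params = AgentParams(dim=2, gamma0=0.1)
    grid = FieldGrid(
        shape=(60, 60), dx=25.0, D_s=100.0, D_f=200.0,
        gamma=0.5, k=0.05, mu=0.02, bc="noflux",
    )
    grid.F = np.ones(grid.shape)
    rng = np.random.default_rng(seed)
    center = grid.extent / 2.0
    x0 = center + rng.normal(scale=60.0, size=(n_cells, 2))
    return simulate_coupled(
        params, grid, n_cells=n_cells, t_end=t_end, dt=0.02,
        seed=seed, x0=x0, bc_cells="reflecting",
    )


def _scenario_adler(seed, *, n_cells=4000, t_end=400.0):
    """Consumed-signal travelling band: S(x,0) = 1, cells eat it and chase
    the receding front at an asymptotically constant speed."""
    params = AgentParams(dim=1, gamma0=0.05, G=lambda s: s)
    grid = FieldGrid(
        shape=(200,), dx=25.0, D_s=200.0, gamma=0.004,
        bc="noflux", consumed_signal=True, S=np.ones(200),
    )
    rng = np.random.default_rng(seed)
    x0 = np.abs(rng.normal(scale=150.0, size=(n_cells, 1)))
    return simulate_coupled(
        params, grid, n_cells=n_cells, t_end=t_end, dt=0.02,
        seed=seed, x0=x0, bc_cells="reflecting", n_snapshots=40,
    )


def _scenario_spiral(seed, *, n_cells=3000, t_end=300.0):
    """Surface swimming with clockwise angular bias: spiral streams."""
    params = AgentParams(dim=2, gamma0=0.1, omega=0.3)
    grid = FieldGrid(
        shape=(50, 50), dx=20.0, D_s=100.0, gamma=1.0, mu=0.01, bc="periodic"
    )
    return simulate_coupled(
        params, grid, n_cells=n_cells, t_end=t_end, dt=0.02, seed=seed
    )


SCENARIOS: dict[str, Callable] = {
    "liquid_aggregation": _scenario_liquid,
    "swarm_ring": _scenario_swarm_ring,
    "adler_band": _scenario_adler,
    "spiral_streams": _scenario_spiral,
}


def run_pattern_scenario(name: str, seed: int | None = 0, **overrides) -> PatternResult:
    """Run one of the named coupled pattern-formation scenarios."""
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}"
        )
    return SCENARIOS[name](seed, **overrides)
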