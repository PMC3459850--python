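"""Population state containers and initial-condition constructors.

The population is stored struct-of-arrays for speed: positions, orientations
and clock phases are flat ``float64`` arrays indexed by agent.  Wrapped
coordinates (inside the domain) drive all geometry; unwrapped coordinates
(``xu``, ``yu``) accumulate true displacement for trajectory statistics such
as the mean-square displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import TWO_PI, wrap_angle
from .params import ConfigError, ModelParams, RandomSource

__all__ = ["AgentState", "RegionMap", "SimulationState",
           "init_uniform_population", "init_two_region_population"]


@dataclass(frozen=True)
class AgentState:
    """Read-only single-agent view (id, centre position, orientation, phase)."""

    id: int
    x: float
    y: float
    theta: float
    phi: float


@dataclass(frozen=True)
class RegionMap:
    """Piecewise-constant signaling probability over x.

    ``edges`` are the interior region boundaries (sorted, µm); region ``k``
    is the half-open interval [edges[k-1], edges[k]) and carries
    ``p0_values[k]``.  An agent belongs to the region containing its centre.
    """

    edges: np.ndarray
    p0_values: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        vals = np.asarray(self.p0_values, dtype=float)
        if edges.ndim != 1 or vals.ndim != 1 or len(vals) != len(edges) + 1:
            raise ValueError("RegionMap needs len(p0_values) == len(edges) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("RegionMap edges must be strictly increasing")
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("RegionMap p0 values must be probabilities in [0, 1]")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "p0_values", vals)

    def lookup(self, x) -> np.ndarray:
        """p0 of the region containing each x (half-open [lo, hi) intervals)."""
        idx = np.searchsorted(self.edges, np.asarray(x, dtype=float), side="right")
        return self.p0_values[idx]


@dataclass
class SimulationState:
    """Mutable population state at simulated time ``t`` (minutes)."""

    t: float
    params: ModelParams
    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    xu: np.ndarray = None  # unwrapped coordinates
    yu: np.ndarray = None
    responsive: np.ndarray = None  # False ⇒ tracer: never reverses on signal
    region_map: Optional[RegionMap] = None
    # number of π-boundaries each phase crossed in the step just advanced;
    # set by advance_phases, consumed by apply_spontaneous_reversals
    half_cycles_crossed: Optional[np.ndarray] = None

    def __post_init__(self):
        n = len(self.ids)
        for name in ("x", "y", "theta", "phi"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"state array {name!r} length mismatch")
        if self.xu is None:
            self.xu = self.x.copy()
        if self.yu is None:
            self.yu = self.y.copy()
        if self.responsive is None:
            self.responsive = np.ones(n, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.ids)

    def agent(self, i: int) -> AgentState:
        return AgentState(int(self.ids[i]), float(self.x[i]), float(self.y[i]),
                          float(self.theta[i]), float(self.phi[i]))

    def p0_of(self, x) -> np.ndarray:
        """Signaling probability at position(s) x (region-dependent if set)."""
        if self.region_map is None:
            return np.full(np.shape(x), self.params.step_p0, dtype=float)
        return self.region_map.lookup(x)

    def copy(self) -> "SimulationState":
        return SimulationState(
            t=self.t, params=self.params, ids=self.ids.copy(),
            x=self.x.copy(), y=self.y.copy(), theta=self.theta.copy(),
            phi=self.phi.copy(), xu=self.xu.copy(), yu=self.yu.copy(),
            responsive=self.responsive.copy(), region_map=self.region_map,
            half_cycles_crossed=None if self.half_cycles_crossed is None
            else self.half_cycles_crossed.copy())


def _nematic_orientations(n: int, spread: float, rng: RandomSource) -> np.ndarray:
    """Orientations near the x-axis: θ ∈ {≈0, ≈π} with equal probability."""
    base = np.where(rng.uniform(0.0, 1.0, size=n) < 0.5, 0.0, np.pi)
    return wrap_angle(base + rng.normal(size=n, scale=spread))


# Rippling M. xanthus swarms are multilayered; the 2-D model projects the
# stack onto the plane, so the footprint coverage n·L·w/A may exceed 1.
MAX_LAYERS = 4.0


def _check_density(params: ModelParams) -> None:
    if params.n_agents * params.L * params.w > MAX_LAYERS * params.domain_x * params.domain_y:
        raise ConfigError(
            "n_agents: population exceeds the hard-packing bound of a "
            f"{MAX_LAYERS:g}-layer swarm (n·L·w = "
            f"{params.n_agents * params.L * params.w:g} µm² > {MAX_LAYERS:g}× domain area "
            f"{params.domain_x * params.domain_y:g} µm²)")


def init_uniform_population(params: ModelParams, rng: RandomSource) -> SimulationState:
    """Uniformly distributed, nematically x-aligned population with random phases."""
    _check_density(params)
    n = params.n_agents
    x = rng.uniform(0.0, params.domain_x, size=n)
    y = rng.uniform(0.0, params.domain_y, size=n)
    theta = _nematic_orientations(n, params.init_angle_spread, rng)
    phi = rng.uniform(0.0, TWO_PI, size=n)
    return SimulationState(t=0.0, params=params, ids=np.arange(n, dtype=np.int64),
                           x=x, y=y, theta=theta, phi=phi)


def init_two_region_population(params: ModelParams, strip_half_width: float,
                               p0_left: float, p0_right: float,
                               rng: RandomSource) -> SimulationState:
    """Agents seeded in a central x-strip of a two-region (prey / no-prey) domain.

    The signaling probability is ``p0_left`` for x below the domain midline
    and ``p0_right`` at and above it (half-open [lo, hi) region convention,
    decided by the agent centre).  Requires the open-x boundary so the
    population can expand in both directions.
    """
    if params.boundary != "open-x":
        raise ConfigError("boundary: init_two_region_population requires boundary='open-x'")
    cx = params.domain_x / 2.0
    if strip_half_width <= 0 or cx - strip_half_width < 0 or cx + strip_half_width > params.domain_x:
        raise ConfigError(
            f"strip_half_width: central strip ±{strip_half_width:g} µm must fit in "
            f"domain_x = {params.domain_x:g} µm")
    if params.n_agents * params.L * params.w > 2 * strip_half_width * params.domain_y:
        raise ConfigError("n_agents: population exceeds the hard-packing bound of the strip")
    n = params.n_agents
    x = rng.uniform(cx - strip_half_width, cx + strip_half_width, size=n)
    y = rng.uniform(0.0, params.domain_y, size=n)
    theta = _nematic_orientations(n, params.init_angle_spread, rng)
    phi = rng.uniform(0.0, TWO_PI, size=n)
    region = RegionMap(edges=np.array([cx]), p0_values=np.array([p0_left, p0_right]))
    return SimulationState(t=0.0, params=params, ids=np.arange(n, dtype=np.int64),
                           x=x, y=y, theta=theta, phi=phi, region_map=region)
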