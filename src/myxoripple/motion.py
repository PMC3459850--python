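"""Agent translation and the noisy reversal phase clock.

Each agent carries an internal phase φ ∈ [0, 2π) advancing at mean speed ω
with Gaussian (Euler–Maruyama) fluctuations of variance 2·D_phi·dt per step.
Crossing either half-cycle boundary (π or 2π) flips the agent's orientation
by 180° — a *spontaneous* reversal.  Noise alone is never allowed to carry a
phase backwards across the boundary it last crossed, so jitter near π / 2π
cannot double-trigger reversals: the phase is clamped at that boundary.

Positions advance by v·dt along the orientation plus isotropic Gaussian
noise of per-axis variance 2·D·dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .geometry import TWO_PI, wrap_angle
from .params import RandomSource
from .state import SimulationState

__all__ = ["ReversalEvent", "EventBatch", "advance_positions", "advance_phases",
           "apply_spontaneous_reversals"]

CAUSE_SPONTANEOUS = "spontaneous"
CAUSE_INDUCED = "induced"


@dataclass(frozen=True)
class ReversalEvent:
    """A single polarity switch: when, where, whose, and why."""

    agent_id: int
    t: float
    x: float
    y: float
    cause: str  # "spontaneous" or "induced"


class EventBatch:
    """Column-oriented batch of reversal events from one step (or one run)."""

    __slots__ = ("agent_id", "t", "x", "y", "cause")

    def __init__(self, agent_id=None, t=None, x=None, y=None, cause=None):
        self.agent_id = np.asarray(agent_id if agent_id is not None else [], dtype=np.int64)
        self.t = np.asarray(t if t is not None else [], dtype=float)
        self.x = np.asarray(x if x is not None else [], dtype=float)
        self.y = np.asarray(y if y is not None else [], dtype=float)
        self.cause = np.asarray(cause if cause is not None else [], dtype=object)

    def __len__(self) -> int:
        return len(self.agent_id)

    def __iter__(self):
        for i in range(len(self)):
            yield ReversalEvent(int(self.agent_id[i]), float(self.t[i]),
                                float(self.x[i]), float(self.y[i]), str(self.cause[i]))

    @classmethod
    def concat(cls, batches: List["EventBatch"]) -> "EventBatch":
        batches = [b for b in batches if len(b)]
        if not batches:
            return cls()
        return cls(np.concatenate([b.agent_id for b in batches]),
                   np.concatenate([b.t for b in batches]),
                   np.concatenate([b.x for b in batches]),
                   np.concatenate([b.y for b in batches]),
                   np.concatenate([b.cause for b in batches]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t_min": self.t, "agent_id": self.agent_id,
                             "x_um": self.x, "y_um": self.y, "cause": self.cause})


def advance_positions(state: SimulationState, rng: RandomSource) -> SimulationState:
    """Displace agents by v·dt along their orientation plus positional noise.

    Mutates ``state`` in place (and returns it).  Periodic boundaries wrap
    both axes; the open-x boundary wraps y only.  Unwrapped coordinates
    accumulate the raw displacements.
    """
    p = state.params
    n = state.n
    sigma = np.sqrt(2.0 * p.D * p.dt)
    dx = p.v * p.dt * np.cos(state.theta)
    dy = p.v * p.dt * np.sin(state.theta)
    if sigma > 0:
        dx = dx + rng.normal(size=n, scale=sigma)
        dy = dy + rng.normal(size=n, scale=sigma)
    state.xu += dx
    state.yu += dy
    state.x += dx
    state.y += dy
    state.y %= p.domain_y
    if p.boundary == "periodic":
        state.x %= p.domain_x
    return state


def advance_phases(state: SimulationState, rng: RandomSource) -> SimulationState:
    """Advance phases by ω·dt plus clock noise, with boundary clamping.

    The clamp: an agent whose phase sits in [0, π) most recently crossed the
    2π→0 boundary, one in [π, 2π) most recently crossed π; a noise draw that
    would move the phase back below that boundary leaves it exactly at the
    boundary instead.  The number of half-cycle boundaries crossed this step
    is recorded on the state for the reversal bookkeeping (crossings are
    detected on the unwrapped per-step increment, so wrapping at 2π is
    harmless).
    """
    p = state.params
    n = state.n
    dphi = np.full(n, p.omega * p.dt)
    if p.D_phi > 0:
        dphi = dphi + rng.normal(size=n, scale=np.sqrt(2.0 * p.D_phi * p.dt))
    last_boundary = np.where(state.phi >= np.pi, np.pi, 0.0)
    unwrapped = np.maximum(state.phi + dphi, last_boundary)
    crossed = (np.floor(unwrapped / np.pi) - np.floor(state.phi / np.pi)).astype(np.int64)
    state.phi = np.mod(unwrapped, TWO_PI)
    state.half_cycles_crossed = crossed
    return state


def apply_spontaneous_reversals(state: SimulationState) -> Tuple[SimulationState, EventBatch]:
    """Flip orientation of every agent whose phase crossed π or 2π this step.

    Requires :func:`advance_phases` to have run in the current step.  Each
    crossing yields one spontaneous :class:`ReversalEvent`; the crossing
    counter is consumed.
    """
    if state.half_cycles_crossed is None:
        raise RuntimeError("apply_spontaneous_reversals: phases not advanced this step")
    crossed = state.half_cycles_crossed
    state.half_cycles_crossed = None
    idx = np.nonzero(crossed > 0)[0]
    if len(idx) == 0:
        return state, EventBatch()
    # a step can in principle span multiple boundaries; every crossing flips,
    # so only an odd number of crossings changes the orientation
    odd = idx[(crossed[idx] % 2) == 1]
    state.theta[odd] = wrap_angle(state.theta[odd] + np.pi)
    events = EventBatch(agent_id=state.ids[idx], t=np.full(len(idx), state.t),
                        x=state.x[idx], y=state.y[idx],
                        cause=np.full(len(idx), CAUSE_SPONTANEOUS, dtype=object))
    return state, events
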