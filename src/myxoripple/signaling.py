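"""Side-to-side contact detection, stochastic signaling, and induced reversals.

Two gliding rods can exchange a reversal-inducing signal when they make
side-to-side contact: orientations antiparallel within ``dtheta0``,
perpendicular centre separation at most one cell width, and long axes
overlapping by at least ``overlap_frac``·L (equivalently, centre separation
along the mean axis at most (1 − overlap_frac)·L).  Each *ordered* pair in
contact fires independently with probability ``p0`` per time step; a firing
of (i → j) affects only j.  A signaled agent reverses unless its phase clock
is inside the refractory sector φ0 past the last reversal boundary; a
refractory agent ignores the signal but can still signal others.

Rule variants (used for the model-ablation comparisons) select which
relative orientation can signal, and whether one event reverses both
partners (``counter_symmetric``) or the two directions are independent
(``counter_asymmetric``, the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .alignment import NeighborIndex
from .geometry import min_image, signed_angle_diff, wrap_angle
from .motion import CAUSE_INDUCED, EventBatch
from .params import RandomSource
from .state import SimulationState

__all__ = ["ContactPair", "ContactPairs", "SignalingEvents", "find_contact_pairs",
           "sample_signaling_events", "apply_induced_reversals"]


@dataclass(frozen=True)
class ContactPair:
    """One ordered signaling-capable contact: source can signal target."""

    source_id: int
    target_id: int
    d_par: float   # centre separation along the pair's mean axis, µm
    d_perp: float  # perpendicular centre separation, µm
    dtheta: float  # angular deviation from the rule's reference alignment, rad


class ContactPairs:
    """Column-oriented batch of ordered contact pairs from one step.

    Both orderings of a geometric pair are present and share an entry of
    ``pair_index`` (the unordered-pair label used by symmetric signaling).
    """

    __slots__ = ("source", "target", "d_par", "d_perp", "dtheta", "pair_index")

    def __init__(self, source, target, d_par, d_perp, dtheta, pair_index):
        self.source = np.asarray(source, dtype=np.int64)
        self.target = np.asarray(target, dtype=np.int64)
        self.d_par = np.asarray(d_par, dtype=float)
        self.d_perp = np.asarray(d_perp, dtype=float)
        self.dtheta = np.asarray(dtheta, dtype=float)
        self.pair_index = np.asarray(pair_index, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.source)

    def __iter__(self):
        for k in range(len(self)):
            yield ContactPair(int(self.source[k]), int(self.target[k]),
                              float(self.d_par[k]), float(self.d_perp[k]),
                              float(self.dtheta[k]))

    @property
    def n_unordered(self) -> int:
        return 0 if len(self) == 0 else int(self.pair_index.max()) + 1

    @classmethod
    def empty(cls) -> "ContactPairs":
        z: list = []
        return cls(z, z, z, z, z, z)


class SignalingEvents:
    """Ordered signaling events sampled from the contact pairs of one step."""

    __slots__ = ("source", "target")

    def __init__(self, source, target):
        self.source = np.asarray(source, dtype=np.int64)
        self.target = np.asarray(target, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.source)


def find_contact_pairs(state: SimulationState,
                       idx: Optional[NeighborIndex] = None) -> ContactPairs:
    """All ordered side-to-side contacts under the configured signaling rule.

    Geometry (per unordered candidate pair, minimum-image on periodic axes):

    * orientation test — deviation from antiparallel (default rule) or from
      parallel at most ``dtheta0``;
    * mean axis ê — normalised difference u₁ − u₂ of the unit orientation
      vectors for near-antiparallel pairs (sum for near-parallel ones);
    * d_par = |r·ê| ≤ (1 − overlap_frac)·L and d_perp = |r·ê⊥| ≤ w.

    The geometric test is symmetric, so both orderings are returned whenever
    it passes.  Without a prebuilt :class:`NeighborIndex` an exact O(N²)
    candidate set is used.
    """
    p = state.params
    if idx is None:
        idx = NeighborIndex.build_brute_force(state)
    cand = idx.contact_candidates
    if len(cand) == 0:
        return ContactPairs.empty()
    i, j = cand[:, 0], cand[:, 1]
    anti_dev = np.abs(signed_angle_diff(state.theta[i] - state.theta[j], np.pi))
    para_dev = np.abs(signed_angle_diff(state.theta[i] - state.theta[j], 0.0))
    rule = p.signaling_rule
    if rule in ("counter_asymmetric", "counter_symmetric"):
        use_anti = anti_dev <= p.dtheta0
        use_para = np.zeros_like(use_anti)
    elif rule == "same_direction":
        use_anti = np.zeros(len(cand), dtype=bool)
        use_para = para_dev <= p.dtheta0
    else:  # any_direction
        use_anti = anti_dev <= p.dtheta0
        use_para = (para_dev <= p.dtheta0) & ~use_anti
    keep = use_anti | use_para
    if not np.any(keep):
        return ContactPairs.empty()
    i, j = i[keep], j[keep]
    anti = use_anti[keep]
    dev = np.where(anti, anti_dev[keep], para_dev[keep])

    ui = np.column_stack([np.cos(state.theta[i]), np.sin(state.theta[i])])
    uj = np.column_stack([np.cos(state.theta[j]), np.sin(state.theta[j])])
    axis = np.where(anti[:, None], ui - uj, ui + uj)
    norm = np.linalg.norm(axis, axis=1)
    # deviation ≤ dtheta0 < π/2 keeps the mean-axis vector well away from 0
    axis /= norm[:, None]
    rx = min_image(state.x[j] - state.x[i], p.domain_x)
    ry = min_image(state.y[j] - state.y[i], p.domain_y)
    d_par = np.abs(rx * axis[:, 0] + ry * axis[:, 1])
    d_perp = np.abs(-rx * axis[:, 1] + ry * axis[:, 0])
    ok = (d_perp <= p.w) & (d_par <= (1.0 - p.overlap_frac) * p.L)
    if not np.any(ok):
        return ContactPairs.empty()
    i, j = i[ok], j[ok]
    d_par, d_perp, dev = d_par[ok], d_perp[ok], dev[ok]
    m = len(i)
    pair_index = np.arange(m, dtype=np.int64)
    return ContactPairs(
        source=np.concatenate([state.ids[i], state.ids[j]]),
        target=np.concatenate([state.ids[j], state.ids[i]]),
        d_par=np.tile(d_par, 2), d_perp=np.tile(d_perp, 2),
        dtheta=np.tile(dev, 2), pair_index=np.tile(pair_index, 2))


def sample_signaling_events(pairs: ContactPairs, state: SimulationState,
                            rng: RandomSource) -> SignalingEvents:
    """Bernoulli-sample which ordered contacts fire this step.

    Each ordered pair fires with the signaling probability of the *target*
    agent's region (region-dependent p0 in two-region scenarios).  Under the
    ``counter_symmetric`` rule the two orderings of a geometric pair share
    one uniform draw, so a single event fires both directions at once.
    """
    m = len(pairs)
    if m == 0:
        return SignalingEvents([], [])
    # targets are ids; ids equal row indices for engine-constructed states
    tpos = pairs.target
    p_fire = state.p0_of(state.x[tpos])
    if state.params.signaling_rule == "counter_symmetric":
        u_unordered = rng.uniform(0.0, 1.0, size=pairs.n_unordered)
        u = u_unordered[pairs.pair_index]
    else:
        u = rng.uniform(0.0, 1.0, size=m)
    fired = u < p_fire
    return SignalingEvents(pairs.source[fired], pairs.target[fired])


def apply_induced_reversals(state: SimulationState, events: SignalingEvents,
                            rng: RandomSource) -> Tuple[SimulationState, EventBatch]:
    """Reverse signaled agents that are outside their refractory sector.

    The phase distance past the last reversal boundary is φ mod π; an agent
    is responsive when that distance is at least φ0 = ω·T0.  A reversal flips
    the orientation by π and advances the phase to the next half-cycle
    boundary (π or 2π→0), so the full refractory sector elapses again before
    the agent can respond to another signal.  Multiple same-step signals to
    one agent cause at most one reversal (targets processed in ascending
    (target_id, source_id) order); refractory or non-responsive (tracer)
    targets are unchanged but remain eligible as sources.  ``rng`` is part of
    the update-step interface; this sub-update draws no random numbers.
    """
    del rng
    p = state.params
    if len(events) == 0:
        return state, EventBatch()
    order = np.lexsort((events.source, events.target))
    targets = events.target[order]
    first = np.ones(len(targets), dtype=bool)
    first[1:] = targets[1:] != targets[:-1]
    targets = targets[first]
    elapsed = np.mod(state.phi[targets], np.pi)
    responsive = state.responsive[targets] & (elapsed >= p.phi0)
    rev = targets[responsive]
    if len(rev) == 0:
        return state, EventBatch()
    state.theta[rev] = wrap_angle(state.theta[rev] + np.pi)
    state.phi[rev] = np.where(state.phi[rev] < np.pi, np.pi, 0.0)
    events_out = EventBatch(agent_id=state.ids[rev], t=np.full(len(rev), state.t),
                            x=state.x[rev], y=state.y[rev],
                            cause=np.full(len(rev), CAUSE_INDUCED, dtype=object))
    return state, events_out
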