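"""Neighbor indexing and local nematic alignment.

Rod-shaped cells glide in dense groups and physically align head–tail
symmetrically (nematically): θ and θ+π are equivalent axes.  Each agent's
orientation relaxes toward the nematic mean axis of the neighbors whose
centres fall in an axis-aligned square of side ``neighbor_box`` centred on
it, with correlation time ``tau_theta`` and Gaussian orientation noise of
variance 2·D_theta·dt, via an unconditionally stable implicit update solved
by fixed-point iteration.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import min_image, nematic_diff, wrap_angle
from .params import RandomSource
from .state import SimulationState

__all__ = ["NeighborIndex", "neighbor_mean_orientation", "relax_orientations"]


class NeighborIndex:
    """Per-step spatial index of agent pairs.

    Holds two pair sets computed from one k-d-tree pass:

    * ``align_pairs`` — unordered pairs whose centres fall in each other's
      square alignment neighborhood (Chebyshev distance ≤ neighbor_box/2,
      minimum-image convention on periodic axes);
    * ``contact_candidates`` — unordered pairs within the larger candidate
      radius that the side-to-side contact test needs
      (√((1−overlap_frac)²L² + w²)).

    The relation is symmetric and excludes self-pairs.
    """

    def __init__(self, align_pairs: np.ndarray, contact_candidates: np.ndarray, n: int):
        self.align_pairs = align_pairs.reshape(-1, 2)
        self.contact_candidates = contact_candidates.reshape(-1, 2)
        self.n = n
        self._adjacency: Optional[list] = None

    # -- construction ----------------------------------------------------
    @classmethod
    def build(cls, state: SimulationState) -> "NeighborIndex":
        """Grid-accelerated build (k-d tree, exact; periodic minimum image)."""
        p = state.params
        half_box = p.neighbor_box / 2.0
        r_contact = np.hypot((1.0 - p.overlap_frac) * p.L, p.w)
        # Chebyshev ball of this radius covers the square alignment box
        # exactly and contains the Euclidean contact-candidate disc
        r_query = max(half_box, r_contact)
        pts = np.column_stack([np.mod(state.x, p.domain_x), np.mod(state.y, p.domain_y)])
        # Both boundary modes use a toroidal tree; open-x scenarios keep a
        # guaranteed empty margin at the x-edges (enforced by the engine), so
        # the x-wraparound can never create spurious neighbors.
        tree = cKDTree(pts, boxsize=[p.domain_x, p.domain_y])
        pairs = tree.query_pairs(r_query, p=np.inf, output_type="ndarray")
        if len(pairs) == 0:
            empty = np.empty((0, 2), dtype=np.int64)
            return cls(empty, empty, state.n)
        dx = min_image(pts[pairs[:, 1], 0] - pts[pairs[:, 0], 0], p.domain_x)
        dy = min_image(pts[pairs[:, 1], 1] - pts[pairs[:, 0], 1], p.domain_y)
        in_box = (np.abs(dx) <= half_box) & (np.abs(dy) <= half_box)
        in_contact = dx * dx + dy * dy <= r_contact * r_contact
        return cls(pairs[in_box], pairs[in_contact], state.n)

    @classmethod
    def build_brute_force(cls, state: SimulationState) -> "NeighborIndex":
        """O(N²) reference construction (test oracle for the grid build)."""
        p = state.params
        half_box = p.neighbor_box / 2.0
        r_contact = np.hypot((1.0 - p.overlap_frac) * p.L, p.w)
        x = np.mod(state.x, p.domain_x)
        y = np.mod(state.y, p.domain_y)
        dx = min_image(x[None, :] - x[:, None], p.domain_x)
        dy = min_image(y[None, :] - y[:, None], p.domain_y)
        upper = np.triu(np.ones((state.n, state.n), dtype=bool), k=1)
        in_box = upper & (np.abs(dx) <= half_box) & (np.abs(dy) <= half_box)
        in_contact = upper & (dx * dx + dy * dy <= r_contact * r_contact)
        ab = np.argwhere(in_box)
        cc = np.argwhere(in_contact)
        return cls(ab.astype(np.int64), cc.astype(np.int64), state.n)

    # -- queries ----------------------------------------------------------
    def neighbors_of(self, i: int) -> np.ndarray:
        """Sorted alignment-neighbor ids of agent ``i``."""
        if self._adjacency is None:
            adj = [[] for _ in range(self.n)]
            for a, b in self.align_pairs:
                adj[a].append(b)
                adj[b].append(a)
            self._adjacency = [np.array(sorted(v), dtype=np.int64) for v in adj]
        return self._adjacency[i]

    def neighbor_counts(self) -> np.ndarray:
        counts = np.zeros(self.n, dtype=np.int64)
        if len(self.align_pairs):
            np.add.at(counts, self.align_pairs[:, 0], 1)
            np.add.at(counts, self.align_pairs[:, 1], 1)
        return counts


def _nematic_neighbor_sums(theta: np.ndarray, pairs: np.ndarray, n: int,
                           ij=None):
    """Per-agent sums of cos 2θ and sin 2θ over alignment neighbors."""
    if len(pairs) == 0:
        z = np.zeros(n)
        return z, z.copy(), np.zeros(n, dtype=np.int64)
    if ij is None:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        i, j = ij
    c2 = np.cos(2.0 * theta)
    s2 = np.sin(2.0 * theta)
    c = np.bincount(i, weights=c2[j], minlength=n)
    s = np.bincount(i, weights=s2[j], minlength=n)
    counts = np.bincount(i, minlength=n)
    return c, s, counts.astype(np.int64)


def neighbor_mean_orientation(state: SimulationState, idx: NeighborIndex,
                              agent_id: int) -> float:
    """Nematic circular mean of an agent's neighbors, near its own orientation.

    Doubled-angle vector average: ½·atan2(Σ sin 2θ_j, Σ cos 2θ_j), with the
    π-degenerate axis disambiguated to the half-circle nearest the focal
    agent's current orientation.  An agent without neighbors returns its own
    orientation.
    """
    i = int(np.nonzero(state.ids == agent_id)[0][0])
    nbrs = idx.neighbors_of(i)
    if len(nbrs) == 0:
        return float(state.theta[i])
    c = float(np.sum(np.cos(2.0 * state.theta[nbrs])))
    s = float(np.sum(np.sin(2.0 * state.theta[nbrs])))
    axis = 0.5 * np.arctan2(s, c)
    return float(wrap_angle(state.theta[i] + nematic_diff(axis, state.theta[i])))


def relax_orientations(state: SimulationState, idx: NeighborIndex,
                       rng: RandomSource, tol: float = 1e-6,
                       max_iter: int = 20) -> SimulationState:
    """Implicitly relax orientations toward the local nematic mean, with noise.

    Discretises dθ/dt = (⟨θ⟩ − θ)/τ_θ + noise implicitly:
    θ(t+dt) = (θ(t) + (dt/τ_θ)·⟨θ⟩(t+dt) + η)/(1 + dt/τ_θ),
    where ⟨θ⟩ is the neighbors' nematic mean mapped onto the half-circle
    nearest θ(t) and η ~ N(0, 2·D_theta·dt).  The coupled system is solved
    by fixed-point iteration (tolerance ``tol`` rad, at most ``max_iter``
    sweeps); non-convergence falls back to the last iterate with a warning.
    Agents without neighbors rotate by pure noise.  Mutates in place.
    """
    p = state.params
    n = state.n
    a = p.dt / p.tau_theta
    noise = rng.normal(size=n, scale=np.sqrt(2.0 * p.D_theta * p.dt)) \
        if p.D_theta > 0 else np.zeros(n)
    theta0 = state.theta
    theta_iter = theta0.copy()
    converged = False
    counts = None
    if len(idx.align_pairs):
        ij = (np.concatenate([idx.align_pairs[:, 0], idx.align_pairs[:, 1]]),
              np.concatenate([idx.align_pairs[:, 1], idx.align_pairs[:, 0]]))
    else:
        ij = None
    for _ in range(max_iter):
        c, s, counts = _nematic_neighbor_sums(theta_iter, idx.align_pairs, n, ij=ij)
        has_nbr = counts > 0
        axis = 0.5 * np.arctan2(s, c)
        delta = np.where(has_nbr, nematic_diff(axis, theta0), 0.0)
        theta_new = np.where(has_nbr,
                             theta0 + (a * delta + noise) / (1.0 + a),
                             theta0 + noise)
        if np.max(np.abs(theta_new - theta_iter)) < tol:
            theta_iter = theta_new
            converged = True
            break
        theta_iter = theta_new
    if not converged:
        warnings.warn("relax_orientations: implicit update did not converge to "
                      f"{tol:g} rad in {max_iter} iterations; using last iterate",
                      RuntimeWarning, stacklevel=2)
    state.theta = wrap_angle(theta_iter)
    return state
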