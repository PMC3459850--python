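"""Contact geometry, stochastic signaling, and refractory-gated reversals."""

import math

import numpy as np
import pytest

import myxoripple as mx
from myxoripple.alignment import NeighborIndex
from myxoripple.signaling import (apply_induced_reversals, find_contact_pairs,
                                  sample_signaling_events, SignalingEvents)
from myxoripple.state import SimulationState


def make_state(params, xs, ys, thetas, phis=None):
    n = len(xs)
    phis = phis if phis is not None else np.full(n, 2.0)
    return SimulationState(t=0.0, params=params,
                           ids=np.arange(n, dtype=np.int64),
                           x=np.asarray(xs, float), y=np.asarray(ys, float),
                           theta=np.asarray(thetas, float),
                           phi=np.asarray(phis, float))


@pytest.fixture()
def geom_params():
    return mx.ModelParams(n_agents=2, L=7.0, w=0.5, domain_x=100.0, domain_y=50.0)


class TestContactGeometry:
    def test_canonical_antiparallel_contact(self, geom_params):
        # overlap 5 um (>= L/2), lateral offset 0.3 <= w, perfectly antiparallel
        st = make_state(geom_params, [10.0, 12.0], [10.0, 10.3], [0.0, np.pi])
        pairs = find_contact_pairs(st)
        assert len(pairs) == 2  # both orderings
        pair = next(iter(pairs))
        assert pair.d_par == pytest.approx(2.0)
        assert pair.d_perp == pytest.approx(0.3)
        assert pair.dtheta == pytest.approx(0.0)
        assert {(q.source_id, q.target_id) for q in pairs} == {(0, 1), (1, 0)}

    @pytest.mark.parametrize("dx,dy,th2,expect", [
        (2.0, 0.3, np.pi, True),
        (2.0, 0.7, np.pi, False),        # lateral separation beyond one width
        (4.0, 0.3, np.pi, False),        # overlap below half a length
        (2.0, 0.3, np.pi - 0.4, False),  # angular deviation beyond 15 deg
        (0.0, 0.0, 0.0, False),          # co-moving, superimposed: no signal
        (3.49, 0.0, np.pi, True),        # boundary of the overlap criterion
    ])
    def test_threshold_conditions(self, geom_params, dx, dy, th2, expect):
        st = make_state(geom_params, [10.0, 10.0 + dx], [10.0, 10.0 + dy], [0.0, th2])
        assert (len(find_contact_pairs(st)) == 2) is expect

    def test_geometric_symmetry_both_orderings(self, geom_params):
        rng = mx.RandomSource(0)
        p = geom_params.replace(n_agents=40)
        st = make_state(p, rng.uniform(0, 100, 40), rng.uniform(0, 50, 40),
                        rng.uniform(0, 2 * np.pi, 40))
        pairs = find_contact_pairs(st)
        ordered = {(q.source_id, q.target_id) for q in pairs}
        assert all((b, a) in ordered for a, b in ordered)

    def test_periodic_wraparound_contact(self, geom_params):
        st = make_state(geom_params, [0.5, 99.5], [10.0, 10.2], [0.0, np.pi])
        assert len(find_contact_pairs(st)) == 2

    def test_grid_equals_brute_force(self):
        # grid-accelerated candidate set reproduces the O(N^2) oracle exactly
        p = mx.ModelParams(n_agents=500, domain_x=200.0, domain_y=100.0)
        st = mx.init_uniform_population(p, mx.RandomSource(77))
        fast = find_contact_pairs(st, NeighborIndex.build(st))
        slow = find_contact_pairs(st, NeighborIndex.build_brute_force(st))
        key = lambda pr: {(q.source_id, q.target_id) for q in pr}
        assert key(fast) == key(slow)


class TestRuleVariants:
    def co_and_counter_state(self, p):
        # pair 0-1 counter-moving, pair 2-3 co-moving; both in side contact
        return make_state(p.replace(n_agents=4),
                          [10.0, 12.0, 30.0, 32.0], [10.0, 10.3, 10.0, 10.3],
                          [0.0, np.pi, 0.0, 0.0])

    def test_counter_rules_exclude_co_moving(self, geom_params):
        st = self.co_and_counter_state(geom_params)
        ids = {(q.source_id, q.target_id) for q in find_contact_pairs(st)}
        assert ids == {(0, 1), (1, 0)}

    def test_same_direction_rule(self, geom_params):
        p = geom_params.replace(signaling_rule="same_direction")
        st = self.co_and_counter_state(p)
        ids = {(q.source_id, q.target_id) for q in find_contact_pairs(st)}
        assert ids == {(2, 3), (3, 2)}

    def test_any_direction_rule(self, geom_params):
        p = geom_params.replace(signaling_rule="any_direction")
        st = self.co_and_counter_state(p)
        ids = {(q.source_id, q.target_id) for q in find_contact_pairs(st)}
        assert ids == {(0, 1), (1, 0), (2, 3), (3, 2)}

    def test_symmetric_rule_fires_both_directions_together(self, geom_params):
        p = geom_params.replace(signaling_rule="counter_symmetric", p0=0.5)
        st = self.co_and_counter_state(p)
        pairs = find_contact_pairs(st)
        for seed in range(40):
            ev = sample_signaling_events(pairs, st, mx.RandomSource(seed))
            fired = set(zip(ev.source.tolist(), ev.target.tolist()))
            assert ((0, 1) in fired) == ((1, 0) in fired)


class TestSampling:
    @pytest.fixture()
    def contact_pairs(self, geom_params):
        st = make_state(geom_params, [10.0, 12.0], [10.0, 10.3], [0.0, np.pi])
        return st, find_contact_pairs(st)

    def test_p0_zero_never_fires(self, geom_params):
        p = geom_params.replace(p0=0.0)
        st = make_state(p, [10.0, 12.0], [10.0, 10.3], [0.0, np.pi])
        pairs = find_contact_pairs(st)
        for seed in range(20):
            assert len(sample_signaling_events(pairs, st, mx.RandomSource(seed))) == 0

    def test_p0_one_always_fires(self, geom_params):
        p = geom_params.replace(p0=1.0)
        st = make_state(p, [10.0, 12.0], [10.0, 10.3], [0.0, np.pi])
        pairs = find_contact_pairs(st)
        for seed in range(20):
            assert len(sample_signaling_events(pairs, st, mx.RandomSource(seed))) == 2

    def test_firing_fraction_binomial(self, geom_params):
        # 1e5 ordered-pair step-instances at p0=0.1: binomial oracle, 3 s.e.
        p = geom_params.replace(p0=0.1)
        st = make_state(p, [10.0, 12.0], [10.0, 10.3], [0.0, np.pi])
        pairs = find_contact_pairs(st)
        rng = mx.RandomSource(5)
        n_inst = 50_000  # x2 ordered pairs
        fired = sum(len(sample_signaling_events(pairs, st, rng))
                    for _ in range(n_inst))
        total = 2 * n_inst
        se = math.sqrt(0.1 * 0.9 / total)
        assert fired / total == pytest.approx(0.1, abs=3 * se)

    def test_region_dependent_probability_of_target(self, geom_params):
        p = geom_params.replace(p0=0.5)
        st = make_state(p, [10.0, 12.0], [10.0, 10.3], [0.0, np.pi])
        st.region_map = mx.RegionMap(edges=np.array([11.0]),
                                     p0_values=np.array([0.0, 1.0]))
        pairs = find_contact_pairs(st)
        ev = sample_signaling_events(pairs, st, mx.RandomSource(1))
        # only the agent at x=12 (right region, p0=1) can be signaled
        assert set(ev.target.tolist()) == {1}


class TestInducedReversals:
    def signaled(self, params, phi, responsive=True):
        st = make_state(params, [10.0], [10.0], [0.3], [phi])
        st.responsive[0] = responsive
        ev = SignalingEvents([9], [0])
        return apply_induced_reversals(st, ev, mx.RandomSource(0))

    def test_responsive_target_reverses_and_resets_phase(self, geom_params):
        phi = geom_params.phi0 + 0.1
        st, out = self.signaled(geom_params, phi)
        assert len(out) == 1 and next(iter(out)).cause == "induced"
        assert st.theta[0] == pytest.approx(0.3 + np.pi)
        assert st.phi[0] == pytest.approx(np.pi)  # advanced to the next boundary

    def test_reset_from_second_half_cycle_wraps(self, geom_params):
        st, out = self.signaled(geom_params, np.pi + geom_params.phi0 + 0.1)
        assert len(out) == 1 and st.phi[0] == pytest.approx(0.0)

    def test_refractory_target_unchanged(self, geom_params):
        phi = geom_params.phi0 - 0.1
        st, out = self.signaled(geom_params, phi)
        assert len(out) == 0
        assert st.theta[0] == pytest.approx(0.3) and st.phi[0] == pytest.approx(phi)

    def test_tracer_never_reverses(self, geom_params):
        st, out = self.signaled(geom_params, geom_params.phi0 + 0.5, responsive=False)
        assert len(out) == 0 and st.theta[0] == pytest.approx(0.3)

    def test_at_most_one_reversal_per_step(self, geom_params):
        st = make_state(geom_params, [10.0], [10.0], [0.3], [geom_params.phi0 + 0.2])
        ev = SignalingEvents([5, 7, 9], [0, 0, 0])
        st, out = apply_induced_reversals(st, ev, mx.RandomSource(0))
        assert len(out) == 1
        assert st.theta[0] == pytest.approx(0.3 + np.pi)

    def test_no_double_reversal_within_refractory_time(self):
        # continuously signaled isolated agent: successive reversals are
        # separated by at least (almost all of) the refractory first-passage
        # time; mean matches T0 and SD the configured calibration (0.7 min)
        p = mx.ModelParams(n_agents=1, domain_x=100, domain_y=50, D=0.0,
                           D_theta=0.0)
        st = make_state(p, [10.0], [10.0], [0.0], [0.0])
        rng = mx.RandomSource(42)
        times = []
        from myxoripple.motion import advance_phases, apply_spontaneous_reversals
        for k in range(40_000):
            advance_phases(st, rng)
            st, _ = apply_spontaneous_reversals(st)
            st, out = apply_induced_reversals(
                st, SignalingEvents([1], [0]), rng)
            if len(out):
                times.append(st.t)
            st.t += p.dt
        intervals = np.diff(times)
        assert np.mean(intervals) == pytest.approx(p.T0, rel=0.06)
        assert np.std(intervals) == pytest.approx(0.7, abs=0.12)
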