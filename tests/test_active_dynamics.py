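"""Heading updates, angle arithmetic, the deposition rule, and the
lattice walk."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antraft import active_dynamics as ad
from antraft.core import STRUCT, WATER, SimParams, init_state
from antraft.io_cli import make_fixture
from antraft.simulator import RunConfig, run

TWO_PI = 2 * math.pi


class TestCircularMean:
    @pytest.mark.parametrize("angles,expected", [
        ([1.3], 1.3),
        ([0.0, math.pi / 2], math.pi / 4),
        ([math.pi - 0.1, math.pi + 0.1], math.pi),
    ])
    def test_symmetry_cases(self, angles, expected):
        assert ad.circular_mean(np.array(angles)) == pytest.approx(expected)

    def test_wraparound_beats_arithmetic_mean(self):
        # headings straddling 0 must average to ~0, not ~pi
        m = ad.circular_mean(np.array([0.1, TWO_PI - 0.1]))
        assert min(m, TWO_PI - m) == pytest.approx(0.0, abs=1e-9)

    def test_cancelling_vectors_need_rng(self, rng):
        with pytest.raises(ValueError):
            ad.circular_mean(np.array([0.0, math.pi]))
        m = ad.circular_mean(np.array([0.0, math.pi]), rng)
        assert 0 <= m < TWO_PI

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ad.circular_mean(np.array([]))

    @given(st.lists(st.floats(0, TWO_PI - 1e-9), min_size=1, max_size=20),
           st.floats(-math.pi, math.pi))
    @settings(max_examples=100, deadline=None)
    def test_rotational_equivariance(self, angles, shift):
        a = np.array(angles)
        try:
            m0 = ad.circular_mean(a)
            m1 = ad.circular_mean(np.mod(a + shift, TWO_PI))
        except ValueError:
            return
        d = abs((m1 - m0 - shift) % TWO_PI)
        assert min(d, TWO_PI - d) < 1e-6


class TestAngleArithmetic:
    @pytest.mark.parametrize("xi,xj,expected", [
        ((0, 0), (1, 0), 0.0),
        ((0, 0), (0, -1), 3 * math.pi / 2),
        ((0, 0), (-1, 0), math.pi),
        ((0, 0), (1, 1), math.pi / 4),
    ])
    def test_relative_angle_branches(self, xi, xj, expected):
        assert ad.relative_angle(np.array(xi), np.array(xj)) == \
            pytest.approx(expected)

    def test_relative_angle_coincident_points_error(self):
        with pytest.raises(ValueError):
            ad.relative_angle(np.array([1.0, 1.0]), np.array([1.0, 1.0]))

    @pytest.mark.parametrize("theta,vartheta,expected", [
        (math.pi / 4, math.pi / 4, 0.0),
        (0.0, math.pi, math.pi),
        (0.0, 3 * math.pi / 2, math.pi / 2),
        (0.1, TWO_PI - 0.1, 0.2),
    ])
    def test_angular_difference_branches(self, theta, vartheta, expected):
        assert ad.angular_difference(theta, vartheta) == \
            pytest.approx(expected)

    @given(st.floats(0, TWO_PI - 1e-9), st.floats(0, TWO_PI - 1e-9))
    @settings(max_examples=200, deadline=None)
    def test_angular_difference_matches_brute_force(self, a, b):
        brute = min(abs(a - b), TWO_PI - abs(a - b))
        assert ad.angular_difference(a, b) == pytest.approx(brute, abs=1e-9)
        assert 0 <= ad.angular_difference(a, b) <= math.pi


class TestVicsekUpdate:
    def _two_agent_state(self, thetas, params):
        state = make_fixture("hex7")
        state.agents.add(np.array([0, 1]), np.array(thetas),
                         state.nodes.pos[[0, 1]])
        state.rebuild_occupancy()
        return state

    def test_isolated_agent_keeps_heading_without_noise(self):
        params = SimParams(A=1.0, eta=0.0)
        state = make_fixture("hex7")
        state.agents.add(np.array([0]), np.array([1.1]),
                         state.nodes.pos[[0]])
        state.rebuild_occupancy()
        ad.vicsek_update(state, params)
        assert state.agents.theta[0] == pytest.approx(1.1)

    def test_mutual_neighbours_average_without_noise(self):
        params = SimParams(A=1.0, eta=0.0)
        state = self._two_agent_state([0.0, math.pi / 2], params)
        ad.vicsek_update(state, params)
        np.testing.assert_allclose(state.agents.theta[:2], math.pi / 4,
                                   atol=1e-9)

    def test_full_noise_decorrelates_to_uniform(self):
        from scipy.stats import kstest
        params = SimParams(A=1.0, eta=1.0)
        state = make_fixture("hex7")
        state.agents.add(np.array([0]), np.array([0.0]),
                         state.nodes.pos[[0]])
        state.rebuild_occupancy()
        samples = []
        for _ in range(4000):
            ad.vicsek_update(state, params)
            samples.append(state.agents.theta[0])
        p = kstest(np.array(samples) / TWO_PI, "uniform").pvalue
        assert p > 0.01

    def test_paused_agents_keep_heading(self):
        params = SimParams(A=1.0, eta=0.0)
        state = self._two_agent_state([0.0, math.pi / 2], params)
        state.agents.pause[1] = 3
        ad.vicsek_update(state, params)
        assert state.agents.theta[1] == pytest.approx(math.pi / 2)
        assert state.agents.theta[0] == pytest.approx(math.pi / 4)


class TestDepositionRule:
    @pytest.mark.parametrize("A,n_s,phi_s,n_w,phi_w,expected", [
        (1.5, 1, 1.0, 1, 1.0, True),     # 1.5 > 1
        (0.9, 1, 1.0, 1, 1.0, False),    # 0.9 < 1
        (1.2, 3, 1.0, 6, 0.5, True),     # 3.6 > 3.0
        (1.0, 2, -0.5, 0, 0.0, False),   # opposing push never deposits
    ])
    def test_inequality(self, A, n_s, phi_s, n_w, phi_w, expected):
        inp = ad.DepositionInputs(n_s, phi_s, n_w, phi_w)
        assert ad.deposition_decision(A, inp) is expected

    def test_requires_positive_activity(self):
        with pytest.raises(ValueError):
            ad.deposition_decision(0.0, ad.DepositionInputs(1, 1.0, 0, 0.0))

    def test_lone_agent_inputs(self):
        state = make_fixture("hex7")
        state.agents.add(np.array([0]), np.array([0.3]),
                         state.nodes.pos[[0]])
        state.rebuild_occupancy()
        inp = ad.deposition_inputs(state, 0, SimParams(A=1.0))
        assert inp.n_sigma == 1
        assert inp.phi_sigma == pytest.approx(1.0)
        assert inp.n_omega == 0

    def test_collinear_water(self):
        state = make_fixture("hex7")
        # make the +x neighbour water; agent at centre heads +x
        state.nodes.kind[1] = WATER
        state.agents.add(np.array([0]), np.array([0.0]),
                         state.nodes.pos[[0]])
        state.rebuild_occupancy()
        inp = ad.deposition_inputs(state, 0, SimParams(A=1.0))
        assert inp.n_omega == 1
        assert inp.phi_omega == pytest.approx(
            SimParams(A=1.0).R_zeta if SimParams(A=1.0).edge_inverse_r
            else 1.0, rel=1e-9)

    def test_hand_computed_vector_sum(self):
        # agent at origin heading 0; walkers at 60 and 300 degrees heading
        # 0 and pi/2; water node at bearing pi/4, distance 1
        params = SimParams(A=1.0, edge_inverse_r=False)
        state = make_fixture("hex7")
        state.nodes.kind[2] = WATER   # the 60-degree node
        ids = state.agents.add(
            np.array([0, 1, 5]), np.array([0.0, 0.0, math.pi / 2]),
            state.nodes.pos[[0, 1, 5]])
        state.rebuild_occupancy()
        inp = ad.deposition_inputs(state, ids[0], params)
        # sigma: self (0) + two neighbours (0, pi/2)
        assert inp.n_sigma == 3
        assert inp.n_sigma * inp.phi_sigma == pytest.approx(2.0)
        # omega: single water at bearing pi/3
        assert inp.n_omega == 1
        assert inp.n_omega * inp.phi_omega == pytest.approx(
            math.cos(math.pi / 3))

    def test_paused_neighbours_do_not_push(self):
        params = SimParams(A=1.0, edge_inverse_r=False)
        state = make_fixture("hex7")
        ids = state.agents.add(np.array([0, 1]), np.array([0.0, 0.0]),
                               state.nodes.pos[[0, 1]])
        state.rebuild_occupancy()
        state.agents.pause[ids[1]] = 2
        inp = ad.deposition_inputs(state, ids[0], params)
        assert inp.n_sigma == 1


class TestStepFreeAgents:
    def test_jammed_agent_pauses(self):
        # centre agent of a fully occupied flower cannot move
        params = SimParams(A=1.0)
        state = make_fixture("hex7")
        ids = state.agents.add(np.arange(7),
                               np.zeros(7), state.nodes.pos[np.arange(7)])
        state.rebuild_occupancy()
        node_before = state.agents.node[0]
        ad.step_free_agents(state, params)
        assert state.agents.node[0] == node_before
        assert state.agents.pause[0] >= 1

    def test_unobstructed_step_takes_best_candidate(self):
        params = SimParams(A=1.0, eta=0.0)
        state = make_fixture("hex7")
        state.agents.add(np.array([0]), np.array([0.0]),
                         state.nodes.pos[[0]])
        state.rebuild_occupancy()
        ad.step_free_agents(state, params)
        # heading 0 -> moves to the +x neighbour (node 1)
        assert state.agents.node[0] == 1
        state.validate()

    def test_volume_exclusion_on_contested_node(self):
        # two agents both prefer the free node between them; exactly one
        # gets it, the other ends elsewhere or paused
        params = SimParams(A=1.0)
        state = make_fixture("hex7")
        # agents on nodes 1 (at 0 deg) and 2 (at 60 deg) both heading
        # towards the centre node 0
        p1 = state.nodes.pos[1]
        p2 = state.nodes.pos[2]
        th1 = math.atan2(-p1[1], -p1[0]) % TWO_PI
        th2 = math.atan2(-p2[1], -p2[0]) % TWO_PI
        state.agents.add(np.array([1, 2]), np.array([th1, th2]),
                         np.stack([p1, p2]))
        state.rebuild_occupancy()
        state.agents.pause[:] = 0
        ad.step_free_agents(state, params.with_(eta=0.0))
        nodes = sorted(state.agents.node[state.agents.active_ids].tolist())
        assert len(set(nodes)) == 2
        assert 0 in nodes
        state.validate()

    def test_engines_agree_step_by_step(self):
        params = SimParams(A=1.36, seed=3, init_radius=4.0)
        s1 = init_state(params, seed=3)
        s2 = s1.copy()
        for _ in range(25):
            ad.vicsek_update(s1, params)
            ad.step_free_agents(s1, params, engine="numba")
        for _ in range(25):
            ad.vicsek_update(s2, params)
            ad.step_free_agents(s2, params, engine="python")
        np.testing.assert_array_equal(s1.agents.node, s2.agents.node)
        np.testing.assert_allclose(s1.agents.theta, s2.agents.theta)
        np.testing.assert_array_equal(s1.agents.pause, s2.agents.pause)
        np.testing.assert_array_equal(s1.nodes.kind, s2.nodes.kind)

    def test_conservation_and_exclusion_over_1000_steps(self):
        """Volume exclusion and total-agent conservation hold through a
        long stretch of the full pipeline."""
        from antraft.simulator import RunConfig, run
        params = SimParams(A=1.36, seed=9, init_radius=4.0)
        state = init_state(params, seed=9)
        total = state.total_agents
        for _ in range(20):
            run(state, params, RunConfig(n_steps=50))
            state.validate()          # exclusion + occupancy invariants
            assert state.total_agents == total
        assert state.step == 1000

    def test_deposition_monotone_in_activity(self):
        # frozen configurations: the set of depositing agents at low A is
        # a subset of that at higher A
        base = SimParams(A=1.0, seed=13, init_radius=4.0)
        state0 = init_state(base, seed=13)
        for _ in range(5):
            ad.vicsek_update(state0, base)
            ad.step_free_agents(state0, base)
        prev: set | None = None
        for A in (0.6, 1.2, 2.4, 4.8):
            st_a = state0.copy()
            params = base.with_(A=A)
            deposits = set()
            for aid in st_a.agents.active_ids:
                tab = ad.dof_table(st_a, aid, params)
                if len(tab.node_ids) and tab.kind[0] == WATER \
                        and tab.dtheta[0] <= params.turn_limit:
                    inp = ad.deposition_inputs(st_a, aid, params)
                    if ad.deposition_decision(A, inp):
                        deposits.add(int(aid))
            if prev is not None:
                assert prev <= deposits
            prev = deposits
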