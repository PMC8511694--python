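"""Unit tests of the agent-based simulator: population, distance kernel,
attachment mechanisms, termination sweeps, step scheduling and full runs."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import gwsn
from gwsn import (GWSNParams, Population, SimulationProtocol, WeightedNetwork,
                  apply_link_aging, apply_link_deletion, apply_node_deletion,
                  ga_selection_counts, global_attachment, init_population,
                  local_attachment, run, step, torus_distance)


# ---------------------------------------------------------------------------
# Parameters and population
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("bad", [
    {"N": 1}, {"N": 100, "F": 0}, {"N": 100, "q": 0},
    {"N": 100, "alpha": -0.5}, {"N": 100, "p_r": 1.5},
    {"N": 100, "p_delta": -0.1}, {"N": 100, "w_r": -1.0},
])
def test_params_validation_rejects_out_of_domain(bad):
    with pytest.raises(ValueError):
        GWSNParams(**bad)


def test_population_single_trait_degeneracy(rng):
    pop = init_population(GWSNParams(N=50, F=4, q=1), rng)
    assert np.all(pop.traits == 1)


def test_population_uniform_positions_and_traits(rng):
    pop = init_population(GWSNParams(N=10_000, F=2, q=5), rng)
    assert abs(pop.positions[:, 0].mean() - 0.5) < 0.02
    assert abs(pop.positions[:, 1].mean() - 0.5) < 0.02
    assert pop.positions.min() >= 0.0 and pop.positions.max() < 1.0
    counts = np.bincount(pop.traits.ravel(), minlength=6)[1:]
    assert np.all(np.abs(counts / pop.traits.size - 0.2) < 0.02)


def test_population_deterministic_under_fixed_seed():
    p = GWSNParams(N=200, F=3, q=4)
    a = init_population(p, np.random.default_rng(7))
    b = init_population(p, np.random.default_rng(7))
    assert np.array_equal(a.positions, b.positions)
    assert np.array_equal(a.traits, b.traits)


# ---------------------------------------------------------------------------
# Torus distance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p1,p2,expected", [
    ((0.1, 0.1), (0.1, 0.1), 0.0),
    ((0.05, 0.5), (0.95, 0.5), 0.1),       # wraps across the boundary
    ((0.0, 0.0), (0.5, 0.5), math.sqrt(0.5)),
    ((0.2, 0.9), (0.2, 0.05), 0.15),
])
def test_torus_distance_hand_cases(p1, p2, expected):
    assert torus_distance(p1, p2) == pytest.approx(expected, abs=1e-12)


@given(st.tuples(*[st.floats(0, 0.999999)] * 4))
def test_torus_distance_symmetric_and_bounded(xy):
    p1, p2 = (xy[0], xy[1]), (xy[2], xy[3])
    d = torus_distance(p1, p2)
    assert d == pytest.approx(torus_distance(p2, p1))
    assert 0.0 <= d <= math.sqrt(2) / 2 + 1e-12


@given(st.tuples(*[st.floats(0, 0.999999)] * 5))
def test_torus_distance_translation_invariant(v):
    p1, p2, s = (v[0], v[1]), (v[2], v[3]), v[4]
    shifted = ((v[0] + s) % 1.0, (v[1] + s) % 1.0), ((v[2] + s) % 1.0, (v[3] + s) % 1.0)
    assert torus_distance(*shifted) == pytest.approx(torus_distance(p1, p2), abs=1e-9)


# ---------------------------------------------------------------------------
# Global attachment
# ---------------------------------------------------------------------------

def _frozen_population(positions, traits):
    pos = np.asarray(positions, dtype=float)
    tr = np.asarray(traits, dtype=np.int64)
    return Population(positions=pos, traits=tr)


def test_ga_two_candidate_distance_kernel():
    # alpha=1, candidates at r=0.1 and r=0.2 -> probabilities 2/3 and 1/3
    pop = _frozen_population([[0.5, 0.5], [0.6, 0.5], [0.7, 0.5]],
                             [[1], [1], [1]])
    net = WeightedNetwork(3)
    params = GWSNParams(N=3, F=1, q=1, alpha=1.0)
    counts = ga_selection_counts(net, pop, 0, 0, params, 100_000, rng=11)
    freq = counts / counts.sum()
    assert counts[0] == 0
    assert freq[1] == pytest.approx(2 / 3, abs=0.01)
    assert freq[2] == pytest.approx(1 / 3, abs=0.01)


def test_ga_uniform_when_alpha_zero(rng):
    # chi-square on a frozen 6-node configuration, 1e5 draws
    pos = np.array([[0.1, 0.1], [0.3, 0.8], [0.9, 0.2],
                    [0.5, 0.5], [0.7, 0.9], [0.05, 0.6]])
    pop = _frozen_population(pos, np.ones((6, 1)))
    net = WeightedNetwork(6)
    params = GWSNParams(N=6, F=1, q=1, alpha=0.0)
    counts = ga_selection_counts(net, pop, 0, 0, params, 100_000, rng=5)
    assert counts[0] == 0
    _, p = stats.chisquare(counts[1:])
    assert p > 0.01


def test_ga_homophily_gate_never_crossed():
    # a candidate with a different trait value is never selected
    pop = _frozen_population(np.random.default_rng(0).random((6, 2)),
                             [[1], [1], [2], [1], [2], [1]])
    net = WeightedNetwork(6)
    params = GWSNParams(N=6, F=1, q=2, alpha=0.0)
    counts = ga_selection_counts(net, pop, 0, 0, params, 100_000, rng=3)
    assert counts[2] == 0 and counts[4] == 0
    assert counts[1] > 0 and counts[3] > 0 and counts[5] > 0


def test_ga_creates_unconditionally_at_degree_zero():
    pop = _frozen_population([[0.1, 0.1], [0.2, 0.2]], [[1], [1]])
    params = GWSNParams(N=2, F=1, q=1, p_r=0.0)  # p_r=0 but k_0=0
    net = WeightedNetwork(2)
    global_attachment(net, pop, 0, params, rng=1)
    assert net.n_links == 1
    assert net.get_weight(0, 1) == params.w0


def test_ga_respects_p_r_gate_when_connected():
    pop = _frozen_population([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3]],
                             [[1], [1], [1]])
    params = GWSNParams(N=3, F=1, q=1, p_r=0.0)
    net = WeightedNetwork.from_edges(3, [(0, 1, 1.0)])
    for s in range(200):
        global_attachment(net, pop, 0, params, rng=s)
    assert net.n_links == 1  # never creates with p_r = 0


def test_ga_empty_candidate_set_is_noop():
    pop = _frozen_population([[0.1, 0.1], [0.9, 0.9]], [[1], [2]])
    params = GWSNParams(N=2, F=1, q=2)
    net = WeightedNetwork(2)
    global_attachment(net, pop, 0, params, rng=0)
    assert net.n_links == 0


# ---------------------------------------------------------------------------
# Local attachment
# ---------------------------------------------------------------------------

def _three_path(w01=1.0, w12=1.0):
    return WeightedNetwork.from_edges(3, [(0, 1, w01), (1, 2, w12)])


def test_la_null_event_leaves_network_unchanged():
    pop = _frozen_population(np.random.default_rng(1).random((3, 2)),
                             np.ones((3, 1)))
    params = GWSNParams(N=3, F=1, q=1, p_delta=0.0, w_r=0.0)
    net = _three_path()
    before = net.edges().copy()
    for s in range(50):
        local_attachment(net, pop, 0, params, rng=s)
    assert np.array_equal(net.edges(), before)


def test_la_noop_when_second_neighborhood_empty():
    # only neighbor of j is i itself: whole LA event is a no-op,
    # including the reinforcement of w_ij
    pop = _frozen_population(np.random.default_rng(2).random((2, 2)),
                             np.ones((2, 1)))
    params = GWSNParams(N=2, F=1, q=1, p_delta=1.0, w_r=1.0)
    net = WeightedNetwork.from_edges(2, [(0, 1, 3.0)])
    local_attachment(net, pop, 0, params, rng=0)
    assert net.get_weight(0, 1) == 3.0


def test_la_triangle_reinforces_all_three_links():
    # closed triad: a successful LA event adds w_r to w_ij, w_jl and w_il
    pop = _frozen_population(np.random.default_rng(3).random((3, 2)),
                             np.ones((3, 1)))
    params = GWSNParams(N=3, F=1, q=1, p_delta=1.0, w_r=1.0)
    net = WeightedNetwork.from_edges(3, [(0, 1, 2.0), (1, 2, 3.0), (0, 2, 4.0)])
    local_attachment(net, pop, 0, params, rng=0)
    assert net.get_weight(0, 1) == 3.0
    assert net.get_weight(1, 2) == 4.0
    assert net.get_weight(0, 2) == 5.0


def test_la_closure_creates_link_at_exactly_w0():
    pop = _frozen_population(np.random.default_rng(4).random((3, 2)),
                             np.ones((3, 1)))
    params = GWSNParams(N=3, F=1, q=1, p_delta=1.0, w_r=0.5, w0=1.0)
    net = _three_path(w01=2.0, w12=3.0)
    local_attachment(net, pop, 0, params, rng=0)
    # the walk 0 -> 1 -> 2 is forced; new link starts at w0, no +w_r
    assert net.get_weight(0, 2) == 1.0
    assert net.get_weight(0, 1) == 2.5
    assert net.get_weight(1, 2) == 3.5


def test_la_closure_blocked_when_p_delta_zero():
    pop = _frozen_population(np.random.default_rng(5).random((3, 2)),
                             np.ones((3, 1)))
    params = GWSNParams(N=3, F=1, q=1, p_delta=0.0, w_r=1.0)
    net = _three_path()
    local_attachment(net, pop, 0, params, rng=0)
    assert net.get_weight(0, 2) == 0.0       # no closure
    assert net.get_weight(0, 1) == 2.0       # but traversed links reinforced
    assert net.get_weight(1, 2) == 2.0


def test_la_trait_restricted_walk():
    # neighbor with non-matching trait is invisible to the walk
    pop = _frozen_population(np.random.default_rng(6).random((3, 2)),
                             [[1], [1], [2]])
    params = GWSNParams(N=3, F=1, q=2, p_delta=1.0, w_r=1.0)
    net = _three_path()
    local_attachment(net, pop, 0, params, rng=0)
    # walk reaches j=1 but l=2 has the wrong trait: full no-op
    assert net.get_weight(0, 1) == 1.0
    assert net.get_weight(1, 2) == 1.0
    assert net.get_weight(0, 2) == 0.0


# ---------------------------------------------------------------------------
# Termination mechanisms
# ---------------------------------------------------------------------------

def test_node_deletion_identity_and_annihilation(k4):
    net = k4.copy()
    apply_node_deletion(net, GWSNParams(N=4, p_nd=0.0), rng=0)
    assert net.n_links == 6
    apply_node_deletion(net, GWSNParams(N=4, p_nd=1.0), rng=0)
    assert net.n_links == 0


def test_node_deletion_binomial_oracle(k4):
    # K4, p_nd = 0.5: a link survives iff both ends survive -> E[L] = 6/4
    params = GWSNParams(N=4, p_nd=0.5)
    total = 0
    n_trials = 10_000
    for s in range(n_trials):
        net = k4.copy()
        apply_node_deletion(net, params, rng=s)
        total += net.n_links
    assert total / n_trials == pytest.approx(1.5, abs=0.05)


def test_node_deletion_keeps_positions_and_traits(rng):
    params = GWSNParams(N=30, F=2, q=3, p_nd=0.5)
    pop = init_population(params, rng)
    pos, traits = pop.positions.copy(), pop.traits.copy()
    net = WeightedNetwork.from_edges(30, [(i, (i + 1) % 30, 1.0) for i in range(30)])
    apply_node_deletion(net, params, rng=1)
    assert np.array_equal(pop.positions, pos)
    assert np.array_equal(pop.traits, traits)


def test_link_deletion_identity_and_annihilation(k4):
    net = k4.copy()
    apply_link_deletion(net, GWSNParams(N=4, p_ld=0.0), rng=0)
    assert net.n_links == 6
    apply_link_deletion(net, GWSNParams(N=4, p_ld=1.0), rng=0)
    assert net.n_links == 0


def test_link_deletion_binomial_oracle():
    # 1,000-link ring lattice, p_ld = 0.3 -> about 700 survivors
    edges = [(i, (i + 1) % 1000, 1.0) for i in range(1000)]
    net = WeightedNetwork.from_edges(1000, edges)
    apply_link_deletion(net, GWSNParams(N=1000, p_ld=0.3), rng=99)
    assert abs(net.n_links - 700) <= 30


def test_aging_identity_when_A_zero(k4):
    net = k4.copy()
    apply_link_aging(net, GWSNParams(N=4, A=0.0))
    assert np.array_equal(net.edges(), k4.edges())


def test_aging_deletes_below_threshold():
    net = WeightedNetwork.from_edges(2, [(0, 1, 1.0)])
    apply_link_aging(net, GWSNParams(N=2, A=0.6))  # 0.4 < w_th = 0.5
    assert net.n_links == 0


def test_aging_geometric_decay_until_deletion():
    # w = 1, A = 0.1: survives six passes (0.9^6 ~ 0.531), gone on the 7th
    net = WeightedNetwork.from_edges(2, [(0, 1, 1.0)])
    params = GWSNParams(N=2, A=0.1)
    for k in range(1, 7):
        apply_link_aging(net, params)
        assert net.get_weight(0, 1) == pytest.approx(0.9**k)
    apply_link_aging(net, params)
    assert net.n_links == 0


def test_weights_never_below_threshold_after_aging(rng):
    params = GWSNParams(N=60, F=1, q=1, p_r=5e-3, p_delta=0.05, w_r=0.3,
                        p_nd=5e-3, p_ld=1e-3, A=0.05)
    pop = init_population(params, rng)
    net = WeightedNetwork(60)
    for s in range(300):
        step(net, pop, params, rng=s)
        e = net.edges()
        if len(e):
            assert e[:, 2].min() >= params.w_th
    net.validate()


# ---------------------------------------------------------------------------
# Step and run
# ---------------------------------------------------------------------------

def test_step_monotone_growth_without_termination(rng):
    params = GWSNParams(N=80, F=1, q=1, p_r=5e-3, p_delta=0.05, w_r=1.0,
                        p_nd=0.0, p_ld=0.0, A=0.0)
    pop = init_population(params, rng)
    net = WeightedNetwork(80)
    last = 0
    for s in range(100):
        step(net, pop, params, rng=s)
        assert net.n_links >= last
        last = net.n_links
    assert last > 0


def test_step_first_sweep_connects_isolated_nodes(rng):
    # from empty with q=1 every node attempts a GA; degree-zero nodes
    # always link, so one step creates at least N/2 links
    params = GWSNParams(N=100, F=1, q=1, p_r=0.0)
    pop = init_population(params, rng)
    net = WeightedNetwork(100)
    step(net, pop, params, rng=0)
    assert net.n_links >= 50


def test_run_deterministic_trajectory():
    params = GWSNParams(N=100, F=2, q=2, p_r=2e-3, p_delta=0.02, w_r=1.0,
                        p_nd=2e-3, p_ld=1e-4, A=1e-3)
    proto = SimulationProtocol(t_max=400, measure_every=100, seed=77)
    a = run(params, proto)
    b = run(params, proto)
    assert a.network == b.network
    for (ta, pa), (tb, pb) in zip(a.checkpoints, b.checkpoints):
        assert ta == tb
        assert np.array_equal(pa.as_array(), pb.as_array(), equal_nan=True)


def test_run_zero_horizon_has_no_checkpoints(sparse_params):
    res = run(sparse_params, SimulationProtocol(t_max=0, measure_every=100, seed=0))
    assert res.checkpoints == []
    assert not res.aborted


def test_run_checkpoint_times_are_multiples(sparse_params):
    proto = SimulationProtocol(t_max=600, measure_every=150, seed=3)
    res = run(sparse_params, proto)
    assert res.checkpoint_times == [150, 300, 450, 600]


def test_run_abort_on_densification():
    params = GWSNParams(N=200, F=1, q=1, p_r=1e-2, p_delta=0.5, w_r=2.0,
                        p_nd=0.0, p_ld=0.0, A=0.0)
    proto = SimulationProtocol(t_max=2000, measure_every=100, k_th=20.0, seed=5)
    res = run(params, proto)
    assert res.aborted
    assert res.abort_step is not None and res.abort_step <= 2000
    assert len(res.checkpoints) < proto.n_checkpoints


def test_run_network_invariants_hold(sparse_params):
    res = run(sparse_params, SimulationProtocol(t_max=300, measure_every=100, seed=9))
    res.network.validate()


def test_homophily_every_link_shares_a_trait(rng):
    params = GWSNParams(N=150, F=3, q=5, p_r=5e-3, p_delta=0.05, w_r=1.0)
    res = run(params, SimulationProtocol(t_max=300, measure_every=300, seed=21))
    traits = res.population.traits
    edges = res.network.edges()
    assert len(edges) > 0
    for i, j, _ in edges:
        assert np.any(traits[int(i)] == traits[int(j)])
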