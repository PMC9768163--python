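import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soam.dynamics import (
    ModelParams,
    StepDraws,
    draw_step,
    expressed_opinions,
    influence_set,
    init_population,
    make_streams,
    run,
    step,
)
from soam.networks import DirectedNetwork, generate_network

from conftest import make_state, small_params


# ---------------------------------------------------------------------------
# Independent brute-force oracle: per-agent scalar evaluation of the
# expressed-opinion rule, the confidence gate, and the averaging update.
# Written separately from the vectorized engine.
# ---------------------------------------------------------------------------

def oracle_expressed(opinions, amplify_now, sigma):
    out = []
    for o, a, sg in zip(opinions, amplify_now, sigma):
        if a:
            out.append(o - sg if o < 0 else o + sg)
        else:
            out.append(o)
    return out


def oracle_step(opinions, amplify_now, sigma, edges, eps, externals=()):
    n = len(opinions)
    so = oracle_expressed(opinions, amplify_now, sigma)
    new = []
    for i in range(n):
        infl = [so[j] for j in range(n) if (j, i) in edges and abs(opinions[i] - so[j]) <= eps]
        infl += [e for e in externals if abs(opinions[i] - e) <= eps]
        new.append((opinions[i] + sum(infl)) / (1 + len(infl)))
    return new


def hk_oracle(x, eps):
    # classic bounded-confidence update on a complete graph; self always counts
    return [np.mean([xj for xj in x if abs(xi - xj) <= eps]) for xi in x]


class TestInitPopulation:
    def test_exact_amplifier_count(self):
        params = ModelParams(n=100, pi=0.2, t_max=1)
        state = init_population(params, np.random.default_rng(0))
        assert state.is_amplifier.sum() == 20
        assert state.strikes.sum() == 0 and state.t == 0

    def test_no_amplifiers_when_pi_zero(self):
        state = init_population(ModelParams(n=100, pi=0.0, t_max=1), np.random.default_rng(0))
        assert state.is_amplifier.sum() == 0

    def test_opinions_uniform_on_unit_interval(self):
        # CLT: per-seed SE = 0.577/sqrt(100); 100 seeds shrink it by 10x
        means = [
            init_population(ModelParams(n=100, t_max=1), np.random.default_rng(s)).opinions.mean()
            for s in range(100)
        ]
        assert np.mean(means) == pytest.approx(0.0, abs=0.06)
        assert all(np.all(np.abs(
            init_population(ModelParams(n=50, t_max=1), np.random.default_rng(s)).opinions) <= 1)
            for s in range(5))


class TestDrawStep:
    def test_p_zero_never_amplifies(self):
        state = make_state([0.1, -0.2, 0.3], is_amplifier=[True] * 3)
        draws = draw_step(state, small_params(p=0.0, pi=1.0), np.random.default_rng(0))
        assert not draws.amplify_now.any()

    def test_p_one_all_amplifiers_amplify(self):
        state = make_state([0.1, -0.2, 0.3], is_amplifier=[True] * 3)
        draws = draw_step(state, small_params(p=1.0, pi=1.0), np.random.default_rng(0))
        assert draws.amplify_now.all()

    def test_non_amplifiers_never_amplify(self):
        state = make_state([0.1, -0.2, 0.3], is_amplifier=[False, True, False])
        draws = draw_step(state, small_params(p=1.0), np.random.default_rng(0))
        assert list(draws.amplify_now) == [False, True, False]

    def test_binomial_mean_amplification_count(self):
        params = ModelParams(n=100, pi=0.2, p=0.5, t_max=1)
        state = init_population(params, np.random.default_rng(1))
        rng = np.random.default_rng(2)
        counts = [draw_step(state, params, rng).amplify_now.sum() for _ in range(200)]
        assert np.mean(counts) == pytest.approx(10, abs=1)

    def test_sigma_bounded_and_zero_for_non_amplifying(self):
        state = make_state(np.linspace(-1, 1, 50), is_amplifier=[True] * 25 + [False] * 25)
        draws = draw_step(state, small_params(n=50, p=0.5, s=0.3), np.random.default_rng(3))
        assert np.all(draws.sigma >= 0) and np.all(draws.sigma <= 0.3)
        assert np.all(draws.sigma[~draws.amplify_now] == 0)


class TestExpressedOpinions:
    @pytest.mark.parametrize(
        "o,amp,sigma,expected",
        [
            (-0.4, True, 0.3, -0.7),   # negative branch pushes down
            (0.0, True, 0.2, 0.2),     # zero counts as nonnegative
            (0.9, False, 0.5, 0.9),    # identity when not amplifying
        ],
    )
    def test_branches(self, o, amp, sigma, expected):
        state = make_state([o], is_amplifier=[amp])
        draws = StepDraws(np.array([amp]), np.array([sigma if amp else 0.0]))
        assert expressed_opinions(state, draws)[0] == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(
        o=st.floats(-1, 1),
        sigma=st.floats(0, 0.5),
    )
    def test_amplification_direction_and_magnitude(self, o, sigma):
        # |SO| in [|O|, |O| + s], same sign as O (0 treated as nonnegative)
        state = make_state([o], is_amplifier=[True])
        so = expressed_opinions(state, StepDraws(np.array([True]), np.array([sigma])))[0]
        assert abs(so) >= abs(o) - 1e-12
        assert abs(so) <= abs(o) + sigma + 1e-12
        assert np.sign(so) == np.sign(o) or o == 0 or so == 0


class TestInfluenceSet:
    def test_boundary_inclusive(self):
        net = DirectedNetwork(4, frozenset({(1, 0), (2, 0), (3, 0)}))
        expressed = np.array([0.0, 0.2, -0.2, 0.21])
        assert influence_set(0, 0.0, expressed, net, 0.2) == {1, 2}

    def test_no_in_neighbors_empty(self, tri_net):
        assert influence_set(0, 0.5, np.zeros(3), tri_net, 1.0) == set()

    def test_zero_threshold_keeps_exact_matches_only(self):
        net = DirectedNetwork(3, frozenset({(1, 0), (2, 0)}))
        expressed = np.array([0.5, 0.5, 0.49])
        assert influence_set(0, 0.5, expressed, net, 0.0) == {1}


class TestStep:
    def test_hand_computed_average(self):
        # own 0.5, visible expressed {0.3, 0.9}, all within eps=0.8
        net = DirectedNetwork(3, frozenset({(1, 0), (2, 0)}))
        state = make_state([0.5, 0.3, 0.9])
        params = small_params(epsilon=0.8)
        draws = StepDraws(np.zeros(3, bool), np.zeros(3))
        new = step(state, net, params, draws=draws)
        assert new.opinions[0] == pytest.approx((0.5 + 0.3 + 0.9) / 3)

    def test_empty_influence_set_leaves_opinion_unchanged(self):
        net = DirectedNetwork(3, frozenset({(1, 0), (2, 0)}))
        state = make_state([0.5, 0.3, 0.9])
        new = step(state, net, small_params(epsilon=0.1),
                   draws=StepDraws(np.zeros(3, bool), np.zeros(3)))
        assert new.opinions[0] == pytest.approx(0.5)

    def test_strikes_increment_on_amplification(self):
        net = DirectedNetwork(2, frozenset({(0, 1)}))
        state = make_state([0.5, 0.2], is_amplifier=[True, False])
        draws = StepDraws(np.array([True, False]), np.array([0.1, 0.0]))
        new = step(state, net, small_params(n=2, k=1), draws=draws)
        assert list(new.strikes) == [1, 0]
        assert new.t == state.t + 1

    @settings(derandomize=True, max_examples=60)
    @given(
        opinions=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        amp=st.lists(st.booleans(), min_size=3, max_size=3),
        sigma=st.lists(st.floats(0, 0.5), min_size=3, max_size=3),
        eps=st.floats(0, 1),
        edge_bits=st.lists(st.booleans(), min_size=6, max_size=6),
        externals=st.lists(st.floats(-1, 1), max_size=3),
    )
    def test_matches_brute_force_oracle(self, opinions, amp, sigma, eps, edge_bits, externals):
        pairs = [(a, b) for a in range(3) for b in range(3) if a != b]
        edges = frozenset(p for p, bit in zip(pairs, edge_bits) if bit)
        net = DirectedNetwork(3, edges)
        state = make_state(opinions, is_amplifier=amp)
        sig = np.where(amp, sigma, 0.0)
        draws = StepDraws(np.array(amp), sig)
        got = step(state, net, small_params(epsilon=eps), draws=draws,
                   externals=externals)
        want = oracle_step(opinions, amp, sig, edges, eps, externals)
        assert np.allclose(got.opinions, want)

    def test_reduces_to_hegselmann_krause_on_complete_network(self):
        rng = np.random.default_rng(12)
        for eps in (0.2, 0.5, 0.8):
            n = 10
            x = rng.uniform(-1, 1, n)
            net = generate_network("complete", n=n, k=0, seed=0)
            state = make_state(x)
            new = step(state, net, ModelParams(n=n, k=n - 1, epsilon=eps, pi=0.0, t_max=1),
                       draws=StepDraws(np.zeros(n, bool), np.zeros(n)))
            assert np.allclose(new.opinions, hk_oracle(x, eps))


class TestRun:
    def test_convex_hull_containment_without_amplifiers(self):
        for seed in range(3):
            traj = run(ModelParams(n=60, k=5, epsilon=0.4, pi=0.0, t_max=100, seed=seed))
            lo, hi = traj.opinions[0].min(), traj.opinions[0].max()
            assert traj.opinions.min() >= lo - 1e-12
            assert traj.opinions.max() <= hi + 1e-12

    def test_zero_timesteps_returns_initial_state_only(self):
        traj = run(ModelParams(n=20, k=3, t_max=0, seed=0))
        assert traj.opinions.shape == (1, 20)
        assert len(traj.conflict) == 1

    def test_seed_determinism_bit_exact(self):
        p = ModelParams(n=50, k=5, epsilon=0.3, pi=0.3, p=0.5, s=0.4, t_max=50, seed=11)
        a, b = run(p), run(p)
        assert np.array_equal(a.opinions, b.opinions)
        assert np.array_equal(a.amplified, b.amplified)
        c = run(ModelParams(**{**p.__dict__, "seed": 12}))
        assert not np.array_equal(a.opinions, c.opinions)

    def test_mismatched_network_size_rejected(self):
        net = generate_network("erdos_renyi", n=10, k=2, seed=0)
        with pytest.raises(ValueError):
            run(ModelParams(n=20, k=2, t_max=1), net=net)

    def test_conflict_series_shape_and_nonnegative(self):
        traj = run(ModelParams(n=30, k=4, pi=0.2, t_max=25, seed=3))
        assert len(traj.conflict) == 26
        assert np.all(traj.conflict >= 0)

    def test_long_dataframe_round_trip(self):
        traj = run(ModelParams(n=10, k=2, pi=0.5, p=0.8, s=0.5, t_max=5, seed=4))
        df = traj.to_long_dataframe()
        assert len(df) == 6 * 10
        # opinions in the table match the matrix
        wide = df.pivot(index="timestep", columns="agent_id", values="opinion")
        assert np.allclose(wide.to_numpy(), traj.opinions)
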