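import math

import numpy as np
import pytest
from scipy import stats as st

from photochoice import arena as ar
from photochoice import synthetic as sb
from photochoice.fractionation import tube_distribution_betabinomial


# ---------------------------------------------------------------------------
# population sampling

def test_spontaneity_population_is_a_point_mass():
    model = sb.PopulationModel.spontaneity(0.7)
    flies = sb.sample_population(model, 5, seed=0)
    assert len(flies) == 5
    assert all(f.p_light == 0.7 for f in flies)


@pytest.mark.parametrize("alpha,beta,mean", [(2, 2, 0.5), (7, 3, 0.7)])
def test_individuality_population_mean(alpha, beta, mean):
    model = sb.PopulationModel.individuality(alpha, beta)
    flies = sb.sample_population(model, 10_000, seed=1)
    p = np.array([f.p_light for f in flies])
    assert p.mean() == pytest.approx(mean, abs=0.02)
    assert np.all((0 <= p) & (p <= 1))


def test_trait_correlation_tracks_rho():
    model = sb.PopulationModel.individuality(2, 2, rho=0.6)
    flies = sb.sample_population(model, 20_000, seed=2)
    p = np.array([f.p_light for f in flies])
    a = np.array([f.activity for f in flies])
    assert np.all(a >= 0)
    assert np.corrcoef(p, a)[0, 1] == pytest.approx(0.6, abs=0.08)


def test_sampling_is_seed_deterministic():
    model = sb.PopulationModel.individuality(2, 5, rho=0.3)
    a = sb.sample_population(model, 50, seed=7)
    b = sb.sample_population(model, 50, seed=7)
    c = sb.sample_population(model, 50, seed=8)
    assert a == b
    assert a != c


def test_invalid_model_parameters_rejected():
    with pytest.raises(ValueError):
        sb.PopulationModel.individuality(-1, 2)
    with pytest.raises(ValueError):
        sb.PopulationModel.spontaneity(1.2)
    with pytest.raises(ValueError):
        sb.PopulationModel(kind="individuality", p_mean=0.9, alpha=2, beta=2)
    with pytest.raises(ValueError):
        sb.sample_population(sb.PopulationModel.spontaneity(0.5), 0)


# ---------------------------------------------------------------------------
# T-maze

def _flies(n, p, activity=1.0):
    return [sb.FlyTraits(f"f{i}", p, activity) for i in range(n)]


def test_tmaze_degenerate_probabilities():
    res = sb.simulate_tmaze(_flies(80, 1.0),
                            sb.TMazeParams(elevator_capture_prob=0.0), seed=0)
    assert (res.session.n_bright, res.session.n_dark,
            res.session.n_elevator) == (80, 0, 0)
    res = sb.simulate_tmaze(_flies(80, 0.0),
                            sb.TMazeParams(elevator_capture_prob=1.0), seed=0)
    assert res.session.n_elevator == 80


def test_tmaze_bright_fraction_is_product_of_probabilities():
    res = sb.simulate_tmaze(_flies(10_000, 0.7),
                            sb.TMazeParams(elevator_capture_prob=0.05), seed=3)
    assert res.session.n_bright / 10_000 == pytest.approx(0.665, abs=0.015)
    # elevator capture is independent of preference
    assert res.session.n_elevator / 10_000 == pytest.approx(0.05, abs=0.01)


def test_tmaze_partitions_flies_exactly():
    res = sb.simulate_tmaze(_flies(123, 0.6), sb.TMazeParams(), seed=4)
    s = res.session
    assert s.n_bright + s.n_dark + s.n_elevator == s.n_total == 123
    assert len(res.outcomes) == 123
    with pytest.raises(ValueError):
        sb.simulate_tmaze([], sb.TMazeParams())


# ---------------------------------------------------------------------------
# CPP

def test_cpp_degenerate_walkers():
    out = sb.simulate_cpp([sb.FlyTraits("w", 1.0, 2.0)], seed=0)
    assert out.tubes[0] == 5 and out.sequences[0].tolist() == [1] * 5
    out = sb.simulate_cpp([sb.FlyTraits("s", 0.0, 1.0)], seed=0)
    assert out.tubes[0] == 0


def test_cpp_tube_occupancy_matches_binomial():
    out = sb.simulate_cpp(_flies(10_000, 0.5), seed=5)
    frac = np.asarray(out.counts.counts) / 10_000
    expected = np.array([1, 5, 10, 10, 5, 1]) / 32
    assert np.allclose(frac, expected, atol=0.01)
    chi2, p = st.chisquare(out.counts.counts, expected * 10_000)
    assert p > 0.01
    assert sum(out.counts.counts) == 10_000


def test_walk_probability_saturating_link():
    params = sb.CPPParams()
    assert sb.walk_probability(sb.FlyTraits("a", 0.8, 0.5), params) == pytest.approx(0.4)
    assert sb.walk_probability(sb.FlyTraits("b", 0.8, 2.0), params) == pytest.approx(0.8)
    pref = sb.CPPParams(walk_link="preference")
    assert sb.walk_probability(sb.FlyTraits("c", 0.8, 0.1), pref) == pytest.approx(0.8)


def test_two_sessions_compose_to_ten_choice_betabinomial():
    """With traits fixed across sessions, total light choices over two
    five-choice sessions follow the ten-choice beta-binomial."""
    model = sb.PopulationModel.individuality(2, 2)
    flies = sb.sample_population(model, 10_000, seed=6)
    params = sb.CPPParams(walk_link="preference")
    first = sb.simulate_cpp(flies, params, seed=7)
    second = sb.simulate_cpp(flies, params, seed=8)
    total = first.tubes + second.tubes
    counts = np.bincount(total, minlength=11)
    expected = tube_distribution_betabinomial(2, 2, 10).probs * 10_000
    chi2, p = st.chisquare(counts, expected)
    assert p > 0.01


# ---------------------------------------------------------------------------
# retest protocols

def test_tmaze_retest_history_independent_under_spontaneity():
    """Successive Bernoulli draws under a shared p are independent, so both
    subgroups reproduce the original bright fraction on the second session."""
    model = sb.PopulationModel.spontaneity(0.7)
    flies = sb.sample_population(model, 10_000, seed=9)
    params = sb.TMazeParams(elevator_capture_prob=0.0)
    first = sb.simulate_tmaze(flies, params, seed=10)
    bright = first.subgroup("bright")
    dark = first.subgroup("dark")
    f_bright = sb.simulate_tmaze(bright, params, seed=11)
    f_dark = sb.simulate_tmaze(dark, params, seed=12)
    frac_b = f_bright.session.n_bright / len(bright)
    frac_d = f_dark.session.n_bright / len(dark)
    assert frac_b == pytest.approx(frac_d, abs=0.03)
    assert frac_d == pytest.approx(0.7, abs=0.03)


def test_cpp_retest_monotone_under_individuality():
    model = sb.PopulationModel.individuality(1, 1)
    res = sb.simulate_retest_protocol(
        model, "cpp", replicates=8, seed=13,
        cpp_params=sb.CPPParams(walk_link="preference"))
    means = [np.mean(res.values(f"tube_{k}")) for k in range(6)]
    assert all(m2 > m1 for m1, m2 in zip(means, means[1:]))
    # posterior-mean prediction (alpha+k)/(alpha+beta+5) sets the scale
    for k, m in enumerate(means):
        assert m == pytest.approx(5 * (1 + k) / 7, abs=0.25)


def test_cpp_retest_flat_under_spontaneity():
    """Choices are independent of history under a point-mass p, so retest
    PIs agree across first-session tubes up to Monte-Carlo error: each tube
    pools 180 flies, giving a per-tube SE of sd(Binom(5,.5))/sqrt(180) ~
    0.083, so a 0.35 band is ~4 sd wide."""
    model = sb.PopulationModel.spontaneity(0.5)
    res = sb.simulate_retest_protocol(
        model, "cpp", replicates=3, seed=14, n_flies=400, minimum=60,
        cpp_params=sb.CPPParams(walk_link="preference"))
    means = [np.mean(res.values(f"tube_{k}")) for k in range(6)]
    assert max(means) - min(means) < 0.35


def test_retest_traits_persist_and_shortfall_flagged():
    model = sb.PopulationModel.spontaneity(0.95)
    res = sb.simulate_retest_protocol(
        model, "cpp", replicates=2, seed=15, n_flies=80, minimum=40,
        max_first_sessions=5)
    # photonegative tubes can never be filled at p=0.95 in 5 sessions
    assert res.flagged()
    labels = res.labels()
    assert "original" in labels and any(l.startswith("tube_") for l in labels)


def test_tmaze_retest_protocol_structure():
    model = sb.PopulationModel.spontaneity(0.7)
    res = sb.simulate_retest_protocol(model, "tmaze", replicates=6, seed=16)
    assert len(res.values("original")) == 6
    assert len(res.values("bright")) == 6
    assert res.values("dark_elevator")  # pooled across replicates
    for r in res.records:
        assert -0.964 - 1e-9 <= r.value <= 1.0 + 1e-9


# ---------------------------------------------------------------------------
# Buridan simulator

def test_buridan_constant_speed_kinematics():
    fly = sb.FlyTraits("k", 0.7, 1.0)
    params = sb.BuridanSimParams(duration=60, pause_rate=0.0,
                                 heading_noise=0.0, base_speed=10.0)
    traj = sb.simulate_buridan(fly, params=params, seed=0)
    disp = traj.displacements()
    # every step is speed*dt = 1.0 mm except the shortened edge-flip steps
    full = np.isclose(disp, 1.0, atol=1e-9)
    assert full.mean() > 0.95
    assert np.all(disp <= 1.0 + 1e-9)
    assert np.all(np.hypot(traj.x, traj.y) <= traj.arena.platform_radius + 1e-9)


def test_buridan_zero_activity_is_stationary():
    fly = sb.FlyTraits("z", 0.7, 0.0)
    traj = sb.simulate_buridan(fly, params=sb.BuridanSimParams(duration=30),
                               seed=1)
    assert np.all(traj.displacements() == 0.0)


def test_buridan_path_length_scales_with_activity():
    params = sb.BuridanSimParams(duration=300, pause_rate=0.0)
    t1 = sb.simulate_buridan(sb.FlyTraits("a", 0.7, 1.0), params=params, seed=2)
    t2 = sb.simulate_buridan(sb.FlyTraits("b", 0.7, 2.0), params=params, seed=2)
    ratio = t2.displacements().sum() / t1.displacements().sum()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_buridan_determinism_and_sampling_grid():
    fly = sb.FlyTraits("d", 0.7, 1.0)
    params = sb.BuridanSimParams(duration=45, sampling_rate=10)
    a = sb.simulate_buridan(fly, params=params, seed=3)
    b = sb.simulate_buridan(fly, params=params, seed=3)
    assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
    assert a.n_samples == 451
    assert a.dt == pytest.approx(0.1, abs=1e-12)


def test_trajectory_round_trips_through_reader(tmp_path):
    fly = sb.FlyTraits("rt", 0.6, 1.2)
    traj = sb.simulate_buridan(fly, params=sb.BuridanSimParams(duration=20),
                               seed=4)
    path = ar.write_trajectory(traj, tmp_path / "rt.csv")
    back = ar.read_trajectory(path)
    assert np.array_equal(back.t, traj.t)
    assert np.array_equal(back.x, traj.x)
    assert np.array_equal(back.y, traj.y)
    assert back.fly_id == "rt"
    assert back.arena == traj.arena


def test_traits_csv_round_trip(tmp_path):
    model = sb.PopulationModel.individuality(2, 3, rho=0.2)
    flies = sb.sample_population(model, 20, seed=5)
    path = sb.write_traits_csv(flies, tmp_path / "traits.csv")
    assert sb.read_traits_csv(path) == flies
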