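"""Unit and property tests for the exact stochastic simulation engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirffl import (
    HillTerm,
    Reaction,
    ReactionNetwork,
    Species,
    hill_activation,
    hill_repression,
    network_from_config,
    network_to_config,
    simulate_endpoint_ensemble,
    simulate_ssa,
)
from conftest import birth_death_network


@pytest.mark.parametrize(
    "x,K,n,expected",
    [(0, 200, 2, 0.0), (200, 200, 2, 0.5), (400, 200, 2, 0.8), (60, 60, 2, 0.5)],
)
def test_hill_activation_values(x, K, n, expected):
    assert hill_activation(x, K, n) == pytest.approx(expected)


@pytest.mark.parametrize(
    "x,K,n,expected",
    [(0, 60, 2, 1.0), (60, 60, 2, 0.5), (42, 60, 2, 1 / 1.49)],
)
def test_hill_repression_values(x, K, n, expected):
    assert hill_repression(x, K, n) == pytest.approx(expected)


@given(
    x=st.floats(0, 1e6),
    K=st.floats(1e-3, 1e4),
    n=st.floats(0.5, 6),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_hill_factors_are_complementary_and_bounded(x, K, n):
    act = hill_activation(x, K, n)
    rep = hill_repression(x, K, n)
    assert 0.0 <= act <= 1.0
    assert 0.0 < rep <= 1.0
    assert act + rep == pytest.approx(1.0)


def test_hill_rejects_nonpositive_parameters():
    with pytest.raises(ValueError):
        hill_activation(10, 0, 2)
    with pytest.raises(ValueError):
        hill_repression(10, 60, -1)


def test_network_validation_rejects_unguarded_consumption():
    # death without a count factor could fire at zero copies
    with pytest.raises(ValueError, match="consumes"):
        ReactionNetwork([Species("X", 1)], [Reaction("death", 1.0, {"X": -1})])
    with pytest.raises(ValueError, match="undeclared"):
        ReactionNetwork([Species("X", 1)], [Reaction("r", 1.0, {"Y": 1})])
    with pytest.raises(ValueError, match="unique"):
        ReactionNetwork([Species("X", 1), Species("X", 2)], [])


def test_frozen_system_returns_initial_state():
    net = ReactionNetwork([Species("X", 5)], [])
    assert simulate_ssa(net, t_end=100.0, seed=1).tolist() == [5]
    # zero-rate reactions freeze too
    net = ReactionNetwork([Species("X", 5)], [Reaction("b", 0.0, {"X": 1})])
    assert simulate_ssa(net, t_end=100.0, seed=1).tolist() == [5]


def test_fixed_seed_is_bit_reproducible():
    net = birth_death_network(10.0, 1.0)
    a = simulate_ssa(net, 50.0, seed=123)
    b = simulate_ssa(net, 50.0, seed=123)
    assert np.array_equal(a, b)
    e1 = simulate_endpoint_ensemble(net, 10.0, 50, base_seed=7)
    e2 = simulate_endpoint_ensemble(net, 10.0, 50, base_seed=7)
    assert np.array_equal(e1.counts, e2.counts)
    assert not np.array_equal(
        e1.counts, simulate_endpoint_ensemble(net, 10.0, 50, base_seed=8).counts
    )


def test_trajectory_matches_endpoint_and_stays_nonnegative():
    net = birth_death_network(10.0, 1.0)
    traj = simulate_ssa(net, 30.0, seed=99, record=True)
    assert np.array_equal(traj.endpoint, simulate_ssa(net, 30.0, seed=99))
    assert (traj.states >= 0).all()
    assert (np.diff(traj.times) > 0).all()


@pytest.mark.parametrize("birth,death", [(10.0, 1.0), (5.0, 0.5), (30.0, 2.0)])
def test_birth_death_matches_poisson_stationary_law(birth, death):
    """Ensemble endpoint of a birth-death process follows Poisson(b/d)."""
    lam = birth / death
    n_runs = 4000
    t_end = 12.0 / death  # many relaxation times
    ens = simulate_endpoint_ensemble(birth_death_network(birth, death), t_end, n_runs, base_seed=11)
    x = ens.counts[:, 0]
    se_mean = np.sqrt(lam / n_runs)
    assert abs(x.mean() - lam) < 3 * se_mean
    # var(sample variance) of Poisson ~ (lam + 2 lam^2) / n
    se_var = np.sqrt((lam + 2 * lam**2) / n_runs)
    assert abs(x.var(ddof=1) - lam) < 3 * se_var


def test_time_rescaling_invariance():
    """Doubling all rates and halving the horizon leaves the endpoint law unchanged."""
    slow = simulate_endpoint_ensemble(birth_death_network(10.0, 1.0), 20.0, 3000, base_seed=5)
    fast = simulate_endpoint_ensemble(birth_death_network(20.0, 2.0), 10.0, 3000, base_seed=6)
    p = stats.mannwhitneyu(slow.counts[:, 0], fast.counts[:, 0]).pvalue
    assert p > 0.01


def test_ensemble_summary_and_degenerate_cv():
    net = birth_death_network(10.0, 1.0)
    ens = simulate_endpoint_ensemble(net, 10.0, 500, base_seed=3)
    summ = ens.summary()
    assert summ.loc["X", "cv_percent"] == pytest.approx(
        100 * ens.counts[:, 0].std(ddof=1) / ens.counts[:, 0].mean()
    )
    with pytest.warns(UserWarning, match="one run"):
        single = simulate_endpoint_ensemble(net, 1.0, 1, base_seed=3)
    with pytest.warns(UserWarning):
        assert np.isnan(single.cv_percent()[0])


def test_hill_modulated_propensity_enters_simulation():
    # production gated by an absent activator never fires
    net = ReactionNetwork(
        [Species("A", 0), Species("X", 0)],
        [Reaction("prod", 5.0, {"X": 1}, hill=(HillTerm("A", 10, 2, "activation"),))],
    )
    assert simulate_ssa(net, 100.0, seed=2)[1] == 0
    # repression by an absent repressor leaves the full rate
    net = ReactionNetwork(
        [Species("R", 0), Species("X", 0)],
        [
            Reaction("prod", 5.0, {"X": 1}, hill=(HillTerm("R", 10, 2, "repression"),)),
            Reaction("deg", 1.0, {"X": -1}, {"X": 1}),
        ],
    )
    ens = simulate_endpoint_ensemble(net, 60.0, 800, base_seed=9)
    assert abs(ens.mean()[1] - 5.0) < 3 * np.sqrt(5.0 / 800)


def test_config_round_trip(tmp_path):
    import yaml

    net = ReactionNetwork(
        [Species("TF", 3), Species("X", 0)],
        [
            Reaction("prod", 2.0, {"X": 1}, hill=(HillTerm("TF", 5, 2, "activation"),)),
            Reaction("deg", 0.5, {"X": -1}, {"X": 1}),
        ],
    )
    cfg = network_to_config(net)
    path = tmp_path / "net.yaml"
    path.write_text(yaml.safe_dump(cfg))
    from mirffl import load_network

    net2 = load_network(path)
    assert net2.species_names == net.species_names
    assert np.array_equal(simulate_ssa(net, 10.0, 4), simulate_ssa(net2, 10.0, 4))
    with pytest.raises(ValueError, match="malformed"):
        network_from_config({"species": [{"name": "X"}]})
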