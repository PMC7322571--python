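import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import circuitscreen as cs
from circuitscreen.engine import (
    EngineError,
    SamplingConfig,
    build_ode,
    find_steady_states,
    run_ensemble,
    sample_parameters,
    shifted_hill,
)
from circuitscreen.topology import RegulatoryNetwork

from conftest import toggle_params


# ---------------------------------------------------------------------------
# shifted Hill function
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "B, B0, n, lam, expected",
    [
        (0.0, 10.0, 2, 5.0, 1.0),          # basal multiplier at zero regulator
        (10.0, 10.0, 3, 0.2, 0.6),         # half-saturation gives (1 + lam)/2
        (30.0, 10.0, 2, 0.1, 0.19),        # 0.1 + 0.9 * 1/(1+9)
    ],
)
def test_shifted_hill_values(B, B0, n, lam, expected):
    assert shifted_hill(B, B0, n, lam) == pytest.approx(expected, abs=1e-12)


def test_shifted_hill_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        shifted_hill(1.0, 0.0, 2, 5.0)


@given(
    st.floats(0, 1e4), st.floats(0.1, 1e3), st.integers(1, 6),
    st.floats(0.01, 100).filter(lambda v: abs(v - 1) > 1e-6),
)
def test_shifted_hill_bounded_and_monotone(B, B0, n, lam):
    h = shifted_hill(B, B0, n, lam)
    assert min(1.0, lam) - 1e-12 <= h <= max(1.0, lam) + 1e-12
    h2 = shifted_hill(B * 1.5 + 1.0, B0, n, lam)
    if lam > 1:
        assert h2 >= h - 1e-12
    else:
        assert h2 <= h + 1e-12


# ---------------------------------------------------------------------------
# parameter sampling
# ---------------------------------------------------------------------------

def test_production_rates_uniform_over_range(paper_net, rng):
    cfg = SamplingConfig()
    draws = np.array(
        [sample_parameters(paper_net, cfg, rng).g[0] for _ in range(10_000)]
    )
    assert draws.min() >= cfg.g_range[0] and draws.max() <= cfg.g_range[1]
    ks = sps.kstest(draws, sps.uniform(cfg.g_range[0], np.ptp(cfg.g_range)).cdf)
    assert ks.pvalue > 0.001


def test_parameter_invariants(paper_net, rng):
    cfg = SamplingConfig()
    inhibitory = np.array([e.sign == "inhibition" for e in paper_net.edges])
    for _ in range(200):
        p = sample_parameters(paper_net, cfg, rng)
        assert np.all((p.k >= cfg.k_range[0]) & (p.k <= cfg.k_range[1]))
        assert np.all((p.n >= cfg.n_range[0]) & (p.n <= cfg.n_range[1]))
        assert np.all(p.b0 > 0)
        assert np.all((p.lam[inhibitory] > 0) & (p.lam[inhibitory] < 1))
        assert np.all(p.lam[~inhibitory] > 1)


def test_sampling_is_deterministic(paper_net):
    cfg = SamplingConfig(seed=5)
    a = [sample_parameters(paper_net, cfg, np.random.default_rng(9)) for _ in range(1)]
    b = [sample_parameters(paper_net, cfg, np.random.default_rng(9)) for _ in range(1)]
    assert np.array_equal(a[0].g, b[0].g)
    assert np.array_equal(a[0].b0, b[0].b0)
    assert np.array_equal(a[0].n, b[0].n)


# ---------------------------------------------------------------------------
# ODE assembly
# ---------------------------------------------------------------------------

def unregulated_params():
    net = RegulatoryNetwork(["A"], [])
    return net, cs.ParameterSet(
        node_names=net.nodes,
        g=np.array([50.0]),
        k=np.array([0.5]),
        edge_src=np.array([], dtype=np.int64),
        edge_tgt=np.array([], dtype=np.int64),
        b0=np.array([]),
        n=np.array([], dtype=np.int64),
        lam=np.array([]),
    )


def test_unregulated_node_rates():
    net, params = unregulated_params()
    deriv = build_ode(net, params)
    assert deriv(np.array([100.0]))[0] == pytest.approx(0.0)  # fixed point at g/k
    assert deriv(np.array([0.0]))[0] == pytest.approx(50.0)   # production only


def test_half_saturation_composes_with_ode(toy_circuits):
    net = toy_circuits["toggle_switch"]
    params = toggle_params(net, b0=50.0, lam=0.2)
    deriv = build_ode(net, params)
    # at A = B0 and B = 0, B's production is (1 + lam)/2 of g_B
    f = deriv(np.array([50.0, 0.0]))
    assert f[1] == pytest.approx(50.0 * (1 + 0.2) / 2)


def test_build_ode_rejects_mismatched_params(paper_net, toy_circuits, rng):
    params = sample_parameters(toy_circuits["toggle_switch"], SamplingConfig(), rng)
    with pytest.raises(ValueError):
        build_ode(paper_net, params)


# ---------------------------------------------------------------------------
# steady-state search
# ---------------------------------------------------------------------------

def test_single_node_settles_to_g_over_k(rng):
    net, params = unregulated_params()
    cfg = SamplingConfig(n_init=10)
    search = find_steady_states(build_ode(net, params), params, cfg, rng)
    assert search.n_states == 1
    assert search.states[0, 0] == pytest.approx(100.0, rel=1e-3)


def test_symmetric_toggle_has_mirror_states(toy_circuits, rng):
    net = toy_circuits["toggle_switch"]
    params = toggle_params(net, b0=50.0)
    cfg = SamplingConfig(n_init=60)
    search = find_steady_states(build_ode(net, params), params, cfg, rng)
    assert search.n_states == 2
    a, b = search.states
    assert a[0] == pytest.approx(b[1], rel=1e-6)
    assert a[1] == pytest.approx(b[0], rel=1e-6)
    assert a[0] < a[1]  # A-low/B-high and its mirror


def test_reported_states_satisfy_convergence_criterion(paper_net, rng):
    cfg = SamplingConfig(n_init=20)
    for _ in range(10):
        params = sample_parameters(paper_net, cfg, rng)
        deriv = build_ode(paper_net, params)
        search = find_steady_states(deriv, params, cfg, rng)
        for s in search.states:
            f = deriv(s)
            assert np.max(np.abs(f) / np.maximum(s, 1.0)) < cfg.conv_tol
            assert np.all(s > 0)


def test_states_respect_attainable_range_bound(toy_circuits, rng):
    cfg = SamplingConfig(n_init=30)
    net = toy_circuits["toggle_switch"]
    for _ in range(30):
        params = sample_parameters(net, cfg, rng)
        search = find_steady_states(build_ode(net, params), params, cfg, rng)
        bound = params.state_upper_bound()
        for s in search.states:
            assert np.all(s <= bound * (1 + 1e-6))


def test_stronger_inhibition_never_raises_target(toy_circuits, rng):
    """On A -| B, decreasing lambda (stronger repression) lowers B's state."""
    net = RegulatoryNetwork(["A", "B"], [("A", "B", "inhibition")])
    cfg = SamplingConfig(n_init=10)
    prev_b = np.inf
    for lam in (0.8, 0.4, 0.1, 0.02):
        params = cs.ParameterSet(
            node_names=net.nodes,
            g=np.array([50.0, 80.0]),
            k=np.array([0.5, 0.5]),
            edge_src=np.array([0]),
            edge_tgt=np.array([1]),
            b0=np.array([60.0]),
            n=np.array([3], dtype=np.int64),
            lam=np.array([lam]),
        )
        search = find_steady_states(
            build_ode(net, params), params, cfg, np.random.default_rng(4)
        )
        assert search.n_states == 1
        b_level = search.states[0, 1]
        assert b_level <= prev_b + 1e-9
        prev_b = b_level


# ---------------------------------------------------------------------------
# ensemble driver
# ---------------------------------------------------------------------------

def test_unregulated_ensemble_rows_equal_g_over_k(rng):
    net = RegulatoryNetwork(["A"], [])
    cfg = SamplingConfig(n_param_sets=10, n_init=5, seed=3)
    ens = run_ensemble(net, cfg)
    assert len(ens.data) == 10
    # replay the sampling stream to recover each set's g/k
    replay = np.random.default_rng(cfg.seed)
    for ps_idx in range(10):
        params = sample_parameters(net, cfg, replay)
        replay.uniform(0.0, 1.0, (cfg.n_init, 1))  # initial-condition draws
        expected = params.g[0] / params.k[0]
        row = ens.data[ens.data.param_set == ps_idx].iloc[0]
        assert row["A"] == pytest.approx(expected, rel=1e-6)


def test_default_circuit_is_monostable(paper_net):
    cfg = SamplingConfig(n_param_sets=50, n_init=20, seed=21)
    ens = run_ensemble(paper_net, cfg)
    assert len(ens.data) == 50
    assert (ens.data["n_states"] == 1).all()


def test_ensemble_export_is_deterministic(tmp_path, paper_net):
    cfg = SamplingConfig(n_param_sets=15, n_init=10, seed=11)
    for name in ("a.tsv", "b.tsv"):
        run_ensemble(paper_net, cfg).to_tsv(tmp_path / name)
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()


def test_ensemble_round_trips_through_tsv(tmp_path, paper_net):
    cfg = SamplingConfig(n_param_sets=5, n_init=10, seed=2)
    ens = run_ensemble(paper_net, cfg)
    path = tmp_path / "e.tsv"
    ens.to_tsv(path)
    back = cs.engine.read_ensemble(path)
    assert tuple(back.nodes) == tuple(ens.nodes)
    assert not back.is_log2
    np.testing.assert_allclose(
        back.data[list(ens.nodes)].to_numpy(), ens.data[list(ens.nodes)].to_numpy()
    )


def test_all_sets_failing_is_a_hard_error(paper_net, monkeypatch):
    from circuitscreen import engine as eng

    def empty_search(deriv, params, config, rng):
        return eng.SteadyStateSearch(
            states=np.empty((0, params.n_nodes)), n_init=config.n_init,
            n_converged=0, n_unconverged=config.n_init, n_diverged=0, n_rescued=0,
        )

    monkeypatch.setattr(eng, "find_steady_states", empty_search)
    with pytest.raises(EngineError):
        eng.run_ensemble(paper_net, SamplingConfig(n_param_sets=3, n_init=5))


@pytest.mark.parametrize(
    "kwargs",
    [
        {"g_range": (0.0, 10.0)},
        {"k_range": (1.0, 0.1)},
        {"lambda_range": (0.5, 100.0)},
        {"n_param_sets": 0},
        {"conv_tol": -1.0},
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SamplingConfig(**kwargs)
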