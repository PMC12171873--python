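import numpy as np
import pytest

from nmsm.igme import (
    MarkovPropagator,
    ck_test,
    fit_igme,
    mfpt,
    scan_igme,
    select_endpoints,
    tpm_series,
    tpt_flux,
)
from nmsm.msm_core import stationary_distribution
from nmsm.synthetic_data import gateway_chain_spec, generate_hidden_chain

T2 = np.array([[0.9, 0.1], [0.2, 0.8]])


def _markov_series(T, n):
    return np.stack([np.linalg.matrix_power(T, t) for t in range(1, n + 1)])


@pytest.fixture(scope="module")
def lumped_data():
    spec = gateway_chain_spec(seed=17)
    trajs, truth = generate_hidden_chain(spec, 10, 50_000)
    series = tpm_series(trajs, 2, 120)
    return trajs, truth, series


# ---------------------------------------------------------------------------
# fitting


def test_markovian_input_is_exact_fixed_point():
    model = fit_igme(_markov_series(T2, 30), tau_k=3, L=10)
    assert np.abs(model.A - np.eye(2)).max() < 1e-8
    np.testing.assert_allclose(model.T_hat, T2, atol=1e-10)
    assert model.rmse < 1e-10
    np.testing.assert_allclose(model.T_hat.sum(axis=1), 1.0, atol=1e-8)


def test_single_point_window_interpolates():
    model = fit_igme(_markov_series(T2, 30), tau_k=5, L=1)
    assert model.rmse < 1e-12
    assert np.abs(model.A - np.eye(2)).max() < 1e-10


def test_fit_rejects_window_beyond_data():
    with pytest.raises(ValueError, match="window"):
        fit_igme(_markov_series(T2, 10), tau_k=8, L=5)


def test_igme_recovers_slow_timescale_of_lumped_chain(lumped_data):
    trajs, truth, series = lumped_data
    best, table = scan_igme(
        series, [2, 4, 6, 8, 10, 12, 14, 16, 18, 20],
        [10, 20, 30, 40, 50, 60, 70, 80, 90, 100], lag_unit=0.1
    )
    assert len(table) == 100
    t_igme = best.implied_timescales(1)[0]
    t_true = truth.slow_timescales[0]
    assert t_igme == pytest.approx(t_true, rel=0.10)
    # the plain lag-1 MSM underestimates the same timescale by more
    msm = MarkovPropagator(series[0], lag_unit=0.1)
    t_msm = msm.implied_timescales(1)[0]
    assert abs(t_igme - t_true) < abs(t_msm - t_true)
    # the selected memory time exceeds the generator's fast mixing time
    fast_frames = truth.slow_timescales[-1] / 0.1
    assert best.tau_k > fast_frames


def test_scan_markovian_ties_break_to_smallest_pair():
    best, table = scan_igme(_markov_series(T2, 30), range(0, 10), range(1, 11))
    assert (best.tau_k, best.L) == (0, 1)
    feasible = table.dropna()
    assert len(feasible) == 100
    assert feasible.rmse_all.max() < 1e-10


def test_scan_rejects_infeasible_grids():
    with pytest.raises(ValueError, match="feasible"):
        scan_igme(_markov_series(T2, 5), [10], [10])


# ---------------------------------------------------------------------------
# CK test


def test_ck_markov_model_on_markov_data_passes():
    p = 0.2
    spec_tpm = np.array([[1 - p, p], [p, 1 - p]])
    # identity-lumped 2-state chain: the observation is genuinely Markov
    from nmsm.synthetic_data import HiddenChainSpec

    spec = HiddenChainSpec(2, spec_tpm, np.array([0, 1]), frame_interval=0.1, seed=23)
    trajs, _ = generate_hidden_chain(spec, 10, 10_000)
    series = tpm_series(trajs, 2, 10)
    model = fit_igme(series, tau_k=0, L=5, lag_unit=0.1)
    report = ck_test(model, trajs, [2, 5, 10], seed=1)
    assert report.passed
    assert not report.degenerate


def test_ck_shuffled_model_fails():
    spec_tpm = np.array([[0.8, 0.2], [0.2, 0.8]])
    from nmsm.synthetic_data import HiddenChainSpec

    spec = HiddenChainSpec(2, spec_tpm, np.array([0, 1]), frame_interval=0.1, seed=29)
    trajs, _ = generate_hidden_chain(spec, 10, 10_000)
    bad = MarkovPropagator(spec_tpm[::-1].copy(), lag_unit=0.1)  # rows swapped
    report = ck_test(bad, trajs, [1, 2, 5], seed=1)
    assert not report.passed


def test_ck_igme_passes_where_lag1_msm_fails(lumped_data):
    trajs, _, series = lumped_data
    model = fit_igme(series, tau_k=10, L=60, lag_unit=0.1)
    lags = [10, 25, 50]
    igme_report = ck_test(model, trajs, lags, seed=5)
    msm_report = ck_test(MarkovPropagator(series[0], lag_unit=0.1), trajs, lags, seed=5)
    assert igme_report.passed
    assert not msm_report.passed
    assert igme_report.fraction_within > msm_report.fraction_within


def test_ck_single_trajectory_flagged_degenerate():
    from nmsm.synthetic_data import HiddenChainSpec

    spec = HiddenChainSpec(
        2, np.array([[0.9, 0.1], [0.1, 0.9]]), np.array([0, 1]), seed=2
    )
    trajs, _ = generate_hidden_chain(spec, 1, 2_000)
    series = tpm_series(trajs, 2, 5)
    model = fit_igme(series, 0, 3)
    assert ck_test(model, trajs, [2], seed=0).degenerate


# ---------------------------------------------------------------------------
# MFPT


def test_mfpt_closed_form_two_state():
    M = mfpt(T2, lag_unit=2.0)
    assert M[0, 1] == pytest.approx(20.0)
    assert M[1, 0] == pytest.approx(10.0)
    assert M[0, 0] == 0.0 and M[1, 1] == 0.0


def test_mfpt_permutation_equivariance():
    T = np.array([[0.7, 0.2, 0.1], [0.3, 0.5, 0.2], [0.1, 0.1, 0.8]])
    perm = [2, 0, 1]
    P = np.eye(3)[perm]
    M = mfpt(T)
    Mp = mfpt(P @ T @ P.T)
    np.testing.assert_allclose(Mp, M[np.ix_(perm, perm)], atol=1e-10)


def test_mfpt_agrees_with_fundamental_matrix_oracle():
    T = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.05, 0.15, 0.8]])
    M = mfpt(T)
    # independent oracle: absorbing-chain fundamental matrix N = (I-Q)^-1,
    # MFPT_i->t = sum_j N_ij
    for target in range(3):
        keep = [i for i in range(3) if i != target]
        N = np.linalg.inv(np.eye(2) - T[np.ix_(keep, keep)])
        np.testing.assert_allclose(M[keep, target], N.sum(axis=1), atol=1e-10)


def test_mfpt_rejects_reducible():
    with pytest.raises(ValueError, match="reducible"):
        mfpt(np.eye(2))


# ---------------------------------------------------------------------------
# TPT


def _linear_3chain():
    return np.array([[0.8, 0.2, 0.0], [0.2, 0.6, 0.2], [0.0, 0.2, 0.8]])


def test_committor_symmetric_linear_chain():
    flux = tpt_flux(_linear_3chain(), source=0, sink=2)
    np.testing.assert_allclose(flux.q_plus, [0.0, 0.5, 1.0], atol=1e-12)
    assert flux.q_minus[0] == 1.0 and flux.q_minus[2] == 0.0


def test_flux_conservation_on_random_chains():
    rng = np.random.default_rng(77)
    for _ in range(50):
        n = rng.integers(3, 9)
        T = rng.uniform(0.05, 1.0, (n, n))
        T /= T.sum(axis=1, keepdims=True)
        source, sink = 0, n - 1
        flux = tpt_flux(T, source=source, sink=sink)
        assert np.all((flux.q_plus >= -1e-12) & (flux.q_plus <= 1 + 1e-12))
        assert np.all((flux.q_minus >= -1e-12) & (flux.q_minus <= 1 + 1e-12))
        out_src = flux.netflux[source].sum() - flux.netflux[:, source].sum()
        into_sink = flux.netflux[:, sink].sum() - flux.netflux[sink].sum()
        assert out_src == pytest.approx(flux.total_flux, abs=1e-10)
        assert into_sink == pytest.approx(flux.total_flux, abs=1e-10)
        for i in range(n):
            if i in (source, sink):
                continue
            assert flux.netflux[i].sum() - flux.netflux[:, i].sum() == pytest.approx(
                0.0, abs=1e-10
            )


def _two_branch_chain():
    # 0 -> {1 (70%), 2 (30%)} -> 3 -> 0; branch states feed only forward
    return np.array(
        [
            [0.90, 0.07, 0.03, 0.0],
            [0.0, 0.9, 0.0, 0.1],
            [0.0, 0.0, 0.9, 0.1],
            [0.1, 0.0, 0.0, 0.9],
        ]
    )


def test_two_branch_flux_split_against_enumeration_oracle():
    T = _two_branch_chain()
    flux = tpt_flux(T, source=0, sink=3)
    # brute-force oracle: enumerate all simple paths in the netflux graph
    import itertools

    n = 4
    best_cap, total_path_flux = 0.0, 0.0
    for r in range(2, n + 1):
        for mid in itertools.permutations([1, 2], r - 2):
            path = [0, *mid, 3]
            caps = [flux.netflux[a, b] for a, b in zip(path[:-1], path[1:])]
            if min(caps) > 0:
                best_cap = max(best_cap, min(caps))
    assert flux.pathways, "decomposition must find pathways"
    dominant_path, dominant_cap = flux.pathways[0]
    assert dominant_cap == pytest.approx(best_cap, rel=1e-9)
    assert dominant_path == [0, 1, 3]
    assert dominant_cap / flux.total_flux == pytest.approx(0.7, abs=0.02)


def test_tpt_rejects_bad_endpoints():
    with pytest.raises(ValueError, match="differ"):
        tpt_flux(_linear_3chain(), source=1, sink=1)


def test_select_endpoints():
    assert select_endpoints(np.array([1.2, 0.0, 0.4])) == (0, 1)
    with pytest.raises(ValueError, match="degenerate"):
        select_endpoints(np.array([0.3, 0.3, 0.3]))
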