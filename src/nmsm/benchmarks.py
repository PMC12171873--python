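"""Self-contained validation experiments on synthetic systems.

Each function runs one pipeline capability against its analytic oracle and
returns a flat dict of measured quantities.  They are used both by the
test suite and by the reproduction script; all randomness is controlled by
the explicit seed arguments.
"""

from __future__ import annotations

import collections
import itertools

import numpy as np

from . import featurize, igme, msm_core, som_pathways, synthetic_data

__all__ = [
    "igme_recovery",
    "ck_discrimination",
    "markovian_limit",
    "closed_forms",
    "tpt_properties",
    "som_pathway_recovery",
    "geometry_oracles",
]

# 100-model scan grid; lags beyond ~2x the slow timescale carry almost no
# slow-mode signal, so the series is kept to 60 frames
_TAU_GRID = tuple(range(1, 11))
_L_GRID = tuple(range(5, 55, 5))


def _pct_err(est: float, true: float) -> float:
    return 100.0 * abs(est - true) / abs(true)


def igme_recovery(
    seed: int,
    n_traj: int = 50,
    traj_frames: int = 20_000,
    max_lag: int = 60,
) -> dict:
    """Slow-timescale and MFPT recovery from a 2-macro lumped observation
    of the gateway chain, IGME vs the lag-1 Markov MSM, against the exact
    hidden-chain values."""
    spec = synthetic_data.gateway_chain_spec(seed=seed)
    trajs, truth = synthetic_data.generate_hidden_chain(spec, n_traj, traj_frames)
    dt = spec.frame_interval
    series = igme.tpm_series(trajs, spec.n_macro, max_lag)
    best, _ = igme.scan_igme(series, _TAU_GRID, _L_GRID, lag_unit=dt)
    msm = igme.MarkovPropagator(series[0], lag_unit=dt)
    t_true = float(truth.slow_timescales[0])
    t_igme = float(best.implied_timescales(1)[0])
    t_msm = float(msm.implied_timescales(1)[0])
    m_true = float(truth.mfpt_matrix[0, 1])
    m_igme = float(igme.mfpt(best)[0, 1])
    m_msm = float(igme.mfpt(msm)[0, 1])
    return {
        "n_frames": n_traj * traj_frames,
        "tau_k": best.tau_k,
        "L": best.L,
        "true_timescale_ns": t_true,
        "igme_timescale_ns": t_igme,
        "msm_timescale_ns": t_msm,
        "igme_timescale_error_pct": _pct_err(t_igme, t_true),
        "msm_timescale_error_pct": _pct_err(t_msm, t_true),
        "true_mfpt_ns": m_true,
        "igme_mfpt_ns": m_igme,
        "msm_mfpt_ns": m_msm,
        "igme_mfpt_error_pct": _pct_err(m_igme, m_true),
        "msm_mfpt_error_pct": _pct_err(m_msm, m_true),
    }


def ck_discrimination(
    seed: int,
    n_traj: int = 50,
    traj_frames: int = 20_000,
    test_lags=(10, 25, 50),
    n_boot: int = 200,
) -> dict:  # same sampling depth as igme_recovery
    """Chapman-Kolmogorov pass/fail for the IGME model vs the lag-1 MSM on
    lumped gateway-chain data (bootstrap over trajectories)."""
    spec = synthetic_data.gateway_chain_spec(seed=seed)
    trajs, _ = synthetic_data.generate_hidden_chain(spec, n_traj, traj_frames)
    dt = spec.frame_interval
    series = igme.tpm_series(trajs, spec.n_macro, max(60, *test_lags))
    model, _ = igme.scan_igme(series, _TAU_GRID, _L_GRID, lag_unit=dt)
    msm = igme.MarkovPropagator(series[0], lag_unit=dt)
    rep_igme = igme.ck_test(model, trajs, list(test_lags), n_boot=n_boot, seed=seed)
    rep_msm = igme.ck_test(msm, trajs, list(test_lags), n_boot=n_boot, seed=seed)
    return {
        "n_frames": n_traj * traj_frames,
        "igme_ck_passed": bool(rep_igme.passed),
        "msm_ck_passed": bool(rep_msm.passed),
        "igme_ck_fraction_within": rep_igme.fraction_within,
        "msm_ck_fraction_within": rep_msm.fraction_within,
    }


def markovian_limit(n_lags: int = 30) -> dict:
    """Exact TPM powers in, memory-free model out: A must be the identity,
    T-hat the input matrix, and every feasible scan cell must fit with
    vanishing RMSE."""
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    series = np.stack([np.linalg.matrix_power(T, t) for t in range(1, n_lags + 1)])
    best, table = igme.scan_igme(series, range(0, 10), range(1, 11))
    feasible = table.dropna()
    return {
        "n_lags": n_lags,
        "n_models": len(table),
        "A_identity_max_dev": float(np.abs(best.A - np.eye(2)).max()),
        "That_max_dev": float(np.abs(best.T_hat - T).max()),
        "scan_max_rmse": float(feasible.rmse_all.max()),
        "selected_tau_k": best.tau_k,
        "selected_L": best.L,
    }


def closed_forms() -> dict:
    """Textbook values: 2-state MFPT at a 2 ns lag, the symmetric 2-state
    stationary distribution, and the symmetric 3-state committor."""
    M = igme.mfpt(np.array([[0.9, 0.1], [0.2, 0.8]]), lag_unit=2.0)
    pi = msm_core.stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
    chain3 = np.array([[0.8, 0.2, 0.0], [0.2, 0.6, 0.2], [0.0, 0.2, 0.8]])
    flux = igme.tpt_flux(chain3, source=0, sink=2)
    return {
        "mfpt_12_ns": float(M[0, 1]),
        "mfpt_21_ns": float(M[1, 0]),
        "stationary_state1": float(pi[0]),
        "committor_source": float(flux.q_plus[0]),
        "committor_mid": float(flux.q_plus[1]),
        "committor_sink": float(flux.q_plus[2]),
    }


def tpt_properties(seed: int, n_chains: int = 50) -> dict:
    """Flux conservation on random irreducible chains plus the dominant
    pathway share on a constructed 70/30 two-branch network (checked
    against simple-path enumeration)."""
    rng = np.random.default_rng(seed)
    max_violation = 0.0
    committor_min, committor_max = np.inf, -np.inf
    for _ in range(n_chains):
        n = int(rng.integers(3, 9))
        T = rng.uniform(0.05, 1.0, (n, n))
        T /= T.sum(axis=1, keepdims=True)
        flux = igme.tpt_flux(T, source=0, sink=n - 1)
        committor_min = min(committor_min, float(flux.q_plus.min()), float(flux.q_minus.min()))
        committor_max = max(committor_max, float(flux.q_plus.max()), float(flux.q_minus.max()))
        div = flux.netflux.sum(axis=1) - flux.netflux.sum(axis=0)
        expected = np.zeros(n)
        expected[0] = flux.total_flux
        expected[n - 1] = -flux.total_flux
        max_violation = max(max_violation, float(np.abs(div - expected).max()))
    # two-branch chain: source feeds branch states with 7%/3% per step
    T = np.array(
        [
            [0.90, 0.07, 0.03, 0.0],
            [0.0, 0.9, 0.0, 0.1],
            [0.0, 0.0, 0.9, 0.1],
            [0.1, 0.0, 0.0, 0.9],
        ]
    )
    flux = igme.tpt_flux(T, source=0, sink=3)
    # enumeration oracle for the dominant simple path
    best_cap = 0.0
    for r in range(0, 3):
        for mid in itertools.permutations([1, 2], r):
            path = [0, *mid, 3]
            caps = [flux.netflux[a, b] for a, b in zip(path[:-1], path[1:])]
            if caps and min(caps) > best_cap:
                best_cap = min(caps)
    dominant = flux.pathways[0]
    return {
        "n_chains": n_chains,
        "max_conservation_violation": max_violation,
        "committor_min": committor_min,
        "committor_max": committor_max,
        "dominant_path_flux_pct": 100.0 * dominant[1] / flux.total_flux,
        "dominant_path_matches_enumeration": bool(abs(dominant[1] - best_cap) < 1e-12),
    }


def som_pathway_recovery(
    seed: int,
    n_traj: int = 200,
    max_steps: int = 6000,
    cycles: int = 5000,
) -> dict:
    """Full pathway-detection leg on the symmetric two-branch channel:
    extract the two egress pathways, map them to branches via the distance
    heatmap, and score per-trajectory assignments against the generator's
    branch labels."""
    spec = synthetic_data.two_branch_channel_spec(seed=seed)
    trajs, truth = synthetic_data.generate_channel_egress(spec, n_traj, max_steps)
    tables = synthetic_data.egress_feature_tables(spec, trajs)
    som = som_pathways.train_som(tables, grid=(10, 10), cycles=cycles, seed=seed)
    clustering = som_pathways.cluster_neurons(som, range(2, 9))
    network = som_pathways.build_transition_network(som)
    heatmap = som_pathways.cluster_heatmap(tables, som, clustering)
    bound, unbound = som_pathways.identify_endpoints(clustering, heatmap, network)
    paths = som_pathways.extract_pathways(network, clustering, som, bound, unbound, n_paths=2)
    branch_cols = {
        b: [c for c in heatmap.columns if c.startswith(f"BR{b}_")] for b in (0, 1)
    }
    branch_of_path = []
    for p in paths:
        inter = p.clusters[1:-1] or p.clusters
        scores = [
            float(np.nanmean(heatmap.loc[inter, branch_cols[b]].to_numpy())) for b in (0, 1)
        ]
        branch_of_path.append(int(np.argmin(scores)))
    assignments = som_pathways.assign_trajectories(som, clustering, paths)
    matched = exited = 0
    assigned_counts = collections.Counter()
    for a, label in zip(assignments, truth.branch_labels):
        if label is None:
            continue
        exited += 1
        if a is not None and branch_of_path[a] == label:
            matched += 1
        if a is not None:
            assigned_counts[branch_of_path[a]] += 1
    exits = collections.Counter(truth.branch_labels)
    true_frac = exits[0] / (exits[0] + exits[1])
    som_frac = assigned_counts[0] / max(1, assigned_counts[0] + assigned_counts[1])
    return {
        "n_traj": n_traj,
        "n_exited": exited,
        "n_pathways": len(paths),
        "pathways_cover_both_branches": len(set(branch_of_path)) == 2,
        "n_clusters": clustering.k,
        "branch_accuracy_pct": 100.0 * matched / exited,
        "true_branch0_fraction": true_frac,
        "assigned_branch0_fraction": som_frac,
        "support_fraction_abs_dev": abs(som_frac - true_frac),
    }


def geometry_oracles(rng_seed: int = 0) -> dict:
    """Constructed-geometry oracles: chi1 round trip and rotamer labels,
    the analytic single-sphere SASA, the hand-enumerated residence
    occupancy, and distance-cap saturation."""
    from .trajectory_io import Atom, Trajectory

    targets = [180.0, -60.0, 60.0, 0.01, 119.999, -120.0]
    toy = synthetic_data.generate_rotamer_toy(targets)
    chi = featurize.compute_chi1(toy, "A:1").values[:, 0]
    chi1_max_err = float(np.abs(chi - np.asarray(targets)).max())
    labels = [featurize.classify_rotamer(c).label for c in chi[:3]]
    convention_ok = labels == ["trans", "gauche_plus", "gauche_minus"]

    atoms = [Atom("C1", "XXX", 1, "A", "C")]
    lone = Trajectory(atoms, np.zeros((1, 1, 3)), 0.1)
    sasa = featurize.compute_sasa(lone, "A:1").values[0, 0]
    sasa_expected = 4.0 * np.pi * (1.7 + 1.4) ** 2

    pair = [Atom("C1", "LIG", 1, "L", "C"), Atom("CA", "ALA", 1, "A", "C")]
    frames = [[[0, 0, 0], [d, 0, 0]] for d in (3.5, 3.9, 4.2, 3.0, 5.1)]
    traj = Trajectory(pair, np.asarray(frames, float), 0.1)
    report = featurize.residence_time(traj, "resname:LIG", "A:1", cutoff=4.0)

    far = Trajectory(pair, np.asarray([[[0, 0, 0], [40.0, 0, 0]]]), 0.1)
    capped = featurize.compute_ligand_distances(far, "resname:LIG", "A:1", cap=12.0)

    return {
        "chi1_max_error_deg": chi1_max_err,
        "rotamer_convention_ok": convention_ok,
        "sasa_sphere_aa2": float(sasa),
        "sasa_sphere_expected_aa2": float(sasa_expected),
        "sasa_sphere_error_pct": _pct_err(sasa, sasa_expected),
        "residence_occupancy": report.occupancy,
        "residence_consistent": report.consistent,
        "capped_distance_max_aa": float(capped.values.max()),
    }
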