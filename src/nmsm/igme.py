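"""Integrative generalized master equation (IGME) for lumped macrostate
dynamics, with Chapman-Kolmogorov validation, mean first passage times and
transition-path-theory flux decomposition.

A lumped observation of a metastable system is non-Markovian at short lag
times: the macrostate transition matrix series T(t) estimated from data is
not a matrix power of T(1).  The IGME absorbs the integrated memory
kernels into a constant correction and models

    T(t) ≈ A · T̂^t,

where T̂ is the long-time propagator (one step per base lag) and A carries
the short-time memory amplitude.  Taking the principal matrix logarithm
makes this linear, ln T(t) ≈ ln A + t · ln T̂, and the fit is an ordinary
elementwise least squares over the lag window t ∈ {τk+1, …, τk+L}: τk is
the memory-kernel relaxation time (lags inside it are discarded because
the kernels have not decayed) and L is the window length.  Hyperparameters
are scanned on a grid and ranked by the RMSE between predicted and
estimated TPMs over all lags beyond τk.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .msm_core import _as_traj_list, _is_irreducible, count_matrix, stationary_distribution

logger = logging.getLogger(__name__)

__all__ = [
    "IGMEModel",
    "MarkovPropagator",
    "CKReport",
    "FluxNetwork",
    "tpm_series",
    "fit_igme",
    "scan_igme",
    "ck_test",
    "mfpt",
    "tpt_flux",
    "select_endpoints",
]


def tpm_series(labels, n_states: int, max_lag: int, mode: str = "sliding") -> np.ndarray:
    """Row-normalised TPM estimates at every lag 1..max_lag (shape
    (max_lag, n, n)); raises if some state has no outgoing pairs at a lag."""
    trajs = _as_traj_list(labels)
    out = np.empty((max_lag, n_states, n_states))
    for lag in range(1, max_lag + 1):
        counts = count_matrix(trajs, lag, n_states=n_states, mode=mode).astype(float)
        rows = counts.sum(axis=1, keepdims=True)
        if (rows == 0).any():
            missing = np.nonzero(rows[:, 0] == 0)[0]
            raise ValueError(f"state(s) {missing.tolist()} have no transitions at lag {lag}")
        out[lag - 1] = counts / rows
    return out


@dataclass
class IGMEModel:
    """Fitted non-Markovian propagator T(t) = A·T̂^t.

    ``lag_unit`` converts one step of T̂ to physical time (ns).
    """

    tau_k: int
    L: int
    A: np.ndarray
    T_hat: np.ndarray
    rmse: float
    lag_unit: float = 1.0
    rmse_extrapolation: float = np.nan

    def predict(self, t: int) -> np.ndarray:
        """Predicted TPM at lag t (entries clamped to [0, 1])."""
        pred = self.A @ np.linalg.matrix_power(self.T_hat, int(t))
        return np.clip(pred, 0.0, 1.0)

    def implied_timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales (ns) of the long-time propagator T̂."""
        w = np.sort(np.abs(np.linalg.eigvals(self.T_hat)))[::-1][1:]
        w = w[: n if n is not None else len(w)]
        with np.errstate(divide="ignore"):
            return np.where((w > 0) & (w < 1), -self.lag_unit / np.log(w), np.nan)


@dataclass
class MarkovPropagator:
    """Plain MSM baseline: T(t) = T(1)^t.  Shares the prediction interface
    of :class:`IGMEModel` so both can be run through the CK test."""

    T: np.ndarray
    lag_unit: float = 1.0

    def predict(self, t: int) -> np.ndarray:
        return np.clip(np.linalg.matrix_power(self.T, int(t)), 0.0, 1.0)

    def implied_timescales(self, n: int | None = None) -> np.ndarray:
        w = np.sort(np.abs(np.linalg.eigvals(self.T)))[::-1][1:]
        w = w[: n if n is not None else len(w)]
        with np.errstate(divide="ignore"):
            return np.where((w > 0) & (w < 1), -self.lag_unit / np.log(w), np.nan)


def _principal_log(matrix: np.ndarray, lag: int) -> np.ndarray:
    if abs(np.linalg.det(matrix)) < 1e-300:
        raise ValueError(f"non-invertible TPM at lag {lag}")
    lm = scipy.linalg.logm(matrix)
    if np.abs(lm.imag).max() > 1e-6 * max(1.0, np.abs(lm.real).max()):
        raise ValueError(f"complex matrix logarithm at lag {lag}")
    return lm.real


def _project_stochastic(matrix: np.ndarray) -> np.ndarray:
    out = np.clip(matrix, 0.0, None)
    rows = out.sum(axis=1, keepdims=True)
    rows[rows == 0] = 1.0
    return out / rows


def _window_rmse(model: IGMEModel, series: np.ndarray, lags: np.ndarray) -> float:
    sq = 0.0
    for t in lags:
        diff = model.predict(t) - series[t - 1]
        sq += float((diff**2).mean())
    return float(np.sqrt(sq / len(lags)))


def fit_igme(series: np.ndarray, tau_k: int, L: int, lag_unit: float = 1.0) -> IGMEModel:
    """Fit T(t) = A·T̂^t to TPM estimates over t ∈ {tau_k+1, …, tau_k+L}.

    ``series[t-1]`` must hold the TPM at lag t frames.  The fit is an
    elementwise OLS in log-matrix space; if a window matrix has a complex
    or defective logarithm the fit falls back to direct nonlinear least
    squares on T(t) initialised from the largest usable log-space fit.
    T̂ is projected back onto the stochastic simplex (clip + renormalise).
    """
    series = np.asarray(series, float)
    n_lags, n, _ = series.shape
    if tau_k < 0 or L < 1:
        raise ValueError("tau_k must be >= 0 and L >= 1")
    if tau_k + L > n_lags:
        raise ValueError(f"fit window tau_k+L={tau_k + L} exceeds available lags ({n_lags})")
    window = np.arange(tau_k + 1, tau_k + L + 1)
    logs = []
    usable = []
    fallback = False
    for t in window:
        try:
            logs.append(_principal_log(series[t - 1], t))
            usable.append(t)
        except ValueError as err:
            logger.warning("log-space fit degraded: %s", err)
            fallback = True
    if not usable:
        raise ValueError("no TPM in the fit window has a real matrix logarithm")
    ts = np.asarray(usable, float)
    Y = np.stack(logs).reshape(len(usable), n * n)
    if len(usable) == 1:
        # a single lag cannot identify memory: attribute everything to the
        # propagator (A = I), which interpolates the point exactly
        lnA = np.zeros((n, n))
        lnT = logs[0] / ts[0]
    else:
        design = np.column_stack([np.ones_like(ts), ts])
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
        lnA = coef[0].reshape(n, n)
        lnT = coef[1].reshape(n, n)
    A = scipy.linalg.expm(lnA).real
    T_hat = _project_stochastic(scipy.linalg.expm(lnT).real)
    model = IGMEModel(tau_k=tau_k, L=L, A=A, T_hat=T_hat, lag_unit=lag_unit, rmse=np.nan)
    if fallback:
        model = _refit_nonlinear(model, series, window, lag_unit)
    model.rmse = _window_rmse(model, series, window)
    return model


def _refit_nonlinear(init: IGMEModel, series: np.ndarray, window: np.ndarray, lag_unit: float) -> IGMEModel:
    n = init.A.shape[0]

    def residuals(x):
        A = x[: n * n].reshape(n, n)
        T = _project_stochastic(np.abs(x[n * n :]).reshape(n, n))
        out = []
        for t in window:
            out.append((A @ np.linalg.matrix_power(T, int(t)) - series[t - 1]).ravel())
        return np.concatenate(out)

    x0 = np.concatenate([init.A.ravel(), init.T_hat.ravel()])
    sol = scipy.optimize.least_squares(residuals, x0, method="lm", max_nfev=2000)
    A = sol.x[: n * n].reshape(n, n)
    T_hat = _project_stochastic(np.abs(sol.x[n * n :]).reshape(n, n))
    return IGMEModel(
        tau_k=init.tau_k, L=init.L, A=A, T_hat=T_hat, lag_unit=lag_unit, rmse=np.nan
    )


def scan_igme(series: np.ndarray, tau_k_grid, L_grid, lag_unit: float = 1.0,
              eval_mode: str = "common"):
    """Fit every (τk, L) pair; rank by prediction RMSE over a lag range.

    With ``eval_mode='common'`` (default) every candidate is scored on the
    same lag set — all lags beyond the largest τk in the grid — so the
    ranking compares like with like; ``'beyond_tau'`` scores each candidate
    on all lags beyond its own τk (which lets large-τk models dodge the
    short-lag region where the memory correction is tested).  Returns
    ``(best_model, table)`` with one table row per pair.  Ties break toward
    smaller τk, then smaller L (parsimony).
    """
    series = np.asarray(series, float)
    n_lags = series.shape[0]
    tau_k_grid = sorted(int(t) for t in tau_k_grid)
    L_grid = sorted(int(l) for l in L_grid)
    if not tau_k_grid or not L_grid:
        raise ValueError("empty hyperparameter grid")
    if eval_mode not in ("common", "beyond_tau"):
        raise ValueError("eval_mode must be 'common' or 'beyond_tau'")
    common_lags = np.arange(min(max(tau_k_grid) + 1, n_lags), n_lags + 1)
    rows = []
    best = None
    best_rmse = np.inf
    feasible = 0
    for tau_k in tau_k_grid:
        eval_lags = common_lags if eval_mode == "common" else np.arange(tau_k + 1, n_lags + 1)
        for L in L_grid:
            if tau_k + L > n_lags:
                rows.append({"tau_k": tau_k, "L": L, "rmse_window": np.nan, "rmse_all": np.nan})
                continue
            feasible += 1
            model = fit_igme(series, tau_k, L, lag_unit=lag_unit)
            rmse_all = _window_rmse(model, series, eval_lags)
            model.rmse_extrapolation = rmse_all
            rows.append(
                {"tau_k": tau_k, "L": L, "rmse_window": model.rmse, "rmse_all": rmse_all}
            )
            if rmse_all < best_rmse - 1e-12:  # strict improvement; earlier (smaller) pair wins ties
                best_rmse = rmse_all
                best = model
    if feasible == 0:
        raise ValueError("no feasible (tau_k, L) pair for the available lags")
    return best, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Chapman-Kolmogorov test


@dataclass
class CKReport:
    test_lags: list
    model_tpm: dict
    data_tpm: dict
    lower: dict
    upper: dict
    deviations: dict
    passed: bool
    fraction_within: float
    degenerate: bool = False


def ck_test(
    model,
    labels,
    test_lags,
    n_boot: int = 200,
    seed: int = 0,
    pass_fraction: float = 0.95,
) -> CKReport:
    """Compare model-predicted T(t) with TPMs re-estimated from the data.

    Bootstrap intervals (percentile 2.5/97.5) come from resampling whole
    trajectories with replacement; the test passes when the model curve
    lies inside the interval for at least ``pass_fraction`` of elements
    across all test lags.  With fewer than two trajectories the intervals
    are degenerate and flagged.
    """
    trajs = _as_traj_list(labels)
    n_states = int(max(t.max() for t in trajs)) + 1
    rng = np.random.default_rng(seed)
    test_lags = [int(t) for t in test_lags]
    if any(all(t.size <= lag for t in trajs) for lag in test_lags):
        raise ValueError("a test lag exceeds every trajectory length")

    # per-trajectory counts once; bootstrap just re-sums them
    per_traj = {
        lag: np.stack(
            [
                count_matrix([t], lag, n_states=n_states)
                if t.size > lag
                else np.zeros((n_states, n_states), dtype=np.int64)
                for t in trajs
            ]
        )
        for lag in test_lags
    }

    def tpm_of(counts: np.ndarray) -> np.ndarray:
        rows = counts.sum(axis=1, keepdims=True).astype(float)
        rows[rows == 0] = np.nan
        return counts / rows

    data_tpm = {lag: tpm_of(per_traj[lag].sum(axis=0)) for lag in test_lags}
    model_tpm = {lag: model.predict(lag) for lag in test_lags}

    degenerate = len(trajs) < 2
    lower, upper = {}, {}
    if degenerate:
        logger.warning("fewer than 2 trajectories: CK intervals are degenerate")
        for lag in test_lags:
            lower[lag] = data_tpm[lag].copy()
            upper[lag] = data_tpm[lag].copy()
    else:
        idx = rng.integers(0, len(trajs), size=(n_boot, len(trajs)))
        for lag in test_lags:
            boots = np.stack([tpm_of(per_traj[lag][draw].sum(axis=0)) for draw in idx])
            lower[lag] = np.nanpercentile(boots, 2.5, axis=0)
            upper[lag] = np.nanpercentile(boots, 97.5, axis=0)

    within = 0
    total = 0
    deviations = {}
    for lag in test_lags:
        deviations[lag] = np.abs(model_tpm[lag] - data_tpm[lag])
        ok = (model_tpm[lag] >= lower[lag] - 1e-12) & (model_tpm[lag] <= upper[lag] + 1e-12)
        within += int(np.count_nonzero(ok))
        total += ok.size
    fraction = within / total
    return CKReport(
        test_lags=test_lags,
        model_tpm=model_tpm,
        data_tpm=data_tpm,
        lower=lower,
        upper=upper,
        deviations=deviations,
        passed=fraction >= pass_fraction,
        fraction_within=fraction,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# MFPT


def mfpt(model_or_tpm, lag_unit: float | None = None) -> np.ndarray:
    """Mean first passage time matrix (ns) of a discrete-time chain.

    For an :class:`IGMEModel` the row-normalised long-time propagator T̂ is
    used (the memory correction A only affects short-time predictions).
    Solves (I − T_B) m = Δt·1 with the target row/column removed.
    """
    if isinstance(model_or_tpm, (IGMEModel, MarkovPropagator)):
        T = model_or_tpm.T_hat if isinstance(model_or_tpm, IGMEModel) else model_or_tpm.T
        dt = model_or_tpm.lag_unit if lag_unit is None else lag_unit
    else:
        T = np.asarray(model_or_tpm, float)
        dt = 1.0 if lag_unit is None else lag_unit
    if not _is_irreducible(T):
        raise ValueError("transition matrix is reducible; MFPT undefined")
    n = T.shape[0]
    out = np.zeros((n, n))
    for target in range(n):
        keep = [i for i in range(n) if i != target]
        sub = T[np.ix_(keep, keep)]
        m = np.linalg.solve(np.eye(n - 1) - sub, dt * np.ones(n - 1))
        out[keep, target] = m
    return out


# ---------------------------------------------------------------------------
# Transition path theory


@dataclass
class FluxNetwork:
    source: int
    sink: int
    q_plus: np.ndarray
    q_minus: np.ndarray
    netflux: np.ndarray
    total_flux: float
    pathways: list = field(default_factory=list)  # (path, capacity) tuples


def _committor(T: np.ndarray, source: int, sink: int) -> np.ndarray:
    n = T.shape[0]
    q = np.zeros(n)
    q[sink] = 1.0
    inter = [i for i in range(n) if i not in (source, sink)]
    if inter:
        Tii = T[np.ix_(inter, inter)]
        rhs = T[inter, sink]
        q[inter] = np.linalg.solve(np.eye(len(inter)) - Tii, rhs)
    return q


def _widest_path(capacity: dict, source: int, sink: int, nodes) -> tuple[list, float]:
    """Maximum-bottleneck simple path via a Dijkstra variant."""
    best = {node: 0.0 for node in nodes}
    best[source] = np.inf
    prev: dict = {}
    heap = [(-np.inf, source)]
    done = set()
    while heap:
        neg_width, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == sink:
            break
        for (a, b), cap in capacity.items():
            if a != u or cap <= 0:
                continue
            width = min(-neg_width, cap)
            if width > best[b]:
                best[b] = width
                prev[b] = u
                heapq.heappush(heap, (-width, b))
    if best[sink] <= 0:
        return [], 0.0
    path = [sink]
    while path[-1] != source:
        path.append(prev[path[-1]])
    return path[::-1], best[sink]


def tpt_flux(
    tpm,
    stationary: np.ndarray | None = None,
    source: int = 0,
    sink: int = 1,
    min_flux_fraction: float = 0.01,
) -> FluxNetwork:
    """Reactive flux decomposition from source to sink.

    Forward committor q+ solves the standard linear system with
    q+(source)=0, q+(sink)=1; the backward committor uses the
    time-reversed chain.  Gross flux f_ij = π_i q−_i T_ij q+_j is
    antisymmetrised to net flux, and pathways are peeled off in order of
    bottleneck capacity until less than ``min_flux_fraction`` of the total
    flux remains.
    """
    T = tpm.matrix if hasattr(tpm, "matrix") else np.asarray(tpm, float)
    if source == sink:
        raise ValueError("source and sink must differ")
    if not _is_irreducible(T):
        raise ValueError("chain is not irreducible")
    pi = stationary_distribution(T) if stationary is None else np.asarray(stationary, float)
    n = T.shape[0]
    q_plus = _committor(T, source, sink)
    T_rev = (pi[None, :] * T.T) / pi[:, None]
    q_minus = _committor(T_rev, sink, source)  # committor to source under reversed dynamics
    f = pi[:, None] * q_minus[:, None] * T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.clip(f - f.T, 0.0, None)
    total = float(net[source].sum() - net[:, source].sum())
    capacity = {(i, j): net[i, j] for i in range(n) for j in range(n) if net[i, j] > 0}
    pathways = []
    remaining = total
    nodes = range(n)
    while remaining > min_flux_fraction * total:
        path, width = _widest_path(capacity, source, sink, nodes)
        if not path or width <= 0:
            break
        pathways.append((path, width))
        for a, b in zip(path[:-1], path[1:]):
            capacity[(a, b)] -= width
        remaining -= width
    return FluxNetwork(
        source=source,
        sink=sink,
        q_plus=q_plus,
        q_minus=q_minus,
        netflux=net,
        total_flux=total,
        pathways=pathways,
    )


def select_endpoints(free_energy_vec: np.ndarray) -> tuple[int, int]:
    """Source = highest-free-energy state, sink = lowest (ΔG = 0).

    Ties resolve toward the lowest index with a log message; a flat
    landscape is rejected.
    """
    dG = np.asarray(free_energy_vec, float)
    if dG.size < 2:
        raise ValueError("need at least two states")
    finite = dG[np.isfinite(dG)]
    if finite.size and np.ptp(finite) < 1e-12:
        raise ValueError("degenerate free-energy landscape")
    source = int(np.argmax(dG))
    sink = int(np.argmin(dG))
    if (dG == dG[source]).sum() > 1 or (dG == dG[sink]).sum() > 1:
        logger.info("free-energy ties broken toward lowest state index")
    return source, sink
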