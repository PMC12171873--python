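"""Microstate Markov-state-model estimation and kinetic lumping.

Count matrices are accumulated per trajectory with a sliding window (no
counts across trajectory boundaries), transition matrices are estimated on
the largest strongly connected component, and macrostates are obtained by
a PCCA+-style simplex-vertex search on the leading right eigenvectors of
the reversible (symmetrised) transition matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph as csgraph

logger = logging.getLogger(__name__)

__all__ = [
    "TransitionProbabilityMatrix",
    "MacrostateModel",
    "count_matrix",
    "estimate_tpm",
    "stationary_distribution",
    "implied_timescales",
    "pcca_lump",
    "free_energy",
    "representative_frame",
    "KB_KCAL",
]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872


@dataclass
class TransitionProbabilityMatrix:
    """Row-stochastic matrix at a stated lag, restricted to the largest
    strongly connected set of the counts.

    ``active_set`` maps row/column indices back to the original state
    labels; ``connected`` is False when states had to be dropped.
    """

    matrix: np.ndarray
    lag: int
    counts: np.ndarray
    active_set: np.ndarray
    connected: bool

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


@dataclass
class MacrostateModel:
    n_macro: int
    memberships: np.ndarray  # micro x macro, rows sum to 1
    crisp_map: np.ndarray  # micro -> macro
    stationary: np.ndarray  # macro probabilities
    free_energy: np.ndarray  # kcal/mol, 0 at the most populated state
    macro_traj: list = field(default_factory=list)  # per-trajectory macro labels


def _as_traj_list(labels) -> list[np.ndarray]:
    if isinstance(labels, np.ndarray) and labels.ndim == 1:
        return [labels]
    return [np.asarray(t, dtype=int) for t in labels]


def count_matrix(labels, lag: int, n_states: int | None = None, mode: str = "sliding") -> np.ndarray:
    """Transition counts C[i, j] over (t, t+lag) pairs, per trajectory."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    trajs = _as_traj_list(labels)
    if n_states is None:
        n_states = int(max(t.max() for t in trajs if t.size)) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    any_pairs = False
    step = lag if mode == "strided" else 1
    for t in trajs:
        if t.size <= lag:
            continue
        any_pairs = True
        i = t[:-lag:step]
        j = t[lag::step]
        flat = np.bincount(i * n_states + j, minlength=n_states * n_states)
        counts += flat.reshape(n_states, n_states)
    if not any_pairs:
        raise ValueError(f"all trajectories are shorter than lag {lag}")
    return counts


def _largest_scc(counts: np.ndarray) -> np.ndarray:
    n, labels = csgraph.connected_components(counts > 0, directed=True, connection="strong")
    sizes = np.bincount(labels, weights=counts.sum(axis=1) + counts.sum(axis=0), minlength=n)
    # largest component by transition mass; ties by count of states
    best = np.argmax(sizes)
    return np.nonzero(labels == best)[0]


def estimate_tpm(counts: np.ndarray, lag: int = 1, mode: str = "rownorm") -> TransitionProbabilityMatrix:
    """Row-normalised or symmetrised (reversible) TPM on the largest
    strongly connected component of the count graph."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if mode not in ("rownorm", "symmetrized"):
        raise ValueError("mode must be 'rownorm' or 'symmetrized'")
    active = _largest_scc(counts)
    if active.size == 0:
        raise ValueError("empty connected component")
    sub = counts[np.ix_(active, active)].astype(float)
    if mode == "symmetrized":
        sub = 0.5 * (sub + sub.T)
    rows = sub.sum(axis=1, keepdims=True)
    if (rows == 0).any():
        raise ValueError("state with zero outgoing counts inside connected set")
    matrix = sub / rows
    return TransitionProbabilityMatrix(
        matrix=matrix,
        lag=lag,
        counts=counts[np.ix_(active, active)],
        active_set=active,
        connected=active.size == counts.shape[0],
    )


def _is_irreducible(matrix: np.ndarray) -> bool:
    n, _ = csgraph.connected_components(matrix > 0, directed=True, connection="strong")
    return n == 1


def stationary_distribution(tpm) -> np.ndarray:
    """Left Perron eigenvector, normalised to a probability vector."""
    matrix = tpm.matrix if isinstance(tpm, TransitionProbabilityMatrix) else np.asarray(tpm, float)
    if not _is_irreducible(matrix):
        raise ValueError("transition matrix is not irreducible")
    w, v = scipy.linalg.eig(matrix.T)
    k = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def implied_timescales(tpms: list, lags: list, frame_interval: float = 1.0, n_timescales: int = 1) -> np.ndarray:
    """Implied timescales t_i(tau) = -tau*dt / ln |lambda_i(T(tau))|.

    Rows follow ``lags``; columns are the slowest ``n_timescales`` processes.
    A lumped non-Markovian observation shows timescales that grow with lag.
    """
    out = np.full((len(lags), n_timescales), np.nan)
    for r, (tpm, lag) in enumerate(zip(tpms, lags)):
        matrix = tpm.matrix if isinstance(tpm, TransitionProbabilityMatrix) else np.asarray(tpm)
        w = np.sort(np.abs(np.linalg.eigvals(matrix)))[::-1]
        for c in range(min(n_timescales, len(w) - 1)):
            lam = w[c + 1]
            if 0 < lam < 1:
                out[r, c] = -lag * frame_interval / np.log(lam)
    return out


# ---------------------------------------------------------------------------
# PCCA+ lumping


def _stationary_for_lumping(matrix: np.ndarray) -> np.ndarray:
    # Power iteration from uniform: tolerant of (nearly) reducible input,
    # always returns a strictly positive weight vector for block systems.
    pi = np.full(matrix.shape[0], 1.0 / matrix.shape[0])
    for _ in range(2000):
        new = pi @ matrix
        if np.abs(new - pi).max() < 1e-14:
            pi = new
            break
        pi = new
    pi = np.clip(pi, 1e-300, None)
    return pi / pi.sum()


def _right_eigenvectors(matrix: np.ndarray, pi: np.ndarray, m: int) -> np.ndarray:
    d = np.sqrt(pi)
    sym = (matrix * d[:, None]) / d[None, :]
    sym = 0.5 * (sym + sym.T)
    w, phi = np.linalg.eigh(sym)
    order = np.argsort(w)[::-1]
    phi = phi[:, order[:m]]
    return phi / d[:, None]


def _simplex_vertices(X: np.ndarray) -> list[int]:
    # Deuflhard-Weber index search: pick the rows spanning the widest
    # simplex in eigenvector space.
    n, m = X.shape
    Y = X.copy()
    verts = [int(np.argmax((Y**2).sum(axis=1)))]
    Y = Y - Y[verts[0]]
    for _ in range(1, m):
        norms = np.linalg.norm(Y, axis=1)
        nxt = int(np.argmax(norms))
        verts.append(nxt)
        direction = Y[nxt] / (norms[nxt] if norms[nxt] > 0 else 1.0)
        Y = Y - np.outer(Y @ direction, direction)
    return verts


def pcca_lump(
    tpm,
    n_macro: int,
    labels=None,
) -> MacrostateModel:
    """PCCA+ kinetic lumping of a (reversible) microstate TPM.

    Memberships come from expressing each microstate's eigenvector row in
    the barycentric coordinates of the simplex spanned by the most extreme
    rows; the crisp assignment is the argmax membership.  When per-frame
    microstate ``labels`` are given, per-frame macrostate labels are
    attached (frames in dropped microstates get −1).
    """
    matrix = tpm.matrix if isinstance(tpm, TransitionProbabilityMatrix) else np.asarray(tpm, float)
    active = tpm.active_set if isinstance(tpm, TransitionProbabilityMatrix) else np.arange(matrix.shape[0])
    n_micro = matrix.shape[0]
    if n_macro > n_micro:
        raise ValueError("n_macro exceeds number of microstates")
    pi = _stationary_for_lumping(matrix)
    X = _right_eigenvectors(matrix, pi, n_macro)
    X[:, 0] = 1.0
    verts = _simplex_vertices(X)
    A = np.linalg.inv(X[verts])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    crisp = np.argmax(chi, axis=1)
    macro_pi = np.array([pi[crisp == k].sum() for k in range(n_macro)])
    macro_pi /= macro_pi.sum()
    dG = free_energy(macro_pi)
    model = MacrostateModel(
        n_macro=n_macro,
        memberships=chi,
        crisp_map=crisp,
        stationary=macro_pi,
        free_energy=dG,
    )
    if labels is not None:
        trajs = _as_traj_list(labels)
        size = max(int(active.max()), max(int(t.max()) for t in trajs)) + 1
        micro_to_macro = np.full(size, -1, dtype=int)
        micro_to_macro[active] = crisp
        model.macro_traj = [micro_to_macro[t] for t in trajs]
    return model


def free_energy(stationary: np.ndarray, temperature: float = 310.0) -> np.ndarray:
    """ΔG_i = −k_B·T·ln(π_i/π_max), kcal/mol; the most populated state is
    the zero of the scale (the 'lowest energy state')."""
    pi = np.asarray(stationary, dtype=float)
    pmax = pi.max()
    with np.errstate(divide="ignore"):
        dG = -KB_KCAL * temperature * np.log(pi / pmax)
    dG[pi == 0] = np.inf
    return dG


def representative_frame(projected: np.ndarray, labels: np.ndarray, target: int, center: np.ndarray | None = None) -> int:
    """Frame of the target state closest to the state centre.

    With no explicit centre the member centroid is used; ties break toward
    the lowest frame index (np.argmin convention).
    """
    projected = np.atleast_2d(np.asarray(projected, float))
    labels = np.asarray(labels)
    members = np.nonzero(labels == target)[0]
    if members.size == 0:
        raise ValueError(f"state {target} has no member frames")
    pts = projected[members]
    if center is None:
        center = pts.mean(axis=0)
    d = np.linalg.norm(pts - center, axis=1)
    return int(members[np.argmin(d)])
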