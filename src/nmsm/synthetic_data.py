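"""Synthetic inputs with analytic ground truth.

Two generators emulate the statistical structure the analysis pipeline
assumes, at toy scale and with exact oracles:

* a hidden Markov chain whose *lumped* observation is non-Markovian at
  short lag times (the property the IGME is designed to repair), with
  stationary distribution, macro MFPTs and slow timescales obtained by
  direct linear algebra on the hidden matrix;
* overdamped Langevin dynamics of a ligand in a 2-D branched exit channel
  (one binding basin, two or more exit branches), with per-trajectory
  branch labels as the oracle for pathway detection.

A third helper builds four-atom side-chain frames with prescribed chi1
angles, the oracle for the dihedral code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .msm_core import _is_irreducible
from .trajectory_io import Atom, FeatureDescriptor, FeatureTable, Trajectory

__all__ = [
    "HiddenChainSpec",
    "ChannelSpec",
    "GroundTruth",
    "gateway_chain_spec",
    "generate_hidden_chain",
    "exact_lumped_tpm_series",
    "two_branch_channel_spec",
    "generate_channel_egress",
    "egress_feature_tables",
    "egress_to_trajectory",
    "generate_rotamer_toy",
    "chain_to_rotamer_trajectory",
]


@dataclass
class GroundTruth:
    """Analytic reference quantities for a synthetic system."""

    stationary: np.ndarray | None = None  # macro probabilities
    mfpt_matrix: np.ndarray | None = None  # macro x macro, ns, 0 diagonal
    slow_timescales: np.ndarray | None = None  # ns, descending
    branch_labels: list = field(default_factory=list)  # per-trajectory exit branch or None


# ---------------------------------------------------------------------------
# hidden lumped chain


@dataclass
class HiddenChainSpec:
    n_hidden: int
    hidden_tpm: np.ndarray
    lump_map: np.ndarray  # hidden state -> macro label
    frame_interval: float = 0.1  # ns
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_tpm = np.asarray(self.hidden_tpm, dtype=float)
        self.lump_map = np.asarray(self.lump_map, dtype=int)
        T = self.hidden_tpm
        if T.shape != (self.n_hidden, self.n_hidden):
            raise ValueError("hidden_tpm shape does not match n_hidden")
        if np.abs(T.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("hidden_tpm rows must sum to 1 within 1e-12")
        if (T < 0).any():
            raise ValueError("hidden_tpm entries must be nonnegative")
        if self.lump_map.shape != (self.n_hidden,):
            raise ValueError("lump_map must assign every hidden state")
        if len(set(self.lump_map.tolist())) < 2:
            raise ValueError("lump_map must be surjective onto at least 2 macro labels")
        if not _is_irreducible(T):
            raise ValueError("hidden chain is reducible")

    @property
    def n_macro(self) -> int:
        return int(self.lump_map.max()) + 1


def gateway_chain_spec(frame_interval: float = 0.1, seed: int = 0) -> HiddenChainSpec:
    """Reference 4-state chain: two metastable pairs exchanging internally
    at 0.20/step, coupled only through their gateway states at 0.04/step.

    Because only one state of each pair can hop, the 2-macro lumped
    observation is genuinely non-Markovian: the lag-1 macro MSM
    underestimates the slow implied timescale by ~10%.
    """
    a, g = 0.20, 0.04
    T = np.array(
        [
            [1 - a - g, a, g, 0.0],
            [a, 1 - a, 0.0, 0.0],
            [g, 0.0, 1 - a - g, a],
            [0.0, 0.0, a, 1 - a],
        ]
    )
    return HiddenChainSpec(
        n_hidden=4,
        hidden_tpm=T,
        lump_map=np.array([0, 0, 1, 1]),
        frame_interval=frame_interval,
        seed=seed,
    )


def _hidden_stationary(T: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(T.T)
    pi = np.abs(np.real(v[:, np.argmin(np.abs(w - 1.0))]))
    return pi / pi.sum()


def _macro_mfpt(spec: HiddenChainSpec, pi: np.ndarray) -> np.ndarray:
    """Exact macro-to-macro MFPT (ns): absorbing macro-target set on the
    hidden chain, start weighted by the stationary distribution restricted
    to the source macro."""
    T = spec.hidden_tpm
    n_macro = spec.n_macro
    dt = spec.frame_interval
    hidden_mfpt_to = np.zeros((spec.n_hidden, n_macro))
    for b in range(n_macro):
        keep = np.nonzero(spec.lump_map != b)[0]
        sub = T[np.ix_(keep, keep)]
        m = np.linalg.solve(np.eye(len(keep)) - sub, dt * np.ones(len(keep)))
        hidden_mfpt_to[keep, b] = m
    out = np.zeros((n_macro, n_macro))
    for a in range(n_macro):
        members = np.nonzero(spec.lump_map == a)[0]
        w = pi[members] / pi[members].sum()
        for b in range(n_macro):
            if a != b:
                out[a, b] = w @ hidden_mfpt_to[members, b]
    return out


def _slow_timescales(spec: HiddenChainSpec) -> np.ndarray:
    lam = np.abs(np.linalg.eigvals(spec.hidden_tpm))
    lam = np.sort(lam)[::-1][1:]  # drop the Perron root
    with np.errstate(divide="ignore"):
        ts = np.where((lam > 0) & (lam < 1), -spec.frame_interval / np.log(lam), np.nan)
    return ts


def generate_hidden_chain(
    spec: HiddenChainSpec,
    n_traj: int,
    n_frames: int,
    return_hidden: bool = False,
):
    """Sample lumped (macro-label) trajectories from the hidden chain.

    Per-trajectory random streams derive from ``spec.seed`` by fixed
    offsets, so results are reproducible and individual trajectories can
    be regenerated independently.  Ground truth (macro stationary, exact
    macro MFPTs, hidden slow timescales) comes from direct linear solves
    on the hidden matrix.
    """
    if n_frames < 100:
        raise ValueError("n_frames must be >= 100")
    T = spec.hidden_tpm
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    pi = _hidden_stationary(T)
    cum_pi = np.cumsum(pi)
    cum_pi[-1] = 1.0
    macro_trajs = []
    hidden_trajs = []
    for k in range(n_traj):
        rng = np.random.default_rng(spec.seed + 1000 * k)
        u = rng.random(n_frames)
        states = np.empty(n_frames, dtype=np.int64)
        s = int(np.searchsorted(cum_pi, u[0]))
        states[0] = s
        for t in range(1, n_frames):
            s = int(np.searchsorted(cum[s], u[t]))
            states[t] = s
        hidden_trajs.append(states)
        macro_trajs.append(spec.lump_map[states])
    macro_pi = np.array([pi[spec.lump_map == m].sum() for m in range(spec.n_macro)])
    truth = GroundTruth(
        stationary=macro_pi,
        mfpt_matrix=_macro_mfpt(spec, pi),
        slow_timescales=_slow_timescales(spec),
    )
    if return_hidden:
        return macro_trajs, truth, hidden_trajs
    return macro_trajs, truth


# ---------------------------------------------------------------------------
# Langevin egress channel


@dataclass
class ChannelSpec:
    """2-D branched exit channel for overdamped Langevin dynamics.

    The potential (in units of kT) confines the particle harmonically to a
    'Y'-shaped skeleton of rays leaving the binding basin at the origin,
    tilts it gently downhill along each ray, and optionally adds a
    Gaussian barrier on individual branches.  Absorbing exits are the
    regions beyond ``absorb_radius``, disjoint from the basin.
    """

    branch_angles_deg: tuple = (45.0, 135.0)
    k_confine: float = 2.0  # kT / Å^2 transverse
    slope: float = 0.5  # kT / Å downhill along a branch
    barriers: tuple = (0.0, 0.0)  # kT, one per branch
    barrier_center: float = 8.0  # Å along the branch
    barrier_width: float = 2.0  # Å
    basin_radius: float = 2.0  # Å (descriptive; start point is the origin)
    absorb_radius: float = 25.0  # Å
    kT: float = 1.0
    diffusion: float = 1.0  # Å^2 / ns
    dt: float = 0.02  # ns
    record_stride: int = 50  # steps between recorded frames
    anchor_points: dict = field(default_factory=dict)  # label -> (x, y) Å
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.barriers) != len(self.branch_angles_deg):
            raise ValueError("one barrier height per branch required")
        params = [self.k_confine, self.slope, self.kT, self.diffusion, self.dt, *self.barriers]
        if not all(math.isfinite(p) for p in params):
            raise ValueError("non-finite channel parameters (forces would be non-finite)")
        if self.kT <= 0 or self.diffusion <= 0 or self.dt <= 0:
            raise ValueError("kT, diffusion and dt must be positive")
        if not self.anchor_points:
            self.anchor_points = self._default_anchors()
        if len(self.anchor_points) < 4:
            raise ValueError("at least 4 anchor points required")
        if self.absorb_radius <= self.basin_radius:
            raise ValueError("absorbing exits must be disjoint from the basin")

    def _default_anchors(self) -> dict:
        anchors = {"B1": (0.8, -0.8), "B2": (-0.8, -0.8)}
        for b, ang in enumerate(self.branch_angles_deg):
            u = (math.cos(math.radians(ang)), math.sin(math.radians(ang)))
            for j, s in enumerate((3.0, 6.0, 9.0)):
                anchors[f"BR{b}_{j}"] = (s * u[0], s * u[1])
        return anchors

    @property
    def branch_units(self) -> list:
        return [
            (math.cos(math.radians(a)), math.sin(math.radians(a)))
            for a in self.branch_angles_deg
        ]


def _force(spec: ChannelSpec, x: float, y: float) -> tuple:
    """-grad U at (x, y); the branch is the ray with the smallest
    transverse distance (radial confinement behind the basin)."""
    best = None
    for b, (ux, uy) in enumerate(spec.branch_units):
        s = x * ux + y * uy
        if s > 0.0:
            d2 = x * x + y * y - s * s
        else:
            s = 0.0
            d2 = x * x + y * y
        if best is None or d2 < best[0]:
            best = (d2, b, s, ux, uy)
    _, b, s, ux, uy = best
    if s > 0.0:
        fx = -spec.k_confine * (x - s * ux)
        fy = -spec.k_confine * (y - s * uy)
        fx += spec.slope * ux
        fy += spec.slope * uy
        h = spec.barriers[b]
        if h != 0.0:
            z = (s - spec.barrier_center) / spec.barrier_width
            g = h * math.exp(-0.5 * z * z) * z / spec.barrier_width
            fx += g * ux
            fy += g * uy
    else:
        fx = -spec.k_confine * x
        fy = -spec.k_confine * y
    return fx, fy


def generate_channel_egress(spec: ChannelSpec, n_traj: int, max_steps: int = 6000):
    """Simulate seeded Euler-Maruyama egress trajectories.

    Each trajectory starts in the basin (origin) and is recorded every
    ``record_stride`` steps until it crosses ``absorb_radius`` (the exit
    branch is the ray with the largest projection at absorption) or
    ``max_steps`` elapses (branch label ``None``).  Returns
    ``(list of (frames, 2) coordinate arrays, GroundTruth)``.
    """
    noise = math.sqrt(2.0 * spec.diffusion * spec.dt)
    mob = spec.diffusion * spec.dt / spec.kT
    trajs = []
    labels: list = []
    units = spec.branch_units
    for k in range(n_traj):
        rng = np.random.default_rng(spec.seed + 1000 * k)
        xi = rng.standard_normal((max_steps, 2))
        x = y = 0.0
        frames = [(0.0, 0.0)]
        label = None
        for step in range(1, max_steps + 1):
            fx, fy = _force(spec, x, y)
            if not (math.isfinite(fx) and math.isfinite(fy)):
                raise ValueError("non-finite force encountered; rejecting channel spec")
            x += mob * fx + noise * xi[step - 1, 0]
            y += mob * fy + noise * xi[step - 1, 1]
            if step % spec.record_stride == 0:
                frames.append((x, y))
            if x * x + y * y >= spec.absorb_radius**2:
                if step % spec.record_stride != 0:
                    frames.append((x, y))
                label = int(np.argmax([x * u[0] + y * u[1] for u in units]))
                break
        trajs.append(np.asarray(frames))
        labels.append(label)
    return trajs, GroundTruth(branch_labels=labels)


def two_branch_channel_spec(seed: int = 0, blocked_branch: int | None = None) -> ChannelSpec:
    """Mirror-symmetric two-branch channel (exits at 45° and 135°).

    With ``blocked_branch`` set, that branch carries a +10 kT Gaussian
    barrier so essentially all exits use the open branch.
    """
    barriers = [0.0, 0.0]
    if blocked_branch is not None:
        barriers[blocked_branch] = 10.0
    return ChannelSpec(barriers=tuple(barriers), seed=seed)


def egress_feature_tables(spec: ChannelSpec, trajs: list, cap: float = 12.0) -> list:
    """Capped ligand-anchor distances per trajectory, the input features of
    the pathway detector (one column per anchor pseudo-residue)."""
    labels = sorted(spec.anchor_points)
    anchors = np.asarray([spec.anchor_points[l] for l in labels])
    descs = [FeatureDescriptor("ligand_distance", l, "angstrom") for l in labels]
    tables = []
    for xy in trajs:
        d = np.linalg.norm(xy[:, None, :] - anchors[None, :, :], axis=2)
        tables.append(FeatureTable(np.minimum(d, cap), descs))
    return tables


def egress_to_trajectory(spec: ChannelSpec, xy: np.ndarray, frame_interval: float = 1.0) -> Trajectory:
    """Embed one 2-D egress path as a 3-D Trajectory: static CA anchor
    pseudo-residues (chain A) plus a moving single-atom ligand (chain L)."""
    labels = sorted(spec.anchor_points)
    atoms = [
        Atom(name="CA", res_name="ANC", res_id=i + 1, chain_id="A", element="C")
        for i in range(len(labels))
    ]
    atoms.append(Atom(name="C1", res_name="LIG", res_id=1, chain_id="L", element="C"))
    n_frames = xy.shape[0]
    coords = np.zeros((n_frames, len(atoms), 3))
    for i, l in enumerate(labels):
        coords[:, i, :2] = spec.anchor_points[l]
    coords[:, -1, :2] = xy
    return Trajectory(atoms, coords, frame_interval)


# ---------------------------------------------------------------------------
# chi1 rotamer toy


def _place_gamma(n: np.ndarray, ca: np.ndarray, cb: np.ndarray,
                 chi1_deg: float, bond: float = 1.52, angle_deg: float = 111.0) -> np.ndarray:
    """Place the gamma atom so that the N-CA-CB-G dihedral equals chi1."""
    bc = cb - ca
    bc = bc / np.linalg.norm(bc)
    ab = ca - n
    normal = np.cross(ab, bc)
    normal = normal / np.linalg.norm(normal)
    m = np.cross(normal, bc)
    theta = math.radians(180.0 - angle_deg)  # deviation from the CB->CA back-direction
    chi = math.radians(chi1_deg)
    d = bond * (
        math.cos(theta) * bc
        + math.sin(theta) * (math.cos(chi) * m - math.sin(chi) * normal)
    )
    return cb + d


def generate_rotamer_toy(chi1_targets, res_name: str = "LEU") -> Trajectory:
    """One four-atom side chain (N, CA, CB, CG); frame f realises
    ``chi1_targets[f]`` exactly (within 1e-6°)."""
    targets = list(chi1_targets)
    for t in targets:
        if not -180.0 < t <= 180.0:
            raise ValueError("chi1 targets must lie in (-180, 180]")
    n = np.array([-0.57, 1.35, 0.0])
    ca = np.array([0.0, 0.0, 0.0])
    cb = np.array([1.53, 0.0, 0.0])
    atoms = [
        Atom("N", res_name, 1, "A", "N"),
        Atom("CA", res_name, 1, "A", "C"),
        Atom("CB", res_name, 1, "A", "C"),
        Atom("CG", res_name, 1, "A", "C"),
    ]
    coords = np.empty((len(targets), 4, 3))
    for f, chi in enumerate(targets):
        coords[f, 0] = n
        coords[f, 1] = ca
        coords[f, 2] = cb
        coords[f, 3] = _place_gamma(n, ca, cb, chi)
    return Trajectory(atoms, coords, frame_interval=0.1)


def chain_to_rotamer_trajectory(
    hidden_states: np.ndarray,
    state_chi1: np.ndarray,
    noise_deg: float = 8.0,
    seed: int = 0,
    frame_interval: float = 0.1,
) -> Trajectory:
    """Embed a hidden-state sequence as side-chain geometry.

    ``state_chi1[s]`` gives the mean chi1 (degrees) of each of several
    residues in hidden state ``s``; frames get wrapped Gaussian angle
    noise.  This turns a discrete-chain fixture into a geometric
    trajectory that exercises the full featurize → tICA → clustering leg.
    """
    hidden_states = np.asarray(hidden_states, int)
    state_chi1 = np.atleast_2d(np.asarray(state_chi1, float))
    n_res = state_chi1.shape[1]
    rng = np.random.default_rng(seed)
    n = np.array([-0.57, 1.35, 0.0])
    ca = np.array([0.0, 0.0, 0.0])
    cb = np.array([1.53, 0.0, 0.0])
    atoms = []
    for r in range(n_res):
        offset = np.array([10.0 * r, 0.0, 0.0])
        for name, el in (("N", "N"), ("CA", "C"), ("CB", "C"), ("CG", "C")):
            atoms.append(Atom(name, "LEU", r + 1, "A", el))
    coords = np.empty((hidden_states.size, 4 * n_res, 3))
    for r in range(n_res):
        offset = np.array([10.0 * r, 0.0, 0.0])
        angles = state_chi1[hidden_states, r] + noise_deg * rng.standard_normal(hidden_states.size)
        angles = (angles + 180.0) % 360.0 - 180.0
        angles[angles == -180.0] = 180.0
        base = 4 * r
        coords[:, base + 0] = n + offset
        coords[:, base + 1] = ca + offset
        coords[:, base + 2] = cb + offset
        for f, chi in enumerate(angles):
            coords[f, base + 3] = _place_gamma(n, ca, cb, float(chi)) + offset
    return Trajectory(atoms, coords, frame_interval)


def exact_lumped_tpm_series(spec: HiddenChainSpec, max_lag: int) -> np.ndarray:
    """Population-level macro TPM series: the exact lumped observation of
    the hidden chain at lags 1..max_lag (stationary-weighted within each
    macro label).  This is what an infinitely long trajectory would give,
    useful for separating estimator bias from sampling noise."""
    T = spec.hidden_tpm
    pi = _hidden_stationary(T)
    n_macro = spec.n_macro
    members = [np.nonzero(spec.lump_map == m)[0] for m in range(n_macro)]
    weights = [pi[idx] / pi[idx].sum() for idx in members]
    out = np.empty((max_lag, n_macro, n_macro))
    power = np.eye(spec.n_hidden)
    for lag in range(1, max_lag + 1):
        power = power @ T
        for a in range(n_macro):
            for b in range(n_macro):
                out[lag - 1, a, b] = weights[a] @ power[np.ix_(members[a], members[b])].sum(axis=1)
    return out
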