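"""Pipeline orchestration: the state-model leg and the pathway leg.

Both legs run from a single YAML config with a mandatory seed.  Lags are
given in ns and converted to whole frames via the frame interval; a lag
that is not a whole number of frames is rejected at validation.  Every
written artifact carries a provenance header (config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import dimred_cluster, featurize, igme, msm_core, som_pathways, trajectory_io

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "load_config", "run_state_model", "run_pathway_detection"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input digest."""

    def __init__(self, stage: str, digest: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed (input digest {digest}): {cause}")
        self.stage = stage
        self.digest = digest
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int
    frame_interval: float = 0.1  # ns
    topology: str | None = None
    frames: str | None = None
    feature_files: list = field(default_factory=list)  # precomputed FeatureTable TSVs
    label_files: list = field(default_factory=list)  # precomputed macro/micro label TSVs
    chi1_residues: list = field(default_factory=list)
    helix_pairs: list = field(default_factory=list)  # [[span_a, span_b], ...]
    ligand: str | None = None
    pathway_residues: list = field(default_factory=list)
    sasa_selections: dict = field(default_factory=dict)  # e.g. extracellular/intracellular sets
    tica_lag: float = 1.0  # ns
    tica_components: int = 3
    n_microstates: int = 100
    msm_lag: float = 0.5  # ns
    n_macro: int = 2
    igme_max_lag: float | None = None  # ns; default from data length
    igme_tau_k_grid: list = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8, 1.0])
    igme_L_grid: list = field(default_factory=lambda: [2.0, 4.0, 6.0, 8.0, 10.0])
    ck_lags: list = field(default_factory=lambda: [1.0, 2.0, 5.0])
    som_grid: tuple = (10, 10)
    som_cycles: int = 5000
    distance_cap: float = 12.0
    som_k_range: list = field(default_factory=lambda: [2, 8])
    temperature: float = 310.0

    def lag_frames(self, lag_ns: float, name: str) -> int:
        frames = lag_ns / self.frame_interval
        if abs(frames - round(frames)) > 1e-9:
            raise ValueError(
                f"{name} = {lag_ns} ns is not a whole number of frames at "
                f"{self.frame_interval} ns/frame"
            )
        if round(frames) < 1:
            raise ValueError(f"{name} must be at least one frame")
        return int(round(frames))

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.lag_frames(self.tica_lag, "tica_lag")
        self.lag_frames(self.msm_lag, "msm_lag")
        for v in [*self.igme_tau_k_grid, *self.igme_L_grid, *self.ck_lags]:
            self.lag_frames(v, "igme/ck lag") if v > 0 else None

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("seed is mandatory")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _provenance(cfg: PipelineConfig) -> dict:
    return {"config_sha256": cfg.digest(), "seed": cfg.seed}


def _stage(name: str, cfg: PipelineConfig):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(name, cfg.digest(), exc) from exc
            logger.info("stage %s: done in %.2fs", name, time.time() - self.t0)
            return False

    return _Ctx()


def _load_inputs(cfg: PipelineConfig):
    traj = None
    features = None
    labels = None
    if cfg.label_files:
        labels = [
            np.loadtxt(p, dtype=int, ndmin=1, comments="#") for p in cfg.label_files
        ]
    elif cfg.feature_files:
        features = [trajectory_io.read_feature_table(p) for p in cfg.feature_files]
    elif cfg.topology:
        traj = trajectory_io.read_trajectory(cfg.topology, cfg.frames, cfg.frame_interval)
    else:
        raise ValueError("config must provide label_files, feature_files or a topology")
    return traj, features, labels


def run_state_model(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """tICA → k-means → microstate MSM → PCCA+ → IGME → CK/MFPT/TPT.

    Inputs may enter at three points: raw trajectory (featurised here),
    precomputed feature tables, or precomputed state-label series (the
    discretisation stages are then skipped).  Returns the artifact dict
    and writes TSV/PDB artifacts with provenance headers.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = _provenance(cfg)
    artifacts: dict = {}

    with _stage("load", cfg):
        traj, features, labels = _load_inputs(cfg)

    if labels is None:
        if features is None:
            with _stage("featurize", cfg):
                tables = []
                if cfg.chi1_residues:
                    tables.append(featurize.compute_chi1(traj, cfg.chi1_residues))
                for span_a, span_b in cfg.helix_pairs:
                    tables.append(featurize.compute_helix_distance(traj, span_a, span_b))
                if not tables:
                    raise ValueError("no features configured")
                table = tables[0]
                for t in tables[1:]:
                    table = table.hstack(t)
                features = [table]
                trajectory_io.write_feature_table(table, out_dir / "features.tsv", meta)
        with _stage("tica", cfg):
            encoded = [dimred_cluster.encode_circular(f) for f in features]
            lag = cfg.lag_frames(cfg.tica_lag, "tica_lag")
            tica = dimred_cluster.fit_tica(encoded, lag, cfg.tica_components)
            projected = [tica.transform(f) for f in encoded]
            artifacts["tica"] = tica
        with _stage("kmeans", cfg):
            micro = dimred_cluster.fit_kmeans(projected, cfg.n_microstates, cfg.seed)
            artifacts["microstates"] = micro
        with _stage("micro_msm", cfg):
            msm_lag = cfg.lag_frames(cfg.msm_lag, "msm_lag")
            counts = msm_core.count_matrix(micro.labels, msm_lag)
            tpm = msm_core.estimate_tpm(counts, lag=msm_lag, mode="symmetrized")
            artifacts["micro_tpm"] = tpm
            trajectory_io.write_matrix(
                tpm.matrix, out_dir / "micro_tpm.tsv", {**meta, "lag_frames": msm_lag}
            )
        with _stage("pcca", cfg):
            macro = msm_core.pcca_lump(tpm, cfg.n_macro, labels=micro.labels)
            artifacts["macrostates"] = macro
            macro_labels = macro.macro_traj
            trajectory_io.write_matrix(
                macro.memberships, out_dir / "pcca_memberships.tsv", meta
            )
    else:
        with _stage("labels", cfg):
            macro_labels = labels
            n_macro = int(max(l.max() for l in labels)) + 1
            counts = msm_core.count_matrix(labels, 1)
            tpm = msm_core.estimate_tpm(counts, lag=1)
            stationary = msm_core.stationary_distribution(tpm)
            macro = msm_core.MacrostateModel(
                n_macro=n_macro,
                memberships=np.eye(n_macro),
                crisp_map=np.arange(n_macro),
                stationary=stationary,
                free_energy=msm_core.free_energy(stationary, cfg.temperature),
                macro_traj=labels,
            )
            artifacts["macrostates"] = macro

    with _stage("igme", cfg):
        n_macro_states = int(max(l.max() for l in macro_labels)) + 1
        shortest = min(l.size for l in macro_labels)
        max_lag_ns = cfg.igme_max_lag
        if max_lag_ns is None:
            max_lag = min(shortest // 5, 200)
        else:
            max_lag = cfg.lag_frames(max_lag_ns, "igme_max_lag")
        series = igme.tpm_series(macro_labels, n_macro_states, max_lag)
        tau_grid = [cfg.lag_frames(v, "tau_k") if v > 0 else 0 for v in cfg.igme_tau_k_grid]
        L_grid = [cfg.lag_frames(v, "L") for v in cfg.igme_L_grid]
        model, scan_table = igme.scan_igme(
            series, tau_grid, L_grid, lag_unit=cfg.frame_interval
        )
        artifacts["igme"] = model
        artifacts["igme_scan"] = scan_table
        scan_table.to_csv(out_dir / "igme_scan.tsv", sep="\t", index=False)
        trajectory_io.write_matrix(
            model.T_hat,
            out_dir / "igme_that.tsv",
            {**meta, "tau_k": model.tau_k, "L": model.L, "rmse": model.rmse},
        )

    with _stage("ck", cfg):
        ck_lags = [cfg.lag_frames(v, "ck_lag") for v in cfg.ck_lags]
        report = igme.ck_test(model, macro_labels, ck_lags, seed=cfg.seed)
        artifacts["ck"] = report

    with _stage("kinetics", cfg):
        mfpt_matrix = igme.mfpt(model)
        artifacts["mfpt"] = mfpt_matrix
        trajectory_io.write_matrix(mfpt_matrix, out_dir / "mfpt_ns.tsv", meta)
        stationary = msm_core.stationary_distribution(model.T_hat)
        dG = msm_core.free_energy(stationary, cfg.temperature)
        artifacts["free_energy"] = dG
        try:
            source, sink = igme.select_endpoints(dG)
            flux = igme.tpt_flux(model.T_hat, stationary, source, sink)
            artifacts["flux"] = flux
            edges = [
                (i, j, flux.netflux[i, j])
                for i in range(len(dG))
                for j in range(len(dG))
                if flux.netflux[i, j] > 0
            ]
            with open(out_dir / "netflux_edges.tsv", "w") as fh:
                for k, v in meta.items():
                    fh.write(f"# {k}={v}\n")
                fh.write("from\tto\tnetflux\n")
                for i, j, w in edges:
                    fh.write(f"{i}\t{j}\t{w:.8g}\n")
        except ValueError as err:
            logger.warning("TPT skipped: %s", err)

    if traj is not None and "microstates" in artifacts:
        with _stage("representatives", cfg):
            flat_proj = np.vstack(projected)
            flat_macro = np.concatenate(macro_labels)
            reps = []
            for state in range(macro.n_macro):
                if (flat_macro == state).any():
                    reps.append(
                        msm_core.representative_frame(flat_proj, flat_macro, state)
                    )
            trajectory_io.write_representatives(traj, reps, out_dir, prefix="state")
            artifacts["representative_frames"] = reps

    return artifacts


def run_pathway_detection(cfg: PipelineConfig, out_dir: str | Path, feature_tables=None) -> dict:
    """Capped ligand distances → SOM → silhouette clustering → transition
    network → endpoint identification → pathway extraction → heatmap."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = _provenance(cfg)
    artifacts: dict = {}

    if feature_tables is None:
        with _stage("load", cfg):
            traj, features, _ = _load_inputs(cfg)
        if features is not None:
            feature_tables = features
        else:
            with _stage("ligand_distances", cfg):
                if not cfg.ligand:
                    raise ValueError("ligand selection required for pathway detection")
                if traj.n_frames < 2:
                    raise ValueError("insufficient frames for pathway detection")
                table = featurize.compute_ligand_distances(
                    traj, cfg.ligand, cfg.pathway_residues, cap=cfg.distance_cap
                )
                feature_tables = [table]
    for t in feature_tables:
        if t.n_frames < 2:
            raise ValueError("insufficient frames for pathway detection")

    with _stage("som", cfg):
        som = som_pathways.train_som(
            feature_tables, grid=tuple(cfg.som_grid), cycles=cfg.som_cycles, seed=cfg.seed
        )
        artifacts["som"] = som
        trajectory_io.write_matrix(som.codebook, out_dir / "som_codebook.tsv", meta)
        with open(out_dir / "som_bmu.tsv", "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            for ti, seq in enumerate(som.bmu):
                fh.write("\t".join([str(ti)] + [str(int(b)) for b in seq]) + "\n")

    with _stage("cluster_neurons", cfg):
        lo, hi = cfg.som_k_range
        clustering = som_pathways.cluster_neurons(som, range(int(lo), int(hi) + 1))
        artifacts["clustering"] = clustering

    with _stage("network", cfg):
        network = som_pathways.build_transition_network(som)
        artifacts["network"] = network

    with _stage("heatmap", cfg):
        heatmap = som_pathways.cluster_heatmap(feature_tables, som, clustering)
        artifacts["heatmap"] = heatmap
        heatmap.to_csv(out_dir / "cluster_heatmap.tsv", sep="\t")

    with _stage("pathways", cfg):
        bound, unbound = som_pathways.identify_endpoints(clustering, heatmap, network)
        artifacts["endpoints"] = (bound, unbound)
        paths = som_pathways.extract_pathways(network, clustering, som, bound, unbound)
        artifacts["pathways"] = paths
        with open(out_dir / "pathways.tsv", "w") as fh:
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            fh.write("rank\tclusters\tbottleneck\tsupport\n")
            for r, p in enumerate(paths):
                fh.write(f"{r}\t{'-'.join(map(str, p.clusters))}\t{p.bottleneck}\t{p.support}\n")

    return artifacts
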