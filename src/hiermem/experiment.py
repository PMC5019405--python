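"""Experiment orchestration: one config file -> a reproducible report bundle.

``run_experiment`` wires the modules into the standard protocol — generate
patterns, train, then any selection of recall evaluation, bifurcation sweep,
similarity/cluster sweep, spontaneous-transition statistics and Lyapunov
estimation — writing every artifact plus a manifest (parameters, derived
seeds, file hashes) into one output directory.  All randomness derives from
a single master seed, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .chaos import largest_lyapunov
from .clustering import count_clusters, similarity_matrix, target_similarity_matrix
from .dynamics import SimulationConfig, random_initial_state, simulate
from .learning import LearningConfig, evaluate_recall, train
from .overlap import bifurcation_sweep
from .patterns import PatternSpec, generate_pattern_set
from .transitions import category_bias, detect_approaches, transition_stats

__all__ = ["ExperimentConfig", "run_experiment"]

log = logging.getLogger("hiermem")

_ALL_STAGES = ("recall", "bifurcation", "clusters", "transitions", "lyapunov")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one end-to-end experiment."""

    out_dir: str = "experiment_out"
    master_seed: int = 0
    pattern: PatternSpec = field(default_factory=PatternSpec)
    learning: LearningConfig = field(default_factory=LearningConfig)
    stages: tuple[str, ...] = _ALL_STAGES
    # analysis settings
    recall_gamma: float = 16.0
    transient: float = 100.0
    window: float = 400.0
    recall_threshold: float = 0.9
    cluster_gammas: tuple[float, ...] = (4.0, 6.0, 16.0)
    cluster_threshold: float = 0.3
    bifurcation_mu: int = 6
    bifurcation_gammas: tuple[float, ...] = tuple(np.arange(0.0, 16.5, 0.5))
    spontaneous_duration: float = 10000.0
    approach_threshold: float = 0.5
    lyapunov_gamma: float = 0.0
    lyapunov_duration: float = 5000.0
    lyapunov_transient: float = 500.0

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "pattern" in d:
            d["pattern"] = PatternSpec(**d["pattern"])
        if "learning" in d:
            d["learning"] = LearningConfig(**d["learning"])
        for key in ("stages", "cluster_gammas", "bifurcation_gammas"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["cluster_gammas"] = list(map(float, self.cluster_gammas))
        d["bifurcation_gammas"] = list(map(float, self.bifurcation_gammas))
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.master_seed).spawn(8)
    seed_of = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("pattern", "train", "recall", "bifurcation", "clusters",
             "transitions", "lyapunov", "spare"),
            seeds,
        )
    }
    manifest: dict = {
        "config": cfg.to_dict(),
        "seeds": seed_of,
        "stages": {},
        "files": {},
    }

    def _stage(name):
        t0 = time.perf_counter()
        log.info("stage %s: start", name)
        return t0

    def _done(name, t0, **info):
        dt = time.perf_counter() - t0
        log.info("stage %s: done in %.1fs", name, dt)
        manifest["stages"][name] = {"seconds": round(dt, 2), **info}

    t0 = _stage("patterns")
    ps = generate_pattern_set(
        dataclasses.replace(cfg.pattern, seed=seed_of["pattern"])
    )
    hio.save_pattern_set(ps, out / "patterns.h5")
    _done("patterns", t0, n_assoc=ps.n_assoc)

    t0 = _stage("train")
    tn = train(ps, dataclasses.replace(cfg.learning, seed=seed_of["train"]))
    hio.save_network(tn, out / "network.h5")
    _done("train", t0, final_error=float(tn.history[-ps.n_assoc:].mean()))

    if "recall" in cfg.stages:
        t0 = _stage("recall")
        rep = evaluate_recall(
            tn, ps, cfg.recall_gamma, cfg.transient, cfg.window,
            cfg.recall_threshold, seed=seed_of["recall"],
        )
        hio.recall_to_csv(rep, out / "recall.csv")
        _done("recall", t0, success_fraction=rep.success_fraction)

    if "bifurcation" in cfg.stages:
        t0 = _stage("bifurcation")
        diag = bifurcation_sweep(
            tn, ps, cfg.bifurcation_mu, np.asarray(cfg.bifurcation_gammas),
            transient=cfg.transient, seed=seed_of["bifurcation"],
        )
        hio.bifurcation_to_csv(diag, out / "bifurcation.csv")
        _done("bifurcation", t0)

    if "clusters" in cfg.stages:
        t0 = _stage("clusters")
        counts = {}
        hio.similarity_to_csv(
            target_similarity_matrix(ps), out / "similarity_targets.csv"
        )
        for g in cfg.cluster_gammas:
            sm = similarity_matrix(
                tn, ps, g, cfg.transient, cfg.window, seed=seed_of["clusters"]
            )
            tree = count_clusters(sm, cfg.cluster_threshold)
            tag = f"{g:g}"
            hio.similarity_to_csv(sm, out / f"similarity_gamma{tag}.csv")
            hio.linkage_to_csv(tree, out / f"linkage_gamma{tag}.csv")
            counts[tag] = tree.n_clusters
        (out / "clusters.json").write_text(json.dumps(counts, indent=2))
        _done("clusters", t0, n_clusters=counts)

    if "transitions" in cfg.stages:
        t0 = _stage("transitions")
        x0 = random_initial_state(ps.spec.n, seed_of["transitions"])
        traj = simulate(
            tn.network, None, 0.0, x0,
            SimulationConfig(duration=cfg.spontaneous_duration,
                             dt=cfg.learning.dt, transient=0.0),
        )
        seq = detect_approaches(traj, ps.targets, cfg.approach_threshold)
        stats = transition_stats(seq, ps.n_assoc, ps.spec.m)
        bias = category_bias(stats)
        tdir = out / "transitions"
        tdir.mkdir(exist_ok=True)
        hio.sequence_to_csv(seq, tdir / "approaches.csv")
        hio.matrix_to_csv(stats.P, tdir / "P.csv")
        hio.matrix_to_csv(stats.T, tdir / "T.csv")
        hio.matrix_to_csv(stats.P_cat, tdir / "P_cat.csv", index_name="category")
        hio.matrix_to_csv(stats.T_cat, tdir / "T_cat.csv", index_name="category")
        (tdir / "category_bias.json").write_text(
            json.dumps(dataclasses.asdict(bias), indent=2)
        )
        _done("transitions", t0, n_visits=len(seq),
              within_p=bias.within_p, cross_p=bias.cross_p)

    if "lyapunov" in cfg.stages:
        t0 = _stage("lyapunov")
        res = largest_lyapunov(
            tn.network, None, cfg.lyapunov_gamma,
            duration=cfg.lyapunov_duration, transient=cfg.lyapunov_transient,
            dt=cfg.learning.dt, seed=seed_of["lyapunov"],
        )
        (out / "lyapunov.json").write_text(json.dumps(
            {"lambda": res.lam, "sd": res.sd, "gamma": res.gamma,
             "duration": res.duration, "transient": res.transient}, indent=2))
        _done("lyapunov", t0, **{"lambda": res.lam})

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
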