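"""Persistence of pattern sets, networks and trajectories (HDF5 + CSV).

Containers are schema-versioned HDF5 files; integer pattern matrices and the
synaptic matrix round-trip bit-exactly.  Matrices and time series also export
to tidy CSV for plotting elsewhere.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import Network, Trajectory
from .learning import LearningConfig, TrainedNetwork
from .overlap import BifurcationDiagram, OverlapProfile
from .patterns import PatternSet, PatternSpec
from .transitions import ApproachSequence, TransitionStats

__all__ = [
    "SchemaError",
    "save_pattern_set",
    "load_pattern_set",
    "save_network",
    "load_network",
    "save_trajectory",
    "load_trajectory",
    "patterns_to_csv",
    "profile_to_csv",
    "recall_to_csv",
    "similarity_to_csv",
    "linkage_to_csv",
    "bifurcation_to_csv",
    "sequence_to_csv",
    "matrix_to_csv",
]

SCHEMA_VERSION = 1
_FORMAT = "hiermem"


class SchemaError(IOError):
    """Unrecognised, corrupt or incompatible container file."""


def _stamp(f: h5py.File, kind: str) -> None:
    f.attrs["format"] = _FORMAT
    f.attrs["schema_version"] = SCHEMA_VERSION
    f.attrs["kind"] = kind


def _check(f: h5py.File, kind: str, path) -> None:
    if f.attrs.get("format") != _FORMAT or f.attrs.get("kind") != kind:
        raise SchemaError(f"{path} is not a {_FORMAT} {kind} file")
    if f.attrs.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema version {f.attrs.get('schema_version')} "
            f"!= supported {SCHEMA_VERSION}"
        )


def _require(f, name: str, path):
    if name not in f:
        raise SchemaError(f"{path}: missing dataset '{name}'")
    return f[name][()]


def _require_attr(f, name: str, path):
    if name not in f.attrs:
        raise SchemaError(f"{path}: missing attribute '{name}'")
    return f.attrs[name]


# ---------------------------------------------------------------- PatternSet

def save_pattern_set(ps: PatternSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, "pattern_set")
        f.create_dataset("inputs", data=ps.inputs, dtype="i1")
        f.create_dataset("targets", data=ps.targets, dtype="i1")
        f.create_dataset("typical_inputs", data=ps.typical_inputs, dtype="i1")
        f.create_dataset("typical_targets", data=ps.typical_targets, dtype="i1")
        f.attrs["spec"] = json.dumps(dataclasses.asdict(ps.spec))


def load_pattern_set(path: str | Path) -> PatternSet:
    with h5py.File(path, "r") as f:
        _check(f, "pattern_set", path)
        spec = PatternSpec(**json.loads(_require_attr(f, "spec", path)))
        return PatternSet(
            inputs=_require(f, "inputs", path),
            targets=_require(f, "targets", path),
            typical_inputs=_require(f, "typical_inputs", path),
            typical_targets=_require(f, "typical_targets", path),
            spec=spec,
        )


# ------------------------------------------------------------------ Network

def save_network(net: Network | TrainedNetwork, path: str | Path) -> None:
    """Save a Network or a TrainedNetwork (with provenance and history)."""
    tn = net if isinstance(net, TrainedNetwork) else None
    network = tn.network if tn is not None else net
    with h5py.File(path, "w") as f:
        _stamp(f, "network")
        f.create_dataset("J", data=network.J)
        f.attrs["beta"] = network.beta
        if tn is not None:
            f.attrs["pattern_spec"] = json.dumps(dataclasses.asdict(tn.pattern_spec))
            f.attrs["learning_config"] = json.dumps(dataclasses.asdict(tn.config))
            if tn.history is not None:
                f.create_dataset("history", data=tn.history)
            if tn.presented is not None:
                f.create_dataset("presented", data=tn.presented)


def load_network(path: str | Path) -> Network | TrainedNetwork:
    """Load a network; returns a TrainedNetwork when provenance is present."""
    with h5py.File(path, "r") as f:
        _check(f, "network", path)
        net = Network(J=_require(f, "J", path), beta=float(_require_attr(f, "beta", path)))
        if "learning_config" not in f.attrs:
            return net
        return TrainedNetwork(
            network=net,
            pattern_spec=PatternSpec(**json.loads(f.attrs["pattern_spec"])),
            config=LearningConfig(**json.loads(f.attrs["learning_config"])),
            history=f["history"][()] if "history" in f else None,
            presented=f["presented"][()] if "presented" in f else None,
        )


# --------------------------------------------------------------- Trajectory

def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        _stamp(f, "trajectory")
        f.create_dataset("times", data=traj.times, chunks=True)
        f.create_dataset("states", data=traj.states, chunks=True)
        f.attrs["gamma"] = traj.gamma
        f.attrs["mu"] = -1 if traj.mu is None else int(traj.mu)
        f.attrs["dt"] = traj.dt
        f.attrs["record_stride"] = traj.record_stride


def load_trajectory(path: str | Path) -> Trajectory:
    with h5py.File(path, "r") as f:
        _check(f, "trajectory", path)
        mu = int(_require_attr(f, "mu", path))
        return Trajectory(
            times=_require(f, "times", path),
            states=_require(f, "states", path),
            gamma=float(_require_attr(f, "gamma", path)),
            mu=None if mu < 0 else mu,
            dt=float(_require_attr(f, "dt", path)),
            record_stride=float(_require_attr(f, "record_stride", path)),
        )


# -------------------------------------------------------------- CSV exports

def patterns_to_csv(ps: PatternSet, path: str | Path) -> None:
    """One row per pattern: role, mu, category, then the N elements."""
    rows = []
    for role, arr in (("input", ps.inputs), ("target", ps.targets)):
        for mu in range(ps.n_assoc):
            rows.append([role, mu, mu // ps.spec.m, *arr[mu]])
    cols = ["role", "mu", "category", *[f"x{i}" for i in range(ps.spec.n)]]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def profile_to_csv(profile: OverlapProfile, path: str | Path) -> None:
    pd.DataFrame(
        {"mu": profile.mu_index, "mean": profile.mean, "sd": profile.sd}
    ).to_csv(path, index=False)


def recall_to_csv(report, path: str | Path) -> None:
    pd.DataFrame(
        {
            "mu": np.arange(len(report.overlaps)),
            "mean_overlap": report.overlaps,
            "success": report.overlaps > report.threshold,
        }
    ).to_csv(path, index=False)


def matrix_to_csv(mat: np.ndarray, path: str | Path, index_name: str = "mu") -> None:
    """Square matrix with integer row/column headers; NaN cells left empty."""
    df = pd.DataFrame(mat)
    df.index.name = index_name
    df.to_csv(path)


def similarity_to_csv(sim, path: str | Path) -> None:
    matrix_to_csv(sim.S, path)


def linkage_to_csv(tree, path: str | Path) -> None:
    pd.DataFrame(
        tree.linkage, columns=["child_a", "child_b", "distance", "size"]
    ).to_csv(path, index=False)


def bifurcation_to_csv(diag: BifurcationDiagram, path: str | Path) -> None:
    """Tidy rows (gamma, mu, sample_time, overlap)."""
    n_samp = diag.samples.shape[1]
    sample_t = diag.transient + diag.sample_interval * np.arange(1, n_samp + 1)
    pd.DataFrame(
        {
            "gamma": np.repeat(diag.gammas, n_samp),
            "mu": diag.mu,
            "sample_time": np.tile(sample_t, len(diag.gammas)),
            "overlap": diag.samples.ravel(),
        }
    ).to_csv(path, index=False)


def sequence_to_csv(seq: ApproachSequence, path: str | Path) -> None:
    pd.DataFrame({"t": seq.times, "target": seq.targets}).to_csv(path, index=False)
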