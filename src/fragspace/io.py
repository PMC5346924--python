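"""Readers and writers for profiles, histograms, weights, reference sets.

TSV is the canonical format; positions are written 1-based. bedGraph export
uses 0-based half-open intervals with a caller-supplied sequence name.
Every stochastic run directory carries a JSON manifest sufficient to re-run
the command bit-identically.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd
import yaml

from .estimator import ECDF, ReferenceSet
from .model import CoverageKind, PatternSpaceModel, Profile, WeightMode
from .simulator import SimulatedLibrary, SimulationConfig

__all__ = [
    "write_profile",
    "read_profile",
    "write_profile_bedgraph",
    "write_distribution",
    "write_weights",
    "read_weights",
    "write_library",
    "write_reference_set",
    "read_reference_set",
    "load_model_config",
    "write_manifest",
]

_FLOAT_FMT = "%.17g"


def write_profile(profile: Profile, path: str | os.PathLike) -> None:
    """TSV with header, 1-based ``position`` and ``value`` columns."""
    values = profile.as_float()
    with open(path, "w") as fh:
        fh.write(f"# kind={CoverageKind(profile.kind).value}"
                 f"\tnormalized={profile.normalized}\n")
        fh.write("position\tvalue\n")
        for pos, value in enumerate(values, start=1):
            fh.write(f"{pos}\t{_FLOAT_FMT % value}\n")


def read_profile(path: str | os.PathLike, model: PatternSpaceModel,
                 kind: CoverageKind | None = None) -> Profile:
    normalized = False
    read_kind = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            fields = dict(item.split("=", 1) for item in first[1:].split())
            read_kind = fields.get("kind")
            normalized = fields.get("normalized") == "True"
    table = pd.read_csv(path, sep="\t", comment="#")
    values = table["value"].to_numpy(dtype=float)
    kind = CoverageKind(kind or read_kind or CoverageKind.START_POINT)
    return Profile(values, kind, model, normalized=normalized)


def write_profile_bedgraph(profile: Profile, path: str | os.PathLike,
                           name: str = "synthetic_transcript") -> None:
    """bedGraph: 0-based half-open intervals on a synthetic sequence name."""
    values = profile.as_float()
    with open(path, "w") as fh:
        for pos, value in enumerate(values):
            fh.write(f"{name}\t{pos}\t{pos + 1}\t{_FLOAT_FMT % value}\n")


def write_distribution(dist, path: str | os.PathLike) -> None:
    """TSV (length, value, interpolated_flag) for an empirical distribution."""
    with open(path, "w") as fh:
        fh.write("length\tvalue\tinterpolated\n")
        for length, freq, flag in zip(dist.lengths, dist.frequencies, dist.interpolated):
            fh.write(f"{length}\t{_FLOAT_FMT % freq}\t{int(flag)}\n")


def write_weights(weights: dict[int, float], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("length\tweight\n")
        for length in sorted(weights):
            fh.write(f"{length}\t{_FLOAT_FMT % weights[length]}\n")


def read_weights(path: str | os.PathLike) -> dict[int, float]:
    table = pd.read_csv(path, sep="\t")
    return {int(l): float(w) for l, w in zip(table["length"], table["weight"])}


def write_library(library: SimulatedLibrary, path: str | os.PathLike) -> None:
    """TSV (start 1-based, length, multiplicity, stage)."""
    with open(path, "w") as fh:
        fh.write("start\tlength\tmultiplicity\tstage\n")
        for start, length, mult in zip(library.starts, library.lengths,
                                       library.multiplicities):
            fh.write(f"{start + 1}\t{length}\t{mult}\t{library.stage}\n")


# -- reference sets ---------------------------------------------------------

def _config_to_dict(config: SimulationConfig) -> dict:
    model = config.model
    return {
        "T": model.T,
        "lengths": list(model.lengths),
        "weights": list(model.weights) if model.weights is not None else None,
        "read_length": model.read_length,
        "weight_mode": WeightMode(model.weight_mode).value,
        "M": config.M,
        "S": config.S,
        "pcr_cycles": config.pcr_cycles,
        "seed": config.seed,
    }


def _config_from_dict(data: dict) -> SimulationConfig:
    weights = data.get("weights")
    model = PatternSpaceModel(
        data["T"], data["lengths"],
        weights=dict(zip(data["lengths"], weights)) if weights else None,
        read_length=data.get("read_length", 1),
        weight_mode=data.get("weight_mode", "contribution"),
    )
    return SimulationConfig(model, M=data["M"], S=data["S"],
                            pcr_cycles=data["pcr_cycles"], seed=data["seed"])


def write_reference_set(ref: ReferenceSet, directory: str | os.PathLike) -> None:
    """Directory of per-M ECDF TSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": ref.grid,
        "n_rep": ref.n_rep,
        "seed": ref.seed,
        "config": _config_to_dict(ref.config),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for m in ref.grid:
        ecdf = ref.ecdfs[m]
        with open(directory / f"ecdf_M{m}.tsv", "w") as fh:
            fh.write("value\tcumulative_probability\n")
            for x, p in zip(ecdf.x, ecdf.p):
                fh.write(f"{_FLOAT_FMT % x}\t{_FLOAT_FMT % p}\n")


def read_reference_set(directory: str | os.PathLike) -> ReferenceSet:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    config = _config_from_dict(manifest["config"])
    ecdfs = {}
    for m in manifest["grid"]:
        table = pd.read_csv(directory / f"ecdf_M{m}.tsv", sep="\t")
        ecdfs[int(m)] = ECDF(table["value"].to_numpy(),
                             table["cumulative_probability"].to_numpy())
    return ReferenceSet(grid=[int(m) for m in manifest["grid"]], ecdfs=ecdfs,
                        config=config, n_rep=int(manifest["n_rep"]),
                        seed=int(manifest["seed"]))


# -- model config and manifests ---------------------------------------------

def load_model_config(path: str | os.PathLike) -> PatternSpaceModel:
    """Flat key-value config: T, lengths or length_range, weights_file,
    read_length, weight_mode."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "lengths" in data:
        lengths = [int(f) for f in data["lengths"]]
    elif "length_range" in data:
        lo, hi = data["length_range"]
        lengths = list(range(int(lo), int(hi) + 1))
    else:
        raise ValueError("config needs 'lengths' or 'length_range'")
    weights = None
    if data.get("weights_file"):
        weights = read_weights(data["weights_file"])
    return PatternSpaceModel(
        int(data["T"]), lengths, weights=weights,
        read_length=int(data.get("read_length", 1)),
        weight_mode=data.get("weight_mode", "contribution"),
    )


def write_manifest(directory: str | os.PathLike, payload: dict) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "manifest.json").write_text(json.dumps(payload, indent=2, default=str))
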