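"""Readers and writers for the on-disk formats (HDF5 containers, CSV labels).

Trial containers: dataset ``/trials`` (n_trials, E, T) float64, ``/labels``
int32, root attributes ``sampling_rate``, ``n_segments``, ``segment_len``,
plus a companion ``labels.csv`` next to the container.  Feature caches:
``/features`` (n_trials, 2, S, E, L), ``/labels``, and the fitted normalizer
min/max arrays.  Every writer embeds the seed/config hash it was given.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from .mra import Normalizer
from .synthetic import LabeledTrialSet

__all__ = [
    "write_trials",
    "read_trials",
    "write_features",
    "read_features",
    "write_archive",
    "read_archive",
    "config_hash",
    "SchemaError",
]


class SchemaError(ValueError):
    """A required dataset/attribute is missing or inconsistent."""


def config_hash(config_obj) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    if hasattr(config_obj, "__dataclass_fields__"):
        import dataclasses

        config_obj = dataclasses.asdict(config_obj)
    payload = json.dumps(config_obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_provenance(handle: h5py.File, seed: int | None, extra: dict | None) -> None:
    if seed is not None:
        handle.attrs["seed"] = int(seed)
    for key, value in (extra or {}).items():
        handle.attrs[key] = value


def write_trials(
    trial_set: LabeledTrialSet,
    path: "str | Path",
    seed: int | None = None,
    extra_attrs: dict | None = None,
) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=trial_set.trials, dtype="float64")
        f.create_dataset("labels", data=trial_set.labels.astype(np.int32))
        f.attrs["sampling_rate"] = float(trial_set.sampling_rate)
        f.attrs["n_segments"] = int(trial_set.n_segments)
        f.attrs["segment_len"] = int(trial_set.segment_len)
        _write_provenance(f, seed, extra_attrs)
    with open(path.with_suffix(".labels.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["trial_id", "label"])
        for i, label in enumerate(trial_set.labels):
            writer.writerow([i, int(label)])


def read_trials(path: "str | Path") -> LabeledTrialSet:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        for key in ("trials", "labels"):
            if key not in f:
                raise SchemaError(f"missing dataset '/{key}' in {path}")
        for attr in ("sampling_rate", "n_segments", "segment_len"):
            if attr not in f.attrs:
                raise SchemaError(f"missing attribute '{attr}' in {path}")
        trial_set = LabeledTrialSet(
            trials=f["trials"][...],
            labels=f["labels"][...],
            sampling_rate=float(f.attrs["sampling_rate"]),
            n_segments=int(f.attrs["n_segments"]),
            segment_len=int(f.attrs["segment_len"]),
        )
    labels_csv = path.with_suffix(".labels.csv")
    if labels_csv.exists():
        with open(labels_csv, newline="") as fh:
            rows = list(csv.DictReader(fh))
        ids = sorted(int(r["trial_id"]) for r in rows)
        if ids != list(range(len(trial_set))):
            raise SchemaError(f"labels.csv trial_id column inconsistent with {path}")
    return trial_set


def write_features(
    features: np.ndarray,
    labels: np.ndarray,
    normalizer: Normalizer,
    path: "str | Path",
    seed: int | None = None,
    extra_attrs: dict | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.asarray(features, dtype="float64"))
        f.create_dataset("labels", data=np.asarray(labels).astype(np.int32))
        f.create_dataset("normalizer_min", data=normalizer.minimum)
        f.create_dataset("normalizer_max", data=normalizer.maximum)
        _write_provenance(f, seed, extra_attrs)


def read_features(path: "str | Path") -> tuple[np.ndarray, np.ndarray, Normalizer]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        for key in ("features", "labels", "normalizer_min", "normalizer_max"):
            if key not in f:
                raise SchemaError(f"missing dataset '/{key}' in {path}")
        features = f["features"][...]
        labels = f["labels"][...]
        normalizer = Normalizer(minimum=f["normalizer_min"][...], maximum=f["normalizer_max"][...])
    if features.ndim != 5 or features.shape[1] != 2:
        raise SchemaError(f"'/features' must be (n, 2, S, E, L); got {features.shape}")
    return features, labels, normalizer


def write_archive(archive, path: "str | Path", extra: dict | None = None) -> None:
    """Serialize a ParetoArchive (genomes, costs, provenance) to JSON."""
    payload = {
        "provenance": {**archive.provenance, **(extra or {})},
        "individuals": [
            {
                "genome": ind.genome.tolist(),
                "costs": list(map(float, ind.costs)),
                "rank": int(ind.rank),
                "crowding": None if np.isinf(ind.crowding) else float(ind.crowding),
            }
            for ind in archive.individuals
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_archive(path: "str | Path"):
    from .moo import Individual, ParetoArchive

    payload = json.loads(Path(path).read_text())
    individuals = [
        Individual(
            genome=np.asarray(entry["genome"], dtype=float),
            costs=tuple(entry["costs"]),
            rank=entry["rank"],
            crowding=np.inf if entry["crowding"] is None else entry["crowding"],
        )
        for entry in payload["individuals"]
    ]
    return ParetoArchive(individuals=individuals, provenance=payload.get("provenance", {}))
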