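"""JSON serialization of trained models (ensembles and sparse pipelines).

Only the quantities needed for prediction are stored: linear discriminant /
margin coefficients, intercepts, class ids, member feature slices, dictionary
atoms.  Files are plain JSON so bundles stay text and diffable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import LinearSVC

from .classifiers import EnsembleModel, LDAModel, SVCModel
from .sparse import SparseDictionary, SRModel

__all__ = ["save_model", "load_model"]


def _linear_to_dict(est) -> dict:
    return {
        "coef": np.asarray(est.coef_).tolist(),
        "intercept": np.asarray(est.intercept_).tolist(),
        "classes": np.asarray(est.classes_).tolist(),
    }


def _lda_from_dict(d: dict, n_features: int) -> LDAModel:
    est = LinearDiscriminantAnalysis(solver="lsqr")
    est.coef_ = np.asarray(d["coef"], dtype=float)
    est.intercept_ = np.asarray(d["intercept"], dtype=float)
    est.classes_ = np.asarray(d["classes"])
    return LDAModel(estimator=est, n_features=n_features)


def _svc_from_dict(d: dict, n_features: int) -> SVCModel:
    est = LinearSVC()
    est.coef_ = np.asarray(d["coef"], dtype=float)
    est.intercept_ = np.asarray(d["intercept"], dtype=float)
    est.classes_ = np.asarray(d["classes"])
    return SVCModel(estimator=est, n_features=n_features)


def _spec_to_json(spec) -> dict:
    if spec[0] == "tsl":
        return {"kind": "tsl", "type": spec[1], "segment": spec[2], "level": spec[3]}
    return {"kind": "seg", "segment": spec[1], "mask": np.asarray(spec[2]).astype(int).tolist()}


def _spec_from_json(d: dict):
    if d["kind"] == "tsl":
        return ("tsl", d["type"], d["segment"], d["level"])
    return ("seg", d["segment"], np.asarray(d["mask"], dtype=bool))


def save_model(model, path: "str | Path", extra: dict | None = None) -> None:
    if isinstance(model, EnsembleModel):
        payload = {
            "kind": "ensemble",
            "structure": model.structure,
            "n_classes": model.n_classes,
            "shape": list(model.shape),
            "members": [
                {
                    "spec": _spec_to_json(spec),
                    "lda": _linear_to_dict(lda.estimator),
                    "n_features": lda.n_features,
                }
                for spec, lda in model.members
            ],
        }
    elif isinstance(model, SRModel):
        payload = {
            "kind": "sr",
            "head_kind": model.head_kind,
            "max_nonzero": model.max_nonzero,
            "shape": list(model.shape),
            "atoms": model.dictionary.atoms.tolist(),
            "class_ranges": [list(r) for r in model.dictionary.class_ranges],
            "head": _linear_to_dict(model.head.estimator),
            "head_n_features": model.head.n_features,
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    payload["meta"] = extra or {}
    Path(path).write_text(json.dumps(payload))


def load_model(path: "str | Path"):
    payload = json.loads(Path(path).read_text())
    if payload["kind"] == "ensemble":
        members = []
        for entry in payload["members"]:
            spec = _spec_from_json(entry["spec"])
            members.append((spec, _lda_from_dict(entry["lda"], entry["n_features"])))
        return EnsembleModel(
            structure=payload["structure"],
            members=members,
            n_classes=payload["n_classes"],
            shape=tuple(payload["shape"]),
        )
    if payload["kind"] == "sr":
        dictionary = SparseDictionary(
            atoms=np.asarray(payload["atoms"], dtype=float),
            class_ranges=[tuple(r) for r in payload["class_ranges"]],
        )
        if payload["head_kind"] == "lda":
            head = _lda_from_dict(payload["head"], payload["head_n_features"])
        else:
            head = _svc_from_dict(payload["head"], payload["head_n_features"])
        return SRModel(
            dictionary=dictionary,
            head=head,
            head_kind=payload["head_kind"],
            max_nonzero=payload["max_nonzero"],
            shape=tuple(payload["shape"]),
        )
    raise ValueError(f"unknown model kind {payload['kind']!r}")
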