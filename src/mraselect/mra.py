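"""Multiresolution variance features for segmented multichannel trials.

Each trial (E electrodes x S*segment_len samples) is cut into S contiguous
segments; every (segment, electrode) signal is decomposed with an L-level
dyadic DWT keeping approximation and detail coefficients at every level, and
each of the 2*L coefficient sets is reduced to its population variance.  The
result is one real value per (type, segment, electrode, level) — a tensor of
2*S*E*L features per trial — followed by per-feature min-max normalization
learned on training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import wavelets

__all__ = [
    "MRAConfig",
    "Normalizer",
    "segment_trial",
    "dwt_multilevel",
    "variance_reduce",
    "fit_normalizer",
    "apply_normalizer",
    "extract_features",
    "feature_shape",
    "n_features",
    "flat_index",
    "structured_index",
    "MRAError",
]

APPROX, DETAIL = 0, 1  # coefficient-type axis ordering


class MRAError(ValueError):
    """Invalid MRA configuration or input dimensions."""


@dataclass(frozen=True)
class MRAConfig:
    """Feature-extraction geometry.

    Attributes
    ----------
    n_segments : number of contiguous segments per trial (S).
    n_electrodes : channels per trial (E).
    n_levels : DWT depth (L); every level contributes one approximation and
        one detail coefficient set.
    segment_len : samples per segment; must be divisible by ``2**n_levels``.
    wavelet : orthonormal wavelet name (``haar`` / ``dbN``).
    """

    n_segments: int = 20
    n_electrodes: int = 15
    n_levels: int = 6
    segment_len: int = 256
    wavelet: str = "db4"

    def __post_init__(self) -> None:
        if min(self.n_segments, self.n_electrodes, self.n_levels) < 1:
            raise MRAError("n_segments, n_electrodes and n_levels must all be >= 1")
        if self.segment_len < 2**self.n_levels or self.segment_len % (2**self.n_levels):
            raise MRAError(
                f"segment_len={self.segment_len} does not support "
                f"{self.n_levels} dyadic levels"
            )

    @property
    def trial_len(self) -> int:
        return self.n_segments * self.segment_len

    @property
    def n_features(self) -> int:
        """Flattened feature count 2*S*E*L."""
        return 2 * self.n_segments * self.n_electrodes * self.n_levels


def feature_shape(config: MRAConfig) -> tuple[int, int, int, int]:
    """Structured feature-tensor shape (type, segment, electrode, level)."""
    return (2, config.n_segments, config.n_electrodes, config.n_levels)


def n_features(config: MRAConfig) -> int:
    return config.n_features


def flat_index(config: MRAConfig, ctype: int, segment: int, electrode: int, level: int) -> int:
    """Flat feature index of a structured (type, segment, electrode, level) entry.

    Level is 1-based (level 1 = finest band), matching the transform depth.
    """
    return int(
        np.ravel_multi_index(
            (ctype, segment, electrode, level - 1), feature_shape(config)
        )
    )


def structured_index(config: MRAConfig, flat: int) -> tuple[int, int, int, int]:
    """Inverse of :func:`flat_index`; returns (type, segment, electrode, level)."""
    ctype, seg, elec, lvl0 = np.unravel_index(flat, feature_shape(config))
    return int(ctype), int(seg), int(elec), int(lvl0) + 1


def segment_trial(trial: np.ndarray, config: MRAConfig) -> list[np.ndarray]:
    """Split an E x T trial into S contiguous E x segment_len blocks."""
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise MRAError(f"trial must be 2-D (electrodes x samples), got shape {trial.shape}")
    expected = config.n_segments * config.segment_len
    if trial.shape[1] != expected:
        raise MRAError(
            f"trial has {trial.shape[1]} samples; expected "
            f"{config.n_segments} x {config.segment_len} = {expected}"
        )
    return [
        trial[:, s * config.segment_len : (s + 1) * config.segment_len]
        for s in range(config.n_segments)
    ]


def dwt_multilevel(signal: np.ndarray, levels: int, wavelet: str = "db4") -> tuple[list[np.ndarray], list[np.ndarray]]:
    """L-level decomposition returning (approximations, details) per level.

    Set sizes halve per level: for a 256-sample signal and 6 levels both lists
    hold sets of sizes (128, 64, 32, 16, 8, 4).
    """
    return wavelets.wavedec(signal, levels, wavelet)


def variance_reduce(approx: list[np.ndarray], detail: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Population variance of every coefficient set.

    Returns two length-L vectors (approximation variances, detail variances).
    """
    for sets in (approx, detail):
        for s in sets:
            if np.asarray(s).size < 2:
                raise MRAError("variance_reduce needs >= 2 coefficients per set")
    return (
        np.array([np.var(s) for s in approx]),
        np.array([np.var(s) for s in detail]),
    )


@dataclass
class Normalizer:
    """Per-feature min-max scaler fitted on training trials.

    ``transform`` maps x -> (x - min) / (max - min); features constant on the
    training set map to 0; outputs are NOT clipped, so unseen data may fall
    outside [0, 1].
    """

    minimum: np.ndarray = field(repr=False)
    maximum: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise MRAError("normalizer min/max shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise MRAError("normalizer max < min")

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.shape[-len(self.minimum.shape):] != self.minimum.shape:
            raise MRAError(
                f"feature shape {features.shape} incompatible with normalizer "
                f"shape {self.minimum.shape}"
            )
        span = self.maximum - self.minimum
        out = np.zeros_like(features)
        ok = span > 0
        out[..., ok] = (features[..., ok] - self.minimum[ok]) / span[ok]
        return out


def fit_normalizer(training_features: np.ndarray) -> Normalizer:
    """Learn per-feature min/max from a (n_trials, ...) stack of raw features."""
    training_features = np.asarray(training_features, dtype=float)
    if training_features.shape[0] < 2:
        raise MRAError("fit_normalizer needs >= 2 training trials")
    return Normalizer(
        minimum=training_features.min(axis=0), maximum=training_features.max(axis=0)
    )


def apply_normalizer(normalizer: Normalizer, features: np.ndarray) -> np.ndarray:
    if normalizer is None:
        raise MRAError("apply_normalizer called before fit")
    return normalizer.transform(features)


def raw_features_for_trial(trial: np.ndarray, config: MRAConfig) -> np.ndarray:
    """Unnormalized (2, S, E, L) variance tensor for one trial."""
    out = np.empty(feature_shape(config))
    for s, block in enumerate(segment_trial(trial, config)):
        for e in range(config.n_electrodes):
            approx, detail = dwt_multilevel(block[e], config.n_levels, config.wavelet)
            va, vd = variance_reduce(approx, detail)
            out[APPROX, s, e, :] = va
            out[DETAIL, s, e, :] = vd
    return out


def extract_features(
    trials: "np.ndarray | list[np.ndarray]",
    config: MRAConfig,
    normalizer: Normalizer | None = None,
) -> tuple[np.ndarray, Normalizer]:
    """Compute normalized variance features for a stack of trials.

    Parameters
    ----------
    trials : (n_trials, E, T) array or list of E x T matrices.
    normalizer : if None (training mode) a min-max normalizer is fitted on the
        given trials; otherwise (test mode) the frozen normalizer is applied.

    Returns
    -------
    (features, normalizer) with features shaped (n_trials, 2, S, E, L).
    """
    raw = np.stack([raw_features_for_trial(np.asarray(t), config) for t in trials])
    if normalizer is None:
        normalizer = fit_normalizer(raw)
    return normalizer.transform(raw), normalizer


def flatten_features(features: np.ndarray) -> np.ndarray:
    """(n_trials, 2, S, E, L) -> (n_trials, 2*S*E*L), C-order."""
    features = np.asarray(features)
    return features.reshape(features.shape[0], -1)
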