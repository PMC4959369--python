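"""Synthetic multichannel trial generator with planted class structure.

Trials are 1/f-like colored Gaussian noise per electrode with band-limited
oscillation bursts added at configurable (electrode, segment-range, band)
sites.  Every class receives a baseline burst at each site; the site's target
class receives the burst scaled by the site gain, producing the band-power
amplification/attenuation that motor-imagery classifiers exploit.  Generation
is a pure function of (config, seed): each trial draws from its own
counter-derived substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mra import APPROX, DETAIL, MRAConfig, feature_shape

__all__ = [
    "InformativeSite",
    "SynthConfig",
    "LabeledTrialSet",
    "generate_dataset",
    "ground_truth_mask",
    "split_train_test",
    "level_band",
    "SynthConfigError",
]


class SynthConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class InformativeSite:
    """A class-discriminative band-power location.

    ``segments`` is a half-open (start, stop) range; ``band`` is an (f_lo,
    f_hi) Hz interval; ``gain`` multiplies the baseline burst amplitude for
    trials of ``class_id`` (gain > 1 amplifies, < 1 attenuates).
    """

    class_id: int
    electrode: int
    segments: tuple[int, int]
    band: tuple[float, float]
    gain: float


@dataclass(frozen=True)
class SynthConfig:
    n_classes: int = 3
    trials_per_class: int = 120
    n_electrodes: int = 15
    n_segments: int = 20
    segment_len: int = 256
    sampling_rate: float = 256.0
    informative_sites: tuple[InformativeSite, ...] = field(default_factory=tuple)
    noise_exponent: float = 1.0
    snr: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_class < 1:
            raise SynthConfigError("trials_per_class must be >= 1")
        if self.n_classes < 1:
            raise SynthConfigError("n_classes must be >= 1")
        if self.segment_len < 2 or self.segment_len & (self.segment_len - 1):
            raise SynthConfigError(
                f"segment_len must be a power of two >= 2, got {self.segment_len}"
            )
        sites = tuple(
            s if isinstance(s, InformativeSite) else InformativeSite(*s)
            for s in self.informative_sites
        )
        object.__setattr__(self, "informative_sites", sites)
        for s in sites:
            if s.gain <= 0:
                raise SynthConfigError(f"site gain must be > 0, got {s.gain}")
            if not 0 <= s.class_id < self.n_classes:
                raise SynthConfigError(f"site class {s.class_id} out of range")
            if not 0 <= s.electrode < self.n_electrodes:
                raise SynthConfigError(f"site electrode {s.electrode} out of range")
            lo, hi = s.segments
            if not (0 <= lo < hi <= self.n_segments):
                raise SynthConfigError(f"site segment range {s.segments} invalid")
            if not (0 < s.band[0] < s.band[1] <= self.sampling_rate / 2):
                raise SynthConfigError(f"site band {s.band} outside (0, Nyquist]")
        self._check_contradictions(sites)

    @staticmethod
    def _check_contradictions(sites: tuple[InformativeSite, ...]) -> None:
        # Two sites for the same class that overlap in electrode, segments and
        # band but demand different gains are contradictory.
        for i, a in enumerate(sites):
            for b in sites[i + 1 :]:
                if a.class_id != b.class_id or a.electrode != b.electrode:
                    continue
                seg_overlap = a.segments[0] < b.segments[1] and b.segments[0] < a.segments[1]
                band_overlap = a.band[0] < b.band[1] and b.band[0] < a.band[1]
                if seg_overlap and band_overlap and a.gain != b.gain:
                    raise SynthConfigError(
                        f"contradictory overlapping sites: {a} vs {b}"
                    )

    @property
    def trial_len(self) -> int:
        return self.n_segments * self.segment_len

    @property
    def n_trials(self) -> int:
        return self.n_classes * self.trials_per_class


@dataclass
class LabeledTrialSet:
    """Stack of same-shaped trials with one class label each."""

    trials: np.ndarray  # (n_trials, E, T)
    labels: np.ndarray  # (n_trials,) int
    sampling_rate: float
    n_segments: int
    segment_len: int

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise SynthConfigError("trials must be (n_trials, E, T)")
        if self.trials.shape[0] != self.labels.shape[0]:
            raise SynthConfigError("labels/trials length mismatch")
        if self.trials.shape[2] != self.n_segments * self.segment_len:
            raise SynthConfigError("trial length inconsistent with segmentation")

    def __len__(self) -> int:
        return self.trials.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.trials.shape[1]

    def subset(self, indices: np.ndarray) -> "LabeledTrialSet":
        return LabeledTrialSet(
            trials=self.trials[indices],
            labels=self.labels[indices],
            sampling_rate=self.sampling_rate,
            n_segments=self.n_segments,
            segment_len=self.segment_len,
        )


def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent amplitude spectrum."""
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0  # zero-mean
    spectrum = shape * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    # Counter-based substream: reproducible independent of generation order.
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(trial_index,)))


def generate_dataset(config: SynthConfig) -> LabeledTrialSet:
    """Generate ``trials_per_class * n_classes`` labeled trials.

    Trial t of class c: per-electrode colored noise plus, for every configured
    site, a random-phase sinusoid burst in the site band over the site segment
    range, with amplitude ``snr`` (baseline) times the site gain when c is the
    site's class.
    """
    T = config.trial_len
    labels = np.repeat(np.arange(config.n_classes), config.trials_per_class)
    trials = np.empty((config.n_trials, config.n_electrodes, T))
    t_axis = np.arange(T) / config.sampling_rate
    for i, label in enumerate(labels):
        rng = _trial_rng(config.seed, i)
        for e in range(config.n_electrodes):
            trials[i, e] = _colored_noise(rng, T, config.noise_exponent)
        for site in config.informative_sites:
            freq = rng.uniform(*site.band)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            amplitude = config.snr * (site.gain if label == site.class_id else 1.0)
            lo = site.segments[0] * config.segment_len
            hi = site.segments[1] * config.segment_len
            trials[i, site.electrode, lo:hi] += amplitude * np.sin(
                2.0 * np.pi * freq * t_axis[lo:hi] + phase
            )
    return LabeledTrialSet(
        trials=trials,
        labels=labels,
        sampling_rate=config.sampling_rate,
        n_segments=config.n_segments,
        segment_len=config.segment_len,
    )


def level_band(level: int, n_levels: int, sampling_rate: float, ctype: int) -> tuple[float, float]:
    """Nominal Hz band of a DWT coefficient set.

    Detail at level l covers the octave [fs/2^(l+1), fs/2^l]; the terminal
    approximation band is [0, fs/2^(L+1)].
    """
    if ctype == DETAIL or level < n_levels:
        return sampling_rate / 2 ** (level + 1), sampling_rate / 2**level
    return 0.0, sampling_rate / 2 ** (n_levels + 1)


def ground_truth_mask(config: SynthConfig, mra_config: MRAConfig) -> np.ndarray:
    """Binary (2, S, E, L) mask of features intersecting informative sites.

    A site marks both coefficient types at every DWT level whose detail octave
    overlaps the site band (plus the terminal approximation band when the site
    reaches below it), for each segment in the site's range, at the site's
    electrode.
    """
    if (
        mra_config.n_segments != config.n_segments
        or mra_config.n_electrodes != config.n_electrodes
        or mra_config.segment_len != config.segment_len
    ):
        raise SynthConfigError("mra_config dimensions incompatible with SynthConfig")
    fs = config.sampling_rate
    L = mra_config.n_levels
    mask = np.zeros(feature_shape(mra_config), dtype=bool)
    for site in config.informative_sites:
        lo, hi = site.band
        levels = [
            l
            for l in range(1, L + 1)
            if lo < fs / 2**l and fs / 2 ** (l + 1) < hi
        ]
        if lo < fs / 2 ** (L + 1):  # reaches the terminal approximation band
            levels.append(L)
        for l in sorted(set(levels)):
            for s in range(*site.segments):
                mask[APPROX, s, site.electrode, l - 1] = True
                mask[DETAIL, s, site.electrode, l - 1] = True
    return mask


def split_train_test(
    trial_set: LabeledTrialSet, train_fraction: float, seed: int
) -> tuple[LabeledTrialSet, LabeledTrialSet]:
    """Stratified per-class split; union = input, intersection empty."""
    if not 0.0 < train_fraction < 1.0:
        raise SynthConfigError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(trial_set.labels):
        members = np.flatnonzero(trial_set.labels == cls)
        if members.size < 2:
            raise SynthConfigError(f"class {cls} has < 2 trials; cannot split")
        perm = rng.permutation(members)
        n_train = int(round(train_fraction * members.size))
        n_train = min(max(n_train, 1), members.size - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return (
        trial_set.subset(np.sort(np.asarray(train_idx))),
        trial_set.subset(np.sort(np.asarray(test_idx))),
    )
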