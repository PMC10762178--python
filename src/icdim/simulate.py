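"""Synthetic EEG-like sources and their linear mixtures.

The generator emulates the standard blind-source-separation study design:
``q_true`` source signals of mixed periodic / non-periodic character are
combined through a random standard-normal mixing matrix ``A`` into ``p``
observed channels, ``X = A S``, optionally with additive Gaussian noise at
a requested per-channel SNR.  The waveform catalog mimics the qualitative
variety of scalp-EEG constituents (rhythms, sweeps, spikes, blinks, drifts,
heavy-tailed noise) without any claim of physiological calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "SourceSet",
    "MixingSpec",
    "SignalMatrix",
    "CATALOG_NAMES",
    "simulate_sources",
    "mix_signals",
]

# Condition-number ceiling above which a drawn mixing matrix is rejected.
_MAX_CONDITION = 1e8


@dataclass(frozen=True)
class SignalMatrix:
    """A ``p x n`` matrix of observed (mixed) channels, one row per channel."""

    data: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"signal matrix must be 2-D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("signal matrix contains non-finite entries")
        p, n = data.shape
        if p < 2:
            raise ValueError(f"need at least 2 channels, got p={p}")
        if n < 4:
            raise ValueError(f"need at least 4 samples, got n={n}")
        if n < 10 * p:
            warnings.warn(
                f"signal length n={n} is short relative to p={p} channels "
                "(n >= 10*p recommended for stable ICA)",
                stacklevel=2,
            )
        if self.channel_labels is not None and len(self.channel_labels) != p:
            raise ValueError(
                f"{len(self.channel_labels)} channel labels for {p} channels"
            )
        object.__setattr__(self, "data", data)

    @property
    def p(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    @property
    def sample_count(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class SourceSet:
    """Ground-truth source signals, one standardized waveform per row."""

    signals: np.ndarray
    kinds: list[str]
    seed: int

    @property
    def source_count(self) -> int:
        return self.signals.shape[0]

    @property
    def sample_count(self) -> int:
        return self.signals.shape[1]


@dataclass(frozen=True)
class MixingSpec:
    """The mixing matrix and noise level used to build a mixture."""

    mixing_matrix: np.ndarray
    snr_db: float | None
    p: int
    seed: int
    noise: np.ndarray | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# Waveform catalog.
#
# Deterministic waveforms are pure functions of the time axis; stochastic
# ones draw from a per-waveform generator so that each row depends only on
# (seed, row index), never on how many other rows were requested.
# Frequencies are in cycles per window (an n-sample window standing in for
# roughly one second of EEG), multiplied by ``freq_scale``.
# ---------------------------------------------------------------------------


def _sine(t, n, fs, rng):
    return np.sin(2.0 * np.pi * 10.0 * fs * t)


def _sawtooth(t, n, fs, rng):
    return sps.sawtooth(2.0 * np.pi * 6.0 * fs * t)


def _square(t, n, fs, rng):
    return sps.square(2.0 * np.pi * 21.0 * fs * t)


def _chirp(t, n, fs, rng):
    # Linear sweep from 2 to 30 cycles/window: mimics a frequency-modulated
    # rhythm; instantaneous frequency rises through the epoch.
    return sps.chirp(t, f0=2.0 * fs, f1=30.0 * fs, t1=1.0, method="linear")


def _spikes(t, n, fs, rng):
    # Sparse impulsive activity: ~2% of samples carry a spike of random
    # sign and amplitude, lightly smoothed so spikes span a few samples.
    x = np.zeros(n)
    k = max(3, int(round(0.02 * n)))
    idx = rng.choice(n, size=k, replace=False)
    x[idx] = rng.standard_normal(k) * 5.0 + np.sign(rng.standard_normal(k)) * 3.0
    kernel = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
    return np.convolve(x, kernel, mode="same")


def _blinks(t, n, fs, rng):
    # Eye-blink-like train: positive raised-cosine bumps (~6% of the window
    # wide) at random, non-overlapping-ish onsets.
    x = np.zeros(n)
    width = max(8, int(round(0.06 * n)))
    bump = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(width) / (width - 1)))
    n_bumps = max(2, int(round(n / (6.0 * width))))
    onsets = rng.choice(max(1, n - width), size=n_bumps, replace=False)
    for o in onsets:
        x[o : o + width] += bump * (0.8 + 0.4 * rng.random())
    return x


def _slow_drift(t, n, fs, rng):
    # Low-pass filtered white noise (smoothed random walk): slow baseline
    # wander such as sweat or electrode drift.
    w = rng.standard_normal(n)
    b, a = sps.butter(4, 0.02)
    return sps.filtfilt(b, a, w)


def _laplace_noise(t, n, fs, rng):
    return rng.laplace(size=n)


_CATALOG = [
    ("sine_10", _sine, False),
    ("sawtooth_6", _sawtooth, False),
    ("square_21", _square, False),
    ("chirp_2_30", _chirp, False),
    ("spike_train", _spikes, True),
    ("blink_bumps", _blinks, True),
    ("slow_drift", _slow_drift, True),
    ("laplace_noise", _laplace_noise, True),
]

CATALOG_NAMES: list[str] = [name for name, _, _ in _CATALOG]


def simulate_sources(
    q_true: int,
    n: int,
    catalog: list[str] | None = None,
    freq_scale: float = 1.0,
    seed: int = 0,
) -> SourceSet:
    """Draw ``q_true`` standardized source signals from the waveform catalog.

    Rows are taken in fixed catalog order (the first ``q_true`` entries of
    ``catalog``), each standardized to zero mean and unit variance.
    Deterministic waveforms (sine, sawtooth, square, chirp) do not depend on
    the seed; stochastic ones depend only on ``(seed, catalog position)``.

    Parameters
    ----------
    q_true
        Number of source signals, at least 2 and at most the catalog size.
    n
        Samples per signal, at least 64.
    catalog
        Optional list of waveform names (subset/reordering of
        :data:`CATALOG_NAMES`); defaults to the full 8-entry catalog.
    freq_scale
        Multiplies the base frequency of every periodic waveform; realizes
        "different frequency range" variants of the same catalog.
    seed
        Seed for the stochastic waveforms.
    """
    names = CATALOG_NAMES if catalog is None else list(catalog)
    if q_true < 2:
        raise ValueError(f"q_true must be >= 2, got {q_true}")
    if q_true > len(names):
        raise ValueError(
            f"q_true={q_true} exceeds the catalog size ({len(names)} waveforms: "
            f"{', '.join(names)})"
        )
    if n < 64:
        raise ValueError(f"n must be >= 64, got {n}")
    if freq_scale <= 0:
        raise ValueError("freq_scale must be positive")
    by_name = {name: (fn, stochastic) for name, fn, stochastic in _CATALOG}
    unknown = [nm for nm in names if nm not in by_name]
    if unknown:
        raise ValueError(f"unknown waveform(s): {unknown}")

    t = np.arange(n) / n
    rows = np.empty((q_true, n))
    kinds: list[str] = []
    for i in range(q_true):
        fn, stochastic = by_name[names[i]]
        rng = np.random.default_rng([seed, i]) if stochastic else None
        row = np.asarray(fn(t, n, freq_scale, rng), dtype=float)
        row = row - row.mean()
        sd = row.std()
        if sd == 0:
            raise ValueError(f"waveform {names[i]!r} produced a constant signal")
        rows[i] = row / sd
        kinds.append(names[i])
    return SourceSet(signals=rows, kinds=kinds, seed=seed)


def _draw_mixing(p: int, q: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal mixing matrix, redrawn wholesale if ill-conditioned."""
    for _ in range(100):
        A = rng.standard_normal((p, q))
        s = np.linalg.svd(A, compute_uv=False)
        if s[-1] > 0 and s[0] / s[-1] < _MAX_CONDITION:
            return A
    raise RuntimeError("could not draw a well-conditioned mixing matrix")


def mix_signals(
    sources: SourceSet,
    p: int,
    snr_db: float | None = None,
    seed: int = 0,
) -> tuple[SignalMatrix, MixingSpec]:
    """Linearly mix sources into ``p`` channels, ``X = A S`` (+ noise).

    ``A`` is ``p x q_true`` with i.i.d. standard-normal entries.  When
    ``snr_db`` is given, i.i.d. zero-mean Gaussian noise is added to each
    mixed row, scaled so that ``10 log10(row signal power / noise power)``
    equals ``snr_db`` for that row.
    """
    q = sources.source_count
    if p < q:
        raise ValueError(
            f"p={p} < q_true={q}: the underdetermined regime is not supported"
        )
    rng = np.random.default_rng(seed)
    A = _draw_mixing(p, q, rng)
    X = A @ sources.signals
    noise = None
    if snr_db is not None:
        signal_power = np.mean(X**2, axis=1)
        noise_power = signal_power / (10.0 ** (snr_db / 10.0))
        raw = rng.standard_normal(X.shape)
        raw = raw - raw.mean(axis=1, keepdims=True)
        raw = raw / raw.std(axis=1, keepdims=True)
        noise = raw * np.sqrt(noise_power)[:, None]
        X = X + noise
    spec = MixingSpec(mixing_matrix=A, snr_db=snr_db, p=p, seed=seed, noise=noise)
    return SignalMatrix(data=X), spec
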