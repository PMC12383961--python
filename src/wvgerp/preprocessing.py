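"""Trial averaging, filter bank, cropping and 80 ms block averaging.

The chain producing one series per (channel, band, condition):

1. average the selected trials of a (channel, condition) cell;
2. mirror-pad the 4 s epoch by 2 s on each side (suppresses filter edge
   transients);
3. band-pass with zero-phase Hamming windowed-sinc FIR filters (high-pass
   then low-pass, -6 dB at the centre of each transition band); the "raw"
   band skips filtering;
4. crop to -1..+2 s around word onset (750 samples at 250 Hz);
5. average consecutive non-overlapping 20-sample (80 ms) blocks, dropping
   a trailing partial block -> 37 points.

Every stage is linear, so scaling the input scales the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import fftconvolve, firwin

from .config import BAND_EDGES, PipelineConfig
from .synthetic import EpochSet

#: FIR length factor: kernel spans ~3.3 periods of the transition bandwidth.
_TAPS_FACTOR = 3.3


@dataclass(frozen=True)
class BandSpec:
    """One filter-bank band: passband edges and transition bandwidths (Hz)."""

    name: str
    low: float | None
    high: float | None
    trans_low: float | None
    trans_high: float | None

    def __post_init__(self) -> None:
        if self.name != "raw":
            if self.low is None or self.high is None or self.low >= self.high:
                raise ValueError("band requires low edge < high edge")
            if self.trans_low <= 0 or self.trans_high <= 0:
                raise ValueError("transition bandwidths must be positive")


def transition_bandwidth(edge: float) -> float:
    """25% of the passband edge, at least 2 Hz, but never above the edge."""
    return min(max(0.25 * edge, 2.0), edge)


def band_spec(name: str) -> BandSpec:
    """BandSpec for a named band (raw/delta/theta/alpha/beta/gamma)."""
    if name == "raw":
        return BandSpec("raw", None, None, None, None)
    try:
        low, high = BAND_EDGES[name]
    except KeyError:
        raise ValueError(f"unknown band {name!r}") from None
    return BandSpec(name, low, high,
                    transition_bandwidth(low), transition_bandwidth(high))


def average_trials(trials: np.ndarray | list) -> np.ndarray:
    """Pointwise arithmetic mean of equally long trials."""
    if len(trials) == 0:
        raise ValueError("cannot average an empty trial list")
    arr = np.asarray(trials, dtype=float)
    if arr.ndim != 2:
        raise ValueError("trials must share a common length")
    return arr.mean(axis=0)


def mirror_pad(series: np.ndarray, pad_samples: int) -> np.ndarray:
    """Reflect about each boundary without duplicating the boundary sample."""
    series = np.asarray(series)
    if pad_samples < 0:
        raise ValueError("pad_samples must be non-negative")
    if pad_samples >= series.size:
        raise ValueError("pad_samples must be smaller than the series length")
    if pad_samples == 0:
        return series.copy()
    return np.pad(series, pad_samples, mode="reflect")


def _fir_taps(trans_bw: float, fs: float) -> int:
    n = int(np.ceil(_TAPS_FACTOR * fs / trans_bw))
    return n + 1 if n % 2 == 0 else n


@lru_cache(maxsize=32)
def _band_kernels(name: str, fs: float) -> tuple[np.ndarray, np.ndarray]:
    spec = band_spec(name)
    hp_cut = spec.low - spec.trans_low / 2.0
    lp_cut = spec.high + spec.trans_high / 2.0
    if hp_cut <= 0:
        raise ValueError(f"band {name!r}: high-pass cutoff not positive")
    if lp_cut >= fs / 2.0:
        raise ValueError(f"band {name!r}: low-pass cutoff above Nyquist")
    hp = firwin(_fir_taps(spec.trans_low, fs), hp_cut,
                window="hamming", pass_zero=False, fs=fs)
    lp = firwin(_fir_taps(spec.trans_high, fs), lp_cut,
                window="hamming", pass_zero=True, fs=fs)
    return hp, lp


def bandpass(series: np.ndarray, band: BandSpec | str, fs: float) -> np.ndarray:
    """Zero-phase band-pass: high-pass then low-pass windowed-sinc kernels.

    Each kernel is linear-phase (symmetric, odd length) and applied in a
    single pass with the group delay compensated, so the -6 dB points sit
    exactly at the centres of the transition bands.
    """
    name = band if isinstance(band, str) else band.name
    if name == "raw":
        raise ValueError("bandpass is undefined for the raw band")
    hp, lp = _band_kernels(name, float(fs))
    series = np.asarray(series, dtype=float)
    out = fftconvolve(series, hp, mode="same")
    return fftconvolve(out, lp, mode="same")


def block_average(series: np.ndarray, block: int = 20) -> np.ndarray:
    """Mean of consecutive non-overlapping blocks; trailing partial dropped."""
    series = np.asarray(series, dtype=float)
    if block < 1:
        raise ValueError("block must be >= 1")
    n_blocks = series.size // block
    if n_blocks == 0:
        raise ValueError("block larger than the series")
    return series[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)


def crop_window(series: np.ndarray, times: np.ndarray,
                t_start: float = -1.0, t_end: float = 2.0) -> np.ndarray:
    """Keep samples whose onset-relative time lies in [t_start, t_end)."""
    series = np.asarray(series)
    if t_start >= t_end:
        raise ValueError("empty crop window")
    if t_start < times[0] - 1e-9 or t_end > times[-1] + (times[1] - times[0]) + 1e-9:
        raise ValueError("crop window outside the epoch span")
    mask = (times >= t_start - 1e-9) & (times < t_end - 1e-9)
    return series[mask]


@dataclass
class BandSeriesGrid:
    """Block-averaged series for one subject.

    ``values`` has shape (n_channels, n_bands, n_conditions, n_points);
    ``step`` is the block duration in seconds (0.08 by default).
    """

    channels: tuple[str, ...]
    bands: tuple[str, ...]
    conditions: tuple[str, ...]
    values: np.ndarray
    step: float

    def series(self, channel: str, band: str, condition: str) -> np.ndarray:
        return self.values[self.channels.index(channel),
                           self.bands.index(band),
                           self.conditions.index(condition)]


def preprocess_subject(epochs: EpochSet, config: PipelineConfig,
                       trial_indices: np.ndarray | None = None) -> BandSeriesGrid:
    """Full preprocessing chain for one subject.

    ``trial_indices`` restricts the average to a trial subset (ensemble
    subgroups); ``config.n_trials`` keeps the first N trials per condition.
    """
    fs = 1.0 / (epochs.times[1] - epochs.times[0])
    pad = int(round(2.0 * fs))
    t0, t1 = config.crop
    n_points = int(np.floor((t1 - t0) * fs)) // config.block
    out = np.empty((len(config.channels), len(config.bands),
                    len(config.conditions), n_points))
    padded_times = epochs.times[0] - pad / fs + np.arange(
        epochs.times.size + 2 * pad) / fs
    for chi, ch in enumerate(config.channels):
        for ci, cond in enumerate(config.conditions):
            trials = epochs.get(ch, cond)
            if config.n_trials is not None:
                trials = trials[: config.n_trials]
            if trial_indices is not None:
                trials = trials[trial_indices]
            avg = average_trials(trials)
            padded = mirror_pad(avg, pad)
            for bi, band in enumerate(config.bands):
                filtered = padded if band == "raw" else bandpass(padded, band, fs)
                cropped = crop_window(filtered, padded_times, t0, t1)
                out[chi, bi, ci] = block_average(cropped, config.block)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite values after preprocessing")
    return BandSeriesGrid(channels=tuple(config.channels),
                          bands=tuple(config.bands),
                          conditions=tuple(config.conditions),
                          values=out, step=config.block / fs)


def band_series_frame(grid: BandSeriesGrid, subject_id: str):
    """Tidy (subject, channel, band, condition, time_index, value) table."""
    import pandas as pd

    records = []
    for chi, ch in enumerate(grid.channels):
        for bi, band in enumerate(grid.bands):
            for ci, cond in enumerate(grid.conditions):
                for ti, v in enumerate(grid.values[chi, bi, ci]):
                    records.append((subject_id, ch, band, cond, ti, v))
    return pd.DataFrame(records, columns=[
        "subject", "channel", "band", "condition", "time_index", "value"])
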