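"""Region-of-interest detection: band-pass filter plus adaptive threshold.

An insect transit shows up as a sudden drop in detector voltage lasting
milliseconds to a second. The raw record is band-pass filtered (default
10–900 Hz) to strip slow baseline drift and high-frequency noise, negated
so that voltage drops become positive extinction excursions, lightly
smoothed, and compared against an adaptive threshold — a 5 s sliding mean
plus 2.5 sliding standard deviations. Runs above threshold longer than
0.1 ms are marked as regions of interest; nearby runs are merged because
one insect's wing glints cross the threshold many times per transit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .records import RunConfig, SignalRecord

__all__ = [
    "RegionOfInterest",
    "bandpass",
    "moving_average",
    "sliding_mean_std",
    "adaptive_threshold",
    "extinction_series",
    "find_regions",
    "extract_raw_slice",
]


@dataclass(frozen=True)
class RegionOfInterest:
    """One detected above-threshold excursion, in raw-signal samples.

    ``start_index``/``end_index`` bound the merged above-threshold run,
    half-open. ``peak_amplitude`` is the maximum of the filtered
    extinction series inside the region, in mV.
    """

    start_index: int
    end_index: int
    peak_amplitude: float

    def __post_init__(self) -> None:
        if self.end_index <= self.start_index:
            raise ValueError("end_index must exceed start_index")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index

    def duration(self, sample_rate: float) -> float:
        return self.n_samples / sample_rate


def bandpass(
    record: SignalRecord | np.ndarray,
    low: float,
    high: float,
    sample_rate: float | None = None,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a voltage series.

    Applied forward-backward (no group delay), so a transient keeps its
    position in time; DC and drift below ``low`` are rejected.
    """
    if isinstance(record, SignalRecord):
        x, fs = record.samples, record.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for bare arrays")
        x, fs = np.asarray(record, dtype=float), sample_rate
    if not (0 < low < high < fs / 2):
        raise ValueError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist={fs / 2}"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average over ``n`` samples, edges use available support."""
    if n <= 1:
        return np.asarray(x, dtype=float)
    return _sliding_sums(np.asarray(x, dtype=float), n)[0]


def _sliding_sums(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered sliding mean and count with edge clipping, via cumulative sums."""
    size = x.size
    half = n // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(size)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx - half + n, size)
    counts = (hi - lo).astype(float)
    means = (cs[hi] - cs[lo]) / counts
    return means, counts


def sliding_mean_std(x: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered sliding mean and population std over ``n``-sample windows.

    Windows are clipped at the record edges (shorter effective windows
    there). Implemented with cumulative sums: O(len(x)), exact up to
    floating-point rounding.
    """
    x = np.asarray(x, dtype=float)
    if n < 2:
        raise ValueError("window must span at least 2 samples")
    if n > x.size:
        raise ValueError(f"window of {n} samples exceeds record length {x.size}")
    mean, counts = _sliding_sums(x, n)
    # second moment around 0; subtracting the running mean keeps it stable
    offset = x.mean()
    mean2, _ = _sliding_sums((x - offset) ** 2, n)
    var = mean2 - (mean - offset) ** 2
    np.clip(var, 0.0, None, out=var)
    return mean, np.sqrt(var)


def adaptive_threshold(
    extinction: np.ndarray,
    window_s: float,
    multiplier: float,
    sample_rate: float,
) -> np.ndarray:
    """Sliding mean + multiplier × sliding std of the extinction series.

    Tracks slow residual drift without chasing the fast excursions that
    are the events themselves.
    """
    n = int(round(window_s * sample_rate))
    if n < 2:
        raise ValueError("threshold window must span at least 2 samples")
    mean, std = sliding_mean_std(np.asarray(extinction, dtype=float), n)
    return mean + multiplier * std


def extinction_series(record: SignalRecord, config: RunConfig) -> np.ndarray:
    """Filtered, negated, smoothed series on which detection operates.

    Insects *decrease* the voltage, so the band-passed record is negated
    to make transits positive excursions, then smoothed with a short
    moving average (default 1 ms) to suppress single-sample noise spikes.
    """
    filt = bandpass(record, config.band_low_hz, config.band_high_hz)
    ext = -filt
    n_smooth = max(int(round(config.smoothing_s * record.sample_rate)), 1)
    return moving_average(ext, n_smooth)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) bounds of contiguous True runs."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(
    runs: list[tuple[int, int]], max_gap: int
) -> list[tuple[int, int]]:
    if not runs:
        return []
    merged = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < max_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def find_regions(
    record: SignalRecord, config: RunConfig
) -> list[RegionOfInterest]:
    """Detect candidate transit regions in a raw record.

    A sample run qualifies when the extinction series stays above the
    adaptive threshold for more than the minimum crossing duration
    (default 0.1 ms); qualifying runs separated by less than the merge
    gap (default 20 ms) are fused into one region. Returns regions sorted
    by start index; an empty list on a quiet record.
    """
    fs = record.sample_rate
    config.validate_for_rate(fs)
    ext = extinction_series(record, config)
    thr = adaptive_threshold(
        ext, config.threshold_window_s, config.threshold_multiplier, fs
    )
    runs = _runs_above(ext > thr)
    min_samples = config.min_crossing_s * fs  # strict: duration must exceed this
    runs = [(s, e) for s, e in runs if (e - s) > min_samples]
    merged = _merge_runs(runs, max_gap=int(round(config.merge_gap_s * fs)))
    return [
        RegionOfInterest(
            start_index=s,
            end_index=e,
            peak_amplitude=float(ext[s:e].max()),
        )
        for s, e in merged
    ]


def extract_raw_slice(
    record: SignalRecord, region: RegionOfInterest, pad_s: float
) -> tuple[np.ndarray, int]:
    """Raw samples for a region with symmetric context padding.

    Returns ``(slice, offset)`` where ``offset`` is the index of the
    slice's first sample in the full record; padding is clipped at the
    record edges.
    """
    pad = int(round(pad_s * record.sample_rate))
    lo = max(region.start_index - pad, 0)
    hi = min(region.end_index + pad, len(record))
    return record.samples[lo:hi], lo
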