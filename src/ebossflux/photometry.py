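"""Event photometry: baseline, body minimum, extinction cross section,
transit time and shape kurtosis.

Under the flat-top beam approximation the fractional signal drop maps
linearly onto occluded beam area, so the body extinction cross section of
an insect is

    sigma_B = sigma_pv * (I0 - IB) / I0

with I0 the baseline intensity before the transit, IB the minimum of the
body component while the insect sits in the beam centre, and sigma_pv
the probe-volume cross section. Transit time is measured as the full
width of the body extinction profile at a fixed fraction (default 10%)
of its peak; the kurtosis of the profile, read as an unnormalised
density over time, summarises the event shape (3 for a Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ProbeGeometry

__all__ = [
    "EventPhotometry",
    "estimate_baseline",
    "to_extinction_cross_section",
    "body_minimum",
    "transit_time",
    "event_kurtosis",
    "measure_event",
]


@dataclass
class EventPhotometry:
    """Physical quantities of one transit event."""

    i0: float  # baseline intensity, mV
    ib: float  # body-minimum intensity, mV
    sigma_b: float  # body extinction cross section, mm²
    transit_time: float  # s
    kurtosis: float
    flags: tuple = ()

    def __post_init__(self) -> None:
        if not (0 < self.ib <= self.i0):
            raise ValueError("need 0 < ib <= i0")
        if self.transit_time <= 0:
            raise ValueError("transit_time must be positive")

    @property
    def extinction_fraction(self) -> float:
        return (self.i0 - self.ib) / self.i0


def estimate_baseline(
    raw_slice: np.ndarray,
    event_start: int,
    event_end: int,
    *,
    window: int | None = None,
) -> tuple[float, bool]:
    """Robust baseline I0 from the pre-event context of a raw slice.

    ``event_start``/``event_end`` are slice-local indices bounding the
    event. Returns the median of up to ``window`` pre-event samples
    (defaults to all available context); when the event starts at the
    record edge and no pre-event context exists, the post-event context
    is used instead and the estimate is flagged.
    """
    x = np.asarray(raw_slice, dtype=float)
    if not (0 <= event_start < event_end <= x.size):
        raise ValueError("event bounds must lie within the slice")
    pre = x[:event_start]
    fallback = False
    if pre.size == 0:
        pre = x[event_end:]
        fallback = True
        if pre.size == 0:
            raise ValueError("no context available on either side of the event")
    if window is not None and pre.size > window:
        pre = pre[-window:] if not fallback else pre[:window]
    return float(np.median(pre)), fallback


def to_extinction_cross_section(
    i0: float, ib: float, geometry: ProbeGeometry
) -> float:
    """Body extinction cross section (mm²) from baseline and body minimum."""
    if ib > i0:
        raise ValueError(f"ib={ib} exceeds i0={i0}: negative extinction")
    if ib <= 0:
        raise ValueError("ib <= 0: full occlusion exceeds the flat-top model")
    return geometry.sigma_pv * (i0 - ib) / i0


def body_minimum(body_component: np.ndarray) -> float:
    """I_B: the minimum of the body component over the event, mV."""
    x = np.asarray(body_component, dtype=float)
    if x.size == 0:
        raise ValueError("empty body component")
    return float(x.min())


def transit_time(
    extinction_profile: np.ndarray,
    sample_rate: float,
    *,
    width_fraction: float = 0.1,
    peak_index: int | None = None,
) -> tuple[float, bool]:
    """Transit duration: full width of the profile at a fraction of peak.

    The width is that of the contiguous above-level run containing the
    peak (``peak_index`` lets the caller anchor the measurement on a
    specific event when neighbouring events share the profile); crossing
    times on each flank are located by linear interpolation between
    samples. Returns ``(width_s, truncated)`` where ``truncated`` flags a
    run still above the level at either end of the profile's support
    (event clipped at the record edge); the width is then computed on the
    available support.
    """
    p = np.asarray(extinction_profile, dtype=float)
    if p.size < 2:
        raise ValueError("profile too short")
    if peak_index is None:
        peak_index = int(np.argmax(p))
    peak = p[peak_index]
    if peak <= 0:
        raise ValueError("profile has no positive peak")
    level = width_fraction * peak
    first, last, truncated = _level_run(p, level, peak_index)
    # interpolate the crossing on each flank (clipped at the support edges)
    if first > 0 and p[first] != p[first - 1]:
        lo = first - 1 + (level - p[first - 1]) / (p[first] - p[first - 1])
    else:
        lo = float(first)
    if last < p.size - 1 and p[last] != p[last + 1]:
        hi = last + (p[last] - level) / (p[last] - p[last + 1])
    else:
        hi = float(last)
    return float((hi - lo) / sample_rate), truncated


def _level_run(
    p: np.ndarray, level: float, peak_index: int
) -> tuple[int, int, bool]:
    """Contiguous above-level run containing the peak; flags edge clipping."""
    above = p >= level
    first = peak_index
    while first > 0 and above[first - 1]:
        first -= 1
    last = peak_index
    while last < p.size - 1 and above[last + 1]:
        last += 1
    truncated = bool(first == 0 and above[0]) or bool(
        last == p.size - 1 and above[-1]
    )
    return first, last, truncated


def event_kurtosis(extinction_profile: np.ndarray) -> float:
    """Pearson kurtosis of the event shape (Gaussian reference = 3).

    The profile is treated as an unnormalised density over the sample
    index: with weights w_i = profile (clipped at 0) over times t_i, the
    statistic is mu4 / mu2^2 of t under w. A rectangular profile gives
    9/5; two symmetric spikes give 1.
    """
    w = np.clip(np.asarray(extinction_profile, dtype=float), 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("profile must have positive mass")
    t = np.arange(w.size, dtype=float)
    mean = (w * t).sum() / total
    d = t - mean
    mu2 = (w * d**2).sum() / total
    mu4 = (w * d**4).sum() / total
    if mu2 == 0:
        raise ValueError("profile concentrated on one sample; kurtosis undefined")
    return float(mu4 / mu2**2)


def measure_event(
    raw_slice: np.ndarray,
    body_component: np.ndarray,
    event_start: int,
    event_end: int,
    sample_rate: float,
    geometry: ProbeGeometry,
    *,
    baseline_window: int | None = None,
    width_fraction: float = 0.1,
) -> EventPhotometry:
    """Full photometric measurement of one event.

    ``raw_slice`` is the padded raw extract, ``body_component`` its
    wing-free body envelope (same length), and ``event_start``/``event_end``
    the slice-local bounds of the detected region. The baseline is the
    median of the *far* half of the pre-event context (the near half can
    still sit in the raw envelope's tails, which the band-passed
    detection series does not show); the transit width and kurtosis are
    measured on the above-level run anchored at the event's own extinction
    peak, so a neighbouring event inside the padding does not leak in.
    """
    flags = []
    body = np.asarray(body_component, dtype=float)
    far_pre = event_start // 2 if baseline_window is None else baseline_window
    i0, used_post = estimate_baseline(
        raw_slice, min(far_pre, event_start), event_end
    )
    if used_post:
        flags.append("baseline_from_post_context")
    profile = np.clip((i0 - body) / i0, 0.0, None)
    if not profile[event_start:event_end].max() > 0:
        raise ValueError("no extinction inside the detected region")
    peak_index = event_start + int(np.argmax(profile[event_start:event_end]))

    ib = float(body[peak_index])
    ib = min(ib, i0)  # noise can push the body estimate above baseline
    if ib <= 0:
        raise ValueError("body minimum <= 0: occlusion exceeds the flat-top model")
    sigma_b = to_extinction_cross_section(i0, ib, geometry)

    dt, truncated = transit_time(
        profile, sample_rate, width_fraction=width_fraction, peak_index=peak_index
    )
    if truncated:
        flags.append("truncated_profile")
    # kurtosis over the event's own support: the above-level run extended
    # by one full width each side captures the Gaussian tails without
    # pulling in neighbouring events
    level = width_fraction * profile[peak_index]
    first, last, _ = _level_run(profile, level, peak_index)
    half = last - first + 1
    k_lo = max(first - half, 0)
    k_hi = min(last + half + 1, profile.size)
    kurt = event_kurtosis(profile[k_lo:k_hi])
    return EventPhotometry(
        i0=i0,
        ib=ib,
        sigma_b=sigma_b,
        transit_time=dt,
        kurtosis=kurt,
        flags=tuple(flags),
    )
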