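"""Transit-time-weighted volumetric biomass density and its aggregations.

Each insect event contributes its estimated mass weighted by the
fraction of the observation window it spent inside the probe volume;
normalising by the probed air volume gives the flying-insect biomass
density in mg/m³ over a window of length t_tot:

    rho_b = sum_n (dt_n / t_tot) * m_n / delta_V

The window length trades time resolution against statistical
uncertainty: minute-scale bins resolve diel activity but fluctuate,
day-scale bins are stable but average over the structure. Aggregation
helpers provide time-binned series, centred rolling means (e.g. a 2-week
rolling average of a daily series, or a 60-minute rolling average of a
minute series), diel (time-of-day) profiles, and event-distribution
summaries with the hard 10 ms transit-time cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DensitySeries",
    "biomass_density",
    "time_binned_density",
    "rolling_average",
    "diel_profile",
    "summarize_events",
]

_MASS_COL = {"wet": "mass_wet_mg", "dry": "mass_dry_mg"}


def _insect_mask(
    events: pd.DataFrame, min_transit: float | None
) -> pd.Series:
    mask = events["is_insect"].astype(bool)
    if min_transit is not None:
        mask &= events["transit_time_s"] >= min_transit
    return mask


def biomass_density(
    events: pd.DataFrame,
    t_tot: float,
    delta_v: float,
    basis: str = "dry",
    *,
    min_transit: float | None = None,
) -> float:
    """Biomass density (mg/m³) of an event set over a window of t_tot seconds.

    Only rows with ``is_insect`` true contribute; ``min_transit`` applies
    the hard transit-time cut-off to the sum as well (pass None to keep
    short events). Zero events give exactly 0.
    """
    if t_tot <= 0:
        raise ValueError("t_tot must be positive")
    if delta_v <= 0:
        raise ValueError("delta_v must be positive")
    if basis not in _MASS_COL:
        raise ValueError("basis must be 'wet' or 'dry'")
    if len(events) == 0:
        return 0.0
    sel = events[_insect_mask(events, min_transit)]
    weighted = (sel["transit_time_s"] / t_tot) * sel[_MASS_COL[basis]]
    return float(weighted.sum() / delta_v)


@dataclass
class DensitySeries:
    """Uniformly binned biomass-density time series."""

    bin_starts: pd.DatetimeIndex  # UTC
    t_tot: float  # bin length, s
    rho_b: np.ndarray  # mg/m³ per bin
    n_events: np.ndarray  # insect events per bin
    delta_v: float  # m³
    basis: str = "dry"

    def __post_init__(self) -> None:
        self.rho_b = np.asarray(self.rho_b, dtype=float)
        self.n_events = np.asarray(self.n_events, dtype=int)
        if np.any(self.rho_b < 0):
            raise ValueError("rho_b must be non-negative")
        if len(self.bin_starts) != self.rho_b.size:
            raise ValueError("bin_starts and rho_b length mismatch")

    def __len__(self) -> int:
        return self.rho_b.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_utc": self.bin_starts,
                "t_tot_s": self.t_tot,
                "n_events": self.n_events,
                "rho_b_mg_m3": self.rho_b,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def time_binned_density(
    events: pd.DataFrame,
    bin_s: float,
    delta_v: float,
    basis: str = "dry",
    *,
    span: tuple | None = None,
    min_transit: float | None = None,
    fractional: bool = False,
) -> DensitySeries:
    """Bin events into uniform windows and evaluate the density per bin.

    Events belong to the bin containing their start time; with
    ``fractional=True`` an event straddling bin edges is apportioned to
    each bin in proportion to the transit time it spends there. ``span``
    fixes the series extent as ``(start, end)`` timestamps; by default it
    covers the observed events, aligned to whole bins from the first
    event's bin.
    """
    if bin_s <= 0:
        raise ValueError("bin must be positive")
    if delta_v <= 0:
        raise ValueError("delta_v must be positive")
    times = pd.to_datetime(events["start_time_utc"], utc=True)
    if span is not None:
        t0 = pd.Timestamp(span[0]).tz_convert("UTC") if pd.Timestamp(span[0]).tzinfo else pd.Timestamp(span[0], tz="UTC")
        t1 = pd.Timestamp(span[1]).tz_convert("UTC") if pd.Timestamp(span[1]).tzinfo else pd.Timestamp(span[1], tz="UTC")
    elif len(events):
        t0 = times.min().floor(f"{int(bin_s)}s" if bin_s >= 1 else "s")
        t1 = times.max()
    else:
        raise ValueError("empty event table requires an explicit span")
    n_bins = max(int(np.ceil((t1 - t0).total_seconds() / bin_s)), 1)
    starts = t0 + pd.to_timedelta(np.arange(n_bins) * bin_s, unit="s")

    rho = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    if len(events):
        sel = events[_insect_mask(events, min_transit)]
        sel_times = pd.to_datetime(sel["start_time_utc"], utc=True)
        offsets = (sel_times - t0).dt.total_seconds().to_numpy()
        masses = sel[_MASS_COL[basis]].to_numpy(dtype=float)
        transits = sel["transit_time_s"].to_numpy(dtype=float)
        for off, m, dt in zip(offsets, masses, transits):
            if off < 0 or off >= n_bins * bin_s:
                continue
            b = int(off // bin_s)
            counts[b] += 1
            if not fractional:
                rho[b] += dt * m
            else:
                # spread transit time across the bins it overlaps
                lo, hi = off, off + dt
                b0, b1 = int(lo // bin_s), int(min(hi, n_bins * bin_s - 1e-12) // bin_s)
                for bb in range(b0, b1 + 1):
                    seg = min(hi, (bb + 1) * bin_s) - max(lo, bb * bin_s)
                    rho[bb] += seg * m
    rho /= bin_s * delta_v
    return DensitySeries(
        bin_starts=pd.DatetimeIndex(starts),
        t_tot=bin_s,
        rho_b=rho,
        n_events=counts,
        delta_v=delta_v,
        basis=basis,
    )


def rolling_average(series: DensitySeries, window: int) -> DensitySeries:
    """Centred unweighted moving mean over ``window`` bins.

    Edge bins average over the bins actually available, so a constant
    series is unchanged and window 1 is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    smoothed = (
        pd.Series(series.rho_b)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return DensitySeries(
        bin_starts=series.bin_starts,
        t_tot=series.t_tot,
        rho_b=smoothed,
        n_events=series.n_events.copy(),
        delta_v=series.delta_v,
        basis=series.basis,
    )


def diel_profile(series: DensitySeries) -> pd.DataFrame:
    """Average density per time-of-day slot across the days of a series.

    The slot width equals the series bin length (which must divide
    24 h evenly); returns columns ``seconds_of_day`` and ``rho_b_mg_m3``.
    """
    day = 86_400.0
    if series.t_tot > day or day % series.t_tot != 0:
        raise ValueError("bin length must evenly divide 24 h")
    sod = (
        series.bin_starts.hour * 3600
        + series.bin_starts.minute * 60
        + series.bin_starts.second
    ).to_numpy()
    df = pd.DataFrame({"seconds_of_day": sod, "rho_b_mg_m3": series.rho_b})
    prof = (
        df.groupby("seconds_of_day", as_index=False)["rho_b_mg_m3"]
        .mean()
        .sort_values("seconds_of_day", ignore_index=True)
    )
    return prof


def summarize_events(
    events: pd.DataFrame, min_transit: float = 10e-3
) -> dict:
    """Distribution summaries of the insect events in a table.

    Events with transit time below ``min_transit`` are removed before any
    statistic is computed (the hard cut-off). Returns means and medians
    of dry/wet mass, transit time, wingbeat frequency and kurtosis, the
    surviving event count, and the surviving per-event arrays for
    histogramming.
    """
    insects = events[events["is_insect"].astype(bool)]
    kept = insects[insects["transit_time_s"] >= min_transit]

    def _stats(col: str) -> dict:
        v = kept[col].dropna().to_numpy(dtype=float)
        if v.size == 0:
            return {"mean": float("nan"), "median": float("nan")}
        return {"mean": float(np.mean(v)), "median": float(np.median(v))}

    return {
        "n_events": int(len(kept)),
        "n_removed_short_transit": int(len(insects) - len(kept)),
        "mass_dry_mg": _stats("mass_dry_mg"),
        "mass_wet_mg": _stats("mass_wet_mg"),
        "transit_time_s": _stats("transit_time_s"),
        "wingbeat_hz": _stats("wingbeat_hz"),
        "kurtosis": _stats("kurtosis"),
        "arrays": {
            c: kept[c].to_numpy(dtype=float)
            for c in (
                "mass_dry_mg",
                "mass_wet_mg",
                "transit_time_s",
                "wingbeat_hz",
                "kurtosis",
            )
            if c in kept
        },
    }
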