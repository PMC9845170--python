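"""Transit-time-weighted biomass density and its aggregations."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

from ebossflux.density import (
    DensitySeries,
    biomass_density,
    diel_profile,
    rolling_average,
    summarize_events,
    time_binned_density,
)

T0 = datetime(2021, 7, 13, 0, 0, tzinfo=timezone.utc)


def events_frame(rows):
    """rows: (offset_s, transit_s, mass_dry, is_insect)"""
    return pd.DataFrame(
        {
            "start_time_utc": [T0 + timedelta(seconds=r[0]) for r in rows],
            "transit_time_s": [r[1] for r in rows],
            "mass_dry_mg": [r[2] for r in rows],
            "mass_wet_mg": [2.1 * r[2] for r in rows],
            "is_insect": [r[3] for r in rows],
        }
    )


class TestBiomassDensity:
    def test_no_events(self):
        assert biomass_density(events_frame([]), 10.0, 0.1466) == 0.0

    def test_single_event_arithmetic(self):
        """One event: dt=0.1 s, m=10 mg, t_tot=10 s, dV=0.1466 m³
        gives (0.1/10)*10/0.1466 = 0.6821 mg/m³."""
        ev = events_frame([(1.0, 0.1, 10.0, True)])
        rho = biomass_density(ev, 10.0, 0.1466)
        assert rho == pytest.approx(0.6821, abs=0.0001)

    def test_non_insects_do_not_contribute(self):
        ev = events_frame([(1.0, 0.1, 10.0, True), (2.0, 0.5, 99.0, False)])
        assert biomass_density(ev, 10.0, 0.1466) == pytest.approx(
            0.6821, abs=0.0001
        )

    def test_transit_cutoff_gates_the_sum(self):
        ev = events_frame([(1.0, 0.005, 10.0, True), (2.0, 0.1, 10.0, True)])
        with_cut = biomass_density(ev, 10.0, 0.1466, min_transit=0.010)
        without = biomass_density(ev, 10.0, 0.1466)
        assert with_cut == pytest.approx(0.6821, abs=0.0001)
        assert without > with_cut

    def test_invalid_parameters(self):
        ev = events_frame([(1.0, 0.1, 1.0, True)])
        with pytest.raises(ValueError):
            biomass_density(ev, 0.0, 0.1)
        with pytest.raises(ValueError):
            biomass_density(ev, 10.0, 0.0)
        with pytest.raises(ValueError):
            biomass_density(ev, 10.0, 0.1, basis="damp")

    def test_linearity_in_mass(self, rng):
        rows = [(float(o), 0.05, float(m), True) for o, m in zip(
            rng.uniform(0, 100, 30), rng.lognormal(1, 1, 30)
        )]
        ev = events_frame(rows)
        rho1 = biomass_density(ev, 100.0, 0.1466)
        ev3 = ev.copy()
        ev3["mass_dry_mg"] *= 3.0
        assert biomass_density(ev3, 100.0, 0.1466) == pytest.approx(3 * rho1)

    def test_never_negative(self, rng):
        rows = [
            (float(o), float(t), float(m), bool(i))
            for o, t, m, i in zip(
                rng.uniform(0, 50, 40),
                rng.uniform(0.01, 1, 40),
                rng.lognormal(0, 1, 40),
                rng.integers(0, 2, 40),
            )
        ]
        assert biomass_density(events_frame(rows), 50.0, 0.1466) >= 0.0


class TestTimeBinned:
    def test_single_bin_equals_whole_window(self):
        rows = [(float(o), 0.1, 5.0, True) for o in (10, 2000, 80_000)]
        ev = events_frame(rows)
        series = time_binned_density(
            ev, 86_400.0, 0.1466, span=(T0, T0 + timedelta(days=1))
        )
        assert len(series) == 1
        assert series.rho_b[0] == pytest.approx(
            biomass_density(ev, 86_400.0, 0.1466)
        )
        assert series.n_events[0] == 3

    def test_additivity_over_partition(self):
        """Density over a window equals the duration-weighted mean of the
        densities over any uniform partition of that window."""
        rng = np.random.default_rng(5)
        rows = [
            (float(o), float(t), float(m), True)
            for o, t, m in zip(
                rng.uniform(0, 3600, 200),
                rng.uniform(0.02, 0.9, 200),
                rng.lognormal(1, 1, 200),
            )
        ]
        ev = events_frame(rows)
        span = (T0, T0 + timedelta(seconds=3600))
        whole = time_binned_density(ev, 3600.0, 0.1466, span=span).rho_b[0]
        parts = time_binned_density(ev, 600.0, 0.1466, span=span).rho_b
        assert parts.mean() == pytest.approx(whole, rel=1e-9)

    def test_event_assigned_to_start_bin_by_default(self):
        # event starts at 59.9 s with a 0.5 s transit straddling the edge
        ev = events_frame([(59.9, 0.5, 6.0, True)])
        span = (T0, T0 + timedelta(seconds=120))
        series = time_binned_density(ev, 60.0, 0.1466, span=span)
        assert series.n_events.tolist() == [1, 0]
        assert series.rho_b[1] == 0.0

    def test_fractional_apportioning_option(self):
        ev = events_frame([(59.9, 0.5, 6.0, True)])
        span = (T0, T0 + timedelta(seconds=120))
        series = time_binned_density(
            ev, 60.0, 0.1466, span=span, fractional=True
        )
        total = series.rho_b.sum() * 60.0  # un-normalise the bin average
        expect = 0.5 * 6.0 / 0.1466
        assert total == pytest.approx(expect, rel=1e-9)
        assert series.rho_b[0] == pytest.approx(
            (0.1 * 6.0) / (60.0 * 0.1466), rel=1e-6
        )

    def test_variance_shrinks_with_bin_size(self):
        """Resolution/uncertainty trade-off: 1-min bins fluctuate more
        than 10-min bins for the same steady traffic."""
        rng = np.random.default_rng(9)
        n = rng.poisson(0.2 * 7200)
        rows = [
            (float(o), float(t), 3.0, True)
            for o, t in zip(
                rng.uniform(0, 7200, n), rng.uniform(0.05, 0.3, n)
            )
        ]
        ev = events_frame(rows)
        span = (T0, T0 + timedelta(seconds=7200))
        fine = time_binned_density(ev, 60.0, 0.1466, span=span).rho_b
        coarse = time_binned_density(ev, 600.0, 0.1466, span=span).rho_b
        assert fine.var() > coarse.var()


class TestRollingAverage:
    def _series(self, values):
        values = np.asarray(values, dtype=float)
        return DensitySeries(
            bin_starts=pd.DatetimeIndex(
                [T0 + timedelta(minutes=i) for i in range(len(values))]
            ),
            t_tot=60.0,
            rho_b=values,
            n_events=np.zeros(len(values), dtype=int),
            delta_v=0.1466,
        )

    def test_window_one_is_identity(self):
        s = self._series([1, 2, 3, 4])
        np.testing.assert_array_equal(rolling_average(s, 1).rho_b, s.rho_b)

    def test_constant_unchanged(self):
        s = self._series(np.full(20, 0.7))
        np.testing.assert_allclose(rolling_average(s, 7).rho_b, 0.7)

    def test_impulse_becomes_rectangle(self):
        values = np.zeros(21)
        values[10] = 1.0
        out = rolling_average(self._series(values), 5).rho_b
        # convolution oracle: centred box of height 1/5
        expect = np.convolve(values, np.ones(5) / 5, mode="same")
        np.testing.assert_allclose(out, expect)


class TestDielProfile:
    def _minute_series(self, days, values):
        n = days * 1440
        return DensitySeries(
            bin_starts=pd.DatetimeIndex(
                [T0 + timedelta(minutes=i) for i in range(n)]
            ),
            t_tot=60.0,
            rho_b=np.asarray(values, dtype=float),
            n_events=np.zeros(n, dtype=int),
            delta_v=0.1466,
        )

    def test_constant_traffic_flat_profile(self):
        s = self._minute_series(3, np.full(3 * 1440, 0.4))
        prof = diel_profile(s)
        assert len(prof) == 1440
        np.testing.assert_allclose(prof["rho_b_mg_m3"], 0.4)

    def test_one_day_input_is_identity(self):
        vals = np.arange(1440, dtype=float)
        s = self._minute_series(1, vals)
        prof = diel_profile(s)
        np.testing.assert_allclose(prof["rho_b_mg_m3"], vals)

    def test_dawn_dusk_peaks_recovered(self):
        """Two activity peaks injected at fixed times of day reappear at
        those times in the multi-day average."""
        minutes = np.arange(3 * 1440) % 1440
        vals = (
            0.1
            + np.exp(-0.5 * ((minutes - 330) / 40.0) ** 2)  # 05:30
            + np.exp(-0.5 * ((minutes - 1260) / 40.0) ** 2)  # 21:00
        )
        prof = diel_profile(self._minute_series(3, vals))
        rho = prof["rho_b_mg_m3"].to_numpy()
        sod = prof["seconds_of_day"].to_numpy()
        morning = sod[np.argmax(np.where(sod < 43_200, rho, -1))]
        evening = sod[np.argmax(np.where(sod >= 43_200, rho, -1))]
        assert abs(morning - 330 * 60) <= 600
        assert abs(evening - 1260 * 60) <= 600

    def test_bin_must_divide_day(self):
        s = DensitySeries(
            bin_starts=pd.DatetimeIndex([T0]),
            t_tot=7000.0,
            rho_b=np.array([1.0]),
            n_events=np.array([1]),
            delta_v=0.1466,
        )
        with pytest.raises(ValueError):
            diel_profile(s)


class TestSummaries:
    def test_hard_transit_cutoff_semantics(self):
        ev = events_frame(
            [(1.0, 0.005, 1.0, True), (2.0, 0.015, 3.0, True), (3.0, 0.020, 5.0, True)]
        )
        ev["wingbeat_hz"] = 100.0
        ev["kurtosis"] = 3.0
        summary = summarize_events(ev, min_transit=0.010)
        assert summary["n_events"] == 2
        assert summary["n_removed_short_transit"] == 1
        assert summary["transit_time_s"]["mean"] == pytest.approx(0.0175)

    def test_mean_median_values(self):
        ev = events_frame(
            [(1.0, 0.1, 1.0, True), (2.0, 0.1, 3.0, True), (3.0, 0.1, 100.0, True)]
        )
        ev["wingbeat_hz"] = 100.0
        ev["kurtosis"] = 3.0
        s = summarize_events(ev, min_transit=0.0)
        assert s["mass_dry_mg"]["mean"] == pytest.approx(34.667, abs=0.001)
        assert s["mass_dry_mg"]["median"] == pytest.approx(3.0)

    def test_heavy_tailed_mass_mean_exceeds_median(self, rng):
        """Log-normal-like mass mixtures give mean >> median, the shape
        seen in field mass distributions."""
        masses = rng.lognormal(1.2, 1.5, 500)
        ev = events_frame(
            [(float(i), 0.1, float(m), True) for i, m in enumerate(masses)]
        )
        ev["wingbeat_hz"] = 100.0
        ev["kurtosis"] = 3.0
        s = summarize_events(ev, min_transit=0.0)
        assert s["mass_dry_mg"]["mean"] > 2 * s["mass_dry_mg"]["median"]

    def test_series_frame_round_trip(self, tmp_path):
        s = DensitySeries(
            bin_starts=pd.DatetimeIndex([T0, T0 + timedelta(seconds=60)]),
            t_tot=60.0,
            rho_b=np.array([0.1, 0.2]),
            n_events=np.array([1, 2]),
            delta_v=0.1466,
        )
        path = tmp_path / "density.csv"
        s.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == [
            "bin_start_utc",
            "t_tot_s",
            "n_events",
            "rho_b_mg_m3",
        ]
        np.testing.assert_allclose(back["rho_b_mg_m3"], [0.1, 0.2])
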