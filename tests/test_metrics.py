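"""Cycle extraction, PV-loop stroke work and the per-cycle metric panel."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cvloop import cycle_metrics, ejection_fraction, extract_cycle, stroke_work


def _series(duration=20.0, dt=1e-3, **signals):
    t = np.arange(0.0, duration + dt / 2, dt)
    data = {"time_s": t}
    for name, value in signals.items():
        data[name] = value(t) if callable(value) else np.full_like(t, value)
    return pd.DataFrame(data)


class TestExtractCycle:
    def test_default_window_is_the_steady_state_cycle(self):
        df = _series(p_lv=1.0)
        cyc = extract_cycle(df)
        t = cyc["time_s"].to_numpy()
        assert t[0] == pytest.approx(18.6)
        assert t[-1] < 19.2
        assert len(cyc) == 600          # one 600 ms cycle at 1 kHz

    def test_window_beyond_series_end_rejected(self):
        df = _series(duration=10.0, p_lv=1.0)
        with pytest.raises(ValueError):
            extract_cycle(df, window_start=9.8, bcl_ms=600)

    def test_sample_count_matches_sampling_rate(self):
        df = _series(duration=5.0, dt=2e-3, p_lv=1.0)
        cyc = extract_cycle(df, window_start=1.0, bcl_ms=600)
        assert len(cyc) == 300


class TestStrokeWork:
    def test_isovolumic_trajectory_has_zero_area(self):
        p = np.linspace(0, 100, 50)
        v = np.full(50, 80.0)
        assert stroke_work(p, v) == pytest.approx(0.0, abs=1e-12)

    def test_rectangular_loop_area(self):
        p = np.array([0.0, 100.0, 100.0, 0.0])
        v = np.array([50.0, 50.0, 70.0, 70.0])
        assert stroke_work(p, v) == pytest.approx(2000.0)

    def test_orientation_and_rotation_invariance(self):
        rng = np.random.default_rng(3)
        theta = np.linspace(0, 2 * np.pi, 73, endpoint=False)
        p = 60 + 40 * np.sin(theta)
        v = 80 + 15 * np.cos(theta)
        base = stroke_work(p, v)
        assert stroke_work(p[::-1], v[::-1]) == pytest.approx(base, rel=1e-12)
        for _ in range(5):
            k = rng.integers(1, 72)
            assert stroke_work(np.roll(p, k), np.roll(v, k)) == pytest.approx(base, rel=1e-12)

    def test_matches_independent_polygon_area_oracle(self):
        """Shoelace result equals shapely's polygon area to 1e-9 on synthetic
        convex and star-shaped loops."""
        from shapely.geometry import Polygon
        rng = np.random.default_rng(12)
        for _ in range(10):
            n = int(rng.integers(8, 200))
            theta = np.sort(rng.uniform(0, 2 * np.pi, n))
            r = rng.uniform(5, 40) + rng.uniform(0, 4, n)
            v = 80 + r * np.cos(theta)
            p = 60 + r * np.sin(theta)
            oracle = Polygon(zip(v, p)).area
            assert stroke_work(p, v) == pytest.approx(oracle, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stroke_work([1, 2, 3], [1, 2])


class TestEjectionFraction:
    @pytest.mark.parametrize("edv, esv, expected", [
        (100.0, 80.0, 0.20),
        (120.0, 90.0, 0.25),
        (75.0, 75.0, 0.0),
    ])
    def test_reference_values(self, edv, esv, expected):
        assert ejection_fraction(edv, esv) == pytest.approx(expected)

    def test_preconditions_enforced(self):
        with pytest.raises(ValueError):
            ejection_fraction(0.0, 0.0)
        with pytest.raises(ValueError):
            ejection_fraction(100.0, 120.0)


class TestCycleMetrics:
    @staticmethod
    def _cycle(**overrides):
        base = dict(p_lv=20.0, p_la=5.0, p_sa=60.0, v_lv=80.0,
                    atp_lv=5.0, q_mi=0.0, q_ao=0.0, q_pump_out=0.0)
        base.update(overrides)
        df = _series(duration=0.599, **base)
        return df

    def test_constant_series_gives_degenerate_panel(self):
        m = cycle_metrics(self._cycle())
        assert m.sv == 0.0
        assert m.ef == 0.0
        assert m.stroke_work == pytest.approx(0.0, abs=1e-9)
        assert m.lapp == pytest.approx(5.0)
        assert m.atp_mean == pytest.approx(5.0)

    def test_peak_of_injected_sinusoid_recovered(self):
        m = cycle_metrics(self._cycle(
            p_la=lambda t: 5 + 10 * np.sin(2 * np.pi * t / 0.6)))
        assert m.lapp == pytest.approx(15.0, rel=1e-4)

    def test_regurgitant_fractions(self):
        q = lambda t: np.where(t < 0.3, 100.0, -10.0)
        m = cycle_metrics(self._cycle(q_mi=q))
        assert m.regurgitant_fraction_mi == pytest.approx(
            (10 * 0.299) / (100 * 0.3), rel=1e-2)
        assert m.regurgitant_fraction_ao == 0.0

    def test_forward_only_flow_has_zero_regurgitant_fraction(self):
        m = cycle_metrics(self._cycle(q_mi=30.0, q_ao=30.0))
        assert m.regurgitant_fraction_mi == 0.0
        assert m.regurgitant_fraction_ao == 0.0

    def test_atp_mean_invariant_to_resampling_density(self):
        f = lambda t: 2.0 + np.sin(2 * np.pi * t / 0.6) ** 2
        coarse = cycle_metrics(self._cycle(atp_lv=f))
        df_fine = _series(duration=0.599, dt=1e-4, p_lv=20.0, p_la=5.0,
                          p_sa=60.0, v_lv=80.0, atp_lv=f, q_mi=0.0,
                          q_ao=0.0, q_pump_out=0.0)
        fine = cycle_metrics(df_fine)
        assert coarse.atp_mean == pytest.approx(fine.atp_mean, rel=1e-3)

    def test_empty_cycle_rejected(self):
        with pytest.raises(ValueError):
            cycle_metrics(self._cycle().iloc[0:0])
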