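"""TG/DTG/DTA processing and the R1/R2 stability indices."""

import numpy as np
import pytest
from scipy.stats import norm

from compostom.synthetic_data import (
    gaussian_area_in_region,
    gaussian_loss_in_region,
    make_maturation_thermogram,
    make_thermogram,
)
from compostom.thermogravimetry import (
    DEFAULT_P1,
    DEFAULT_P2,
    ThermalRegion,
    Thermogram,
    compute_dtg,
    detect_dtg_peaks,
    dta_peak_area,
    read_thermogram,
    region_mass_loss,
    thermal_indices,
)


def _linear_gram(slope=-0.1):
    T = np.arange(25.0, 651.0, 1.0)
    mass = 100.0 + slope * (T - 25.0)
    mass = np.clip(mass, 1.0, 100.0)
    return Thermogram(T, mass, np.zeros_like(T))


class TestComputeDtg:
    def test_linear_ramp_constant_derivative(self):
        T = np.arange(25.0, 651.0, 1.0)
        mass = 100.0 - 0.1 * (T - 25.0)
        dtg = compute_dtg(Thermogram(T, mass, np.zeros_like(T)))
        assert dtg == pytest.approx(np.full_like(T, 0.1), abs=1e-9)

    def test_constant_mass_zero_dtg(self):
        T = np.arange(25.0, 651.0, 1.0)
        dtg = compute_dtg(Thermogram(T, np.full_like(T, 80.0), np.zeros_like(T)))
        assert np.max(np.abs(dtg)) < 1e-12

    def test_gaussian_event_center_and_area(self):
        gram, _ = make_thermogram([(320.0, 25.0, 30.0)], [])
        dtg = compute_dtg(gram)
        T = gram.temperature
        assert T[np.argmax(dtg)] == pytest.approx(320.0, abs=2.0)
        area = np.trapezoid(dtg, T)
        assert area == pytest.approx(30.0, rel=0.01)

    def test_derivative_integral_roundtrip(self):
        gram, _ = make_thermogram(
            [(300.0, 20.0, 28.0), (350.0, 18.0, 22.0), (475.0, 16.0, 20.0)], [])
        dtg = compute_dtg(gram)
        T = gram.temperature
        for lo, hi in ((200.0, 420.0), (420.0, 560.0), (150.0, 600.0)):
            m = (T >= lo) & (T <= hi)
            recon = np.trapezoid(dtg[m], T[m])
            direct = np.interp(lo, T, gram.mass) - np.interp(hi, T, gram.mass)
            assert recon == pytest.approx(direct, rel=0.01, abs=0.05)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError, match="window"):
            compute_dtg(_linear_gram(), smooth_window=0.5)


class TestPeakDetection:
    def test_two_gaussians_found(self):
        gram, _ = make_thermogram([(300.0, 18.0, 25.0), (480.0, 15.0, 18.0)], [])
        dtg = compute_dtg(gram)
        peaks = detect_dtg_peaks(gram.temperature, dtg,
                                 [ThermalRegion("P1", 250, 400), ThermalRegion("P2", 450, 520)])
        assert len(peaks) == 2
        assert peaks[0][1] == pytest.approx(300.0, abs=2.0)
        assert peaks[1][1] == pytest.approx(480.0, abs=2.0)

    def test_flat_trace_empty(self):
        T = np.arange(25.0, 651.0, 1.0)
        assert detect_dtg_peaks(T, np.zeros_like(T), [DEFAULT_P1]) == []

    def test_three_gaussians_assigned_to_windows(self):
        gram, _ = make_thermogram(
            [(280.0, 15.0, 18.0), (360.0, 15.0, 18.0), (480.0, 12.0, 15.0)], [])
        dtg = compute_dtg(gram)
        peaks = detect_dtg_peaks(gram.temperature, dtg,
                                 [ThermalRegion("W1", 250, 400), ThermalRegion("W2", 450, 500)])
        w1 = [p for p in peaks if p[0] == "W1"]
        w2 = [p for p in peaks if p[0] == "W2"]
        assert sorted(round(p[1]) for p in w1) == pytest.approx([280, 360], abs=2)
        assert len(w2) == 1 and w2[0][1] == pytest.approx(480, abs=2)

    def test_empty_window_warns(self):
        gram, _ = make_thermogram([(300.0, 18.0, 25.0)], [])
        dtg = compute_dtg(gram)
        with pytest.warns(UserWarning, match="no DTG peak"):
            detect_dtg_peaks(gram.temperature, dtg, [ThermalRegion("P2", 450, 520)])


class TestRegionMassLoss:
    def test_single_sigmoid_loss(self):
        gram, truth = make_thermogram([(320.0, 25.0, 30.0)], [])
        got = region_mass_loss(gram, ThermalRegion("P1", 250, 400))
        want = gaussian_loss_in_region(truth["components"], 250, 400)
        assert got == pytest.approx(want, abs=1e-6)
        assert got == pytest.approx(30.0, abs=0.5)

    def test_plateau_is_zero(self):
        gram, _ = make_thermogram([(320.0, 15.0, 30.0)], [])
        assert region_mass_loss(gram, ThermalRegion("Q", 500, 600)) == pytest.approx(0.0, abs=1e-9)

    def test_full_span(self):
        gram, truth = make_thermogram(
            [(300.0, 20.0, 40.0), (480.0, 15.0, 30.0)], [])
        got = region_mass_loss(gram, ThermalRegion("F", 150, 600))
        assert got == pytest.approx(70.0, abs=0.5)

    def test_additive_over_adjacent_regions(self):
        gram, _ = make_thermogram([(320.0, 30.0, 35.0), (470.0, 20.0, 20.0)], [])
        full = region_mass_loss(gram, ThermalRegion("F", 200, 600))
        left = region_mass_loss(gram, ThermalRegion("L", 200, 411.3))
        right = region_mass_loss(gram, ThermalRegion("R", 411.3, 600))
        assert left + right == pytest.approx(full, abs=1e-12)

    def test_region_outside_grid_rejected(self):
        gram, _ = make_thermogram([(320.0, 25.0, 30.0)], [], temp_range=(25.0, 610.0))
        with pytest.raises(ValueError, match="outside"):
            region_mass_loss(gram, ThermalRegion("X", 600.0, 649.0))


class TestDtaPeakArea:
    def test_gaussian_on_zero_baseline(self):
        gram, _ = make_thermogram([], [(320.0, 20.0, 500.0)])
        got = dta_peak_area(gram, ThermalRegion("P1", 250, 400))
        assert got == pytest.approx(500.0, rel=0.01)

    def test_zero_heat_flow(self):
        gram, _ = make_thermogram([(320.0, 25.0, 30.0)], [])
        assert dta_peak_area(gram, DEFAULT_P1) == pytest.approx(0.0, abs=1e-9)

    def test_sloped_baseline_corrected(self):
        gram, _ = make_thermogram([], [(320.0, 18.0, 500.0)], drift=0.01)
        got = dta_peak_area(gram, ThermalRegion("P1", 250, 400))
        assert got == pytest.approx(500.0, rel=0.02)

    def test_constant_offset_invariance(self):
        gram, _ = make_thermogram([], [(320.0, 18.0, 400.0)])
        shifted = Thermogram(gram.temperature, gram.mass, gram.heat_flow + 7.5)
        a0 = dta_peak_area(gram, DEFAULT_P1)
        a1 = dta_peak_area(shifted, DEFAULT_P1)
        assert a1 == pytest.approx(a0, abs=1e-9)

    def test_horizontal_min_baseline(self):
        gram, _ = make_thermogram([], [(320.0, 18.0, 400.0)])
        a = dta_peak_area(gram, DEFAULT_P1, baseline="horizontal_min")
        assert a == pytest.approx(400.0, rel=0.05)


class TestThermalIndices:
    def test_reported_ratio_examples(self):
        # ratios recomputed from the example table's printed P1/P2 values
        assert 19.8 / 51.9 == pytest.approx(0.38, abs=0.005)
        assert 1425.0 / 891.0 == pytest.approx(1.60, abs=0.005)

    def test_assembles_consistent_ratios(self):
        gram, truth = make_maturation_thermogram(0.5)
        idx = thermal_indices(gram)
        assert idx.r1 == pytest.approx(idx.p2_mass_loss / idx.p1_mass_loss, rel=1e-12)
        assert idx.r2 == pytest.approx(idx.p2_area / idx.p1_area, rel=1e-12)
        want_r1 = (gaussian_loss_in_region(truth["components"], 400, 580)
                   / gaussian_loss_in_region(truth["components"], 250, 400))
        assert idx.r1 == pytest.approx(want_r1, rel=0.01)

    def test_equal_regions_symmetry(self):
        # mirror-symmetric signal about 400 °C: equal losses/areas either side
        gram, _ = make_thermogram([(350.0, 15.0, 20.0), (450.0, 15.0, 20.0)],
                                  [(350.0, 15.0, 300.0), (450.0, 15.0, 300.0)])
        idx = thermal_indices(gram, ThermalRegion("P1", 250, 400), ThermalRegion("P2", 400, 550))
        assert idx.r1 == pytest.approx(1.0, abs=0.01)
        assert idx.r2 == pytest.approx(1.0, abs=0.01)

    def test_maturation_sequence_monotonic(self):
        stages = [0.0, 0.25, 0.5, 0.75, 1.0]
        r1s, r2s = [], []
        for s in stages:
            idx = thermal_indices(make_maturation_thermogram(s)[0])
            r1s.append(idx.r1)
            r2s.append(idx.r2)
        assert np.all(np.diff(r1s) > 0)
        assert np.all(np.diff(r2s) > 0)

    def test_zero_p1_loss_raises(self):
        gram, _ = make_thermogram([(550.0, 10.0, 20.0)], [(550.0, 10.0, 100.0)])
        with pytest.raises(ZeroDivisionError):
            thermal_indices(gram)


def test_read_thermogram_normalises_mg(tmp_path):
    gram, _ = make_thermogram([(320.0, 25.0, 30.0)], [(320.0, 25.0, 100.0)])
    p = tmp_path / "tg.csv"
    import pandas as pd
    pd.DataFrame({"temperature_c": gram.temperature,
                  "mass_mg": gram.mass * 0.05,  # absolute mg, 5 mg sample
                  "heat_flow": gram.heat_flow}).to_csv(p, index=False)
    back = read_thermogram(p)
    assert back.mass[0] == pytest.approx(100.0)
    assert region_mass_loss(back, DEFAULT_P1) == pytest.approx(
        region_mass_loss(gram, DEFAULT_P1), rel=1e-9)


def test_thermogram_validation():
    T = np.arange(25.0, 651.0, 1.0)
    with pytest.raises(ValueError, match="increasing"):
        Thermogram(T[::-1], np.full_like(T, 50.0), np.zeros_like(T))
    with pytest.raises(ValueError, match="span"):
        Thermogram(np.arange(200.0, 400.0, 1.0), np.full(200, 50.0), np.zeros(200))
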