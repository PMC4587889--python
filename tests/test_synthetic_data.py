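"""Generator determinism, ground-truth consistency and scenario ordering."""

import json

import numpy as np
import pytest

from compostom import temperature as temp
from compostom.kinetics import predict_om_loss
from compostom.synthetic_data import (
    PileScenario,
    SCENARIOS,
    make_ftir_spectrum,
    make_nmr_spectrum,
    make_om_loss_series,
    make_temperature_series,
    make_thermogram,
    write_fixture_set,
)


def _scenario(**kw):
    base = dict(pile_id="X", labile_fraction=0.4, recalcitrant_fraction=0.4,
                a_max_true=45.0, k_true=0.015, heating_amplitude=25.0)
    base.update(kw)
    return PileScenario(**base)


class TestScenarioValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fractions"):
            _scenario(labile_fraction=0.7, recalcitrant_fraction=0.5)

    def test_kinetic_bounds(self):
        with pytest.raises(ValueError):
            _scenario(a_max_true=0.0)
        with pytest.raises(ValueError):
            _scenario(k_true=-0.1)


class TestTemperatureGenerator:
    def test_zero_amplitude_pile_equals_ambient(self):
        sc = _scenario(heating_amplitude=0.0)
        series, truth = make_temperature_series(sc, days=40)
        assert np.allclose(series.pile_temp, series.ambient_temp)
        assert truth["exi_full"] == 0.0

    def test_noiseless_exi_matches_closed_form(self):
        series, truth = make_temperature_series(SCENARIOS["A"], days=90)
        exi = temp.exothermic_index(series, end_day=90)
        assert exi == pytest.approx(float(truth["daily_offsets"].sum()), abs=1e-9)

    def test_higher_labile_fraction_strictly_larger_exi(self):
        lo, _ = make_temperature_series(_scenario(labile_fraction=0.3), days=90)
        hi, t_hi = make_temperature_series(_scenario(labile_fraction=0.6,
                                                     recalcitrant_fraction=0.3), days=90)
        t_lo = make_temperature_series(_scenario(labile_fraction=0.3), days=90)[1]
        assert t_hi["exi_full"] > t_lo["exi_full"]

    def test_deterministic_under_seed(self):
        a1, _ = make_temperature_series(SCENARIOS["B"], seed=7, noise_sd=0.5)
        a2, _ = make_temperature_series(SCENARIOS["B"], seed=7, noise_sd=0.5)
        assert np.array_equal(a1.pile_temp, a2.pile_temp)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="30 days"):
            make_temperature_series(SCENARIOS["A"], days=10)


class TestOmLossGenerator:
    def test_zero_noise_is_exact_model(self):
        days = [0.0, 28.0, 105.0, 168.0]
        series, _ = make_om_loss_series(SCENARIOS["A"], days)
        want = predict_om_loss(49.6, 0.0131, np.array(days))
        assert np.allclose(series.losses, want)

    def test_same_seed_identical(self):
        days = list(np.linspace(0, 105, 16))
        s1, _ = make_om_loss_series(SCENARIOS["C"], days, noise_sd=2.0, seed=4)
        s2, _ = make_om_loss_series(SCENARIOS["C"], days, noise_sd=2.0, seed=4)
        assert np.array_equal(s1.losses, s2.losses)

    def test_losses_clipped_to_valid_range(self):
        days = list(np.linspace(0, 200, 12))
        s, _ = make_om_loss_series(SCENARIOS["B"], days, noise_sd=50.0, seed=1)
        assert np.all((s.losses >= 0) & (s.losses <= 100))


class TestThermogramGenerator:
    def test_no_components_flat_mass(self):
        gram, _ = make_thermogram([], [])
        assert np.allclose(gram.mass, 100.0)

    def test_total_loss_capped(self):
        with pytest.raises(ValueError, match="below 100"):
            make_thermogram([(300.0, 20.0, 60.0), (450.0, 20.0, 45.0)], [])

    def test_deterministic_under_seed(self):
        g1, _ = make_thermogram([(320.0, 25.0, 30.0)], [(320.0, 25.0, 400.0)],
                                noise_sd=0.05, seed=2)
        g2, _ = make_thermogram([(320.0, 25.0, 30.0)], [(320.0, 25.0, 400.0)],
                                noise_sd=0.05, seed=2)
        assert np.array_equal(g1.mass, g2.mass)
        assert np.array_equal(g1.heat_flow, g2.heat_flow)


class TestSpectrumGenerators:
    def test_ftir_truth_is_exact_ra_of_heights(self):
        heights = {1037.0: 2.0, 1384.0: 1.0, 875.0: 1.0}
        _, truth = make_ftir_spectrum(heights)
        assert truth["ra"][1037.0] == pytest.approx(50.0)
        assert truth["ratio_1037_1384"] == pytest.approx(2.0)

    def test_nmr_targets_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum to 100"):
            make_nmr_spectrum({"alkyl": 50.0, "O-alkyl": 40.0})

    def test_nmr_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            make_nmr_spectrum({"alkyl": 50.0, "bogus": 50.0})

    def test_same_seed_identical_spectra(self):
        h = {1037.0: 1.0, 1384.0: 0.5}
        s1, _ = make_ftir_spectrum(h, noise_sd=0.01, seed=3)
        s2, _ = make_ftir_spectrum(h, noise_sd=0.01, seed=3)
        assert np.array_equal(s1.y, s2.y)


class TestFixtureSet:
    def test_every_file_has_truth_entry(self, fixture_dir):
        truth = json.loads((fixture_dir / "truth.json").read_text())
        for f in fixture_dir.iterdir():
            stem = f.stem
            if f.suffix not in (".csv", ".jdx", ".tsv") or stem in ("truth", "chemical"):
                continue
            assert stem in truth, f"no truth entry for {f.name}"

    def test_fixture_set_deterministic(self, tmp_path):
        t1 = write_fixture_set(tmp_path / "a", seed=99)
        t2 = write_fixture_set(tmp_path / "b", seed=99)
        assert json.dumps(t1, sort_keys=True, default=str) == \
            json.dumps(t2, sort_keys=True, default=str)
        f1 = (tmp_path / "a" / "omloss_A.csv").read_bytes()
        f2 = (tmp_path / "b" / "omloss_A.csv").read_bytes()
        assert f1 == f2

    def test_exi_ordering_over_seed_sweep(self):
        """Grape-marc scenario (B) heats most for every seed; A ~ C."""
        for seed in range(20):
            exis = {}
            for pid, sc in SCENARIOS.items():
                series, _ = make_temperature_series(sc, days=110, seed=seed, noise_sd=0.3)
                end = temp.detect_bio_oxidative_end(series)
                exis[pid] = temp.exothermic_index(series, end if end is not None else 110)
            assert exis["B"] > exis["A"] and exis["B"] > exis["C"]
            assert abs(exis["A"] - exis["C"]) < 0.35 * exis["B"]
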