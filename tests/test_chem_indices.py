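"""Chemical humification/maturity index computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compostom.chem_indices import (
    AshPair,
    CompostSampleRecord,
    HumicFractionSet,
    MaturityThresholds,
    elemental_ratio,
    humification_index,
    humification_ratio,
    index_table,
    maturity_flags,
    om_loss,
    percent_decrease,
    percentage_humic_acids,
    polymerisation_rate,
    read_samples,
)


@pytest.mark.parametrize(
    "func, args, expected, tol",
    [
        (humification_ratio, (13.0, 100.0), 13.0, 1e-12),
        (humification_ratio, (0.0, 40.0), 0.0, 1e-12),
        # CT back-solved from the example table (Cext=3.54+2.98, HR=12.99)
        (humification_ratio, (6.52, 50.19), 12.99, 0.01),
        (humification_index, (2.98, 50.19), 5.94, 0.01),
        (humification_index, (0.0, 50.0), 0.0, 1e-12),
        (humification_index, (50.0, 50.0), 100.0, 1e-12),
        (percentage_humic_acids, (2.98, 6.52), 45.72, 0.05),
        (percentage_humic_acids, (1.0, 2.0), 50.0, 1e-12),
        (percentage_humic_acids, (1.43, 4.34), 32.97, 0.05),
        (polymerisation_rate, (2.98, 3.54), 0.84, 0.005),
        (polymerisation_rate, (1.43, 2.91), 0.49, 0.005),
        (polymerisation_rate, (0.0, 1.0), 0.0, 1e-12),
        (elemental_ratio, (3.14, 3.14 / 1.42), 1.42, 0.02),
        (elemental_ratio, (5.0, 5.0), 1.0, 1e-12),
        (elemental_ratio, (1.10, 2.62), 0.42, 0.01),
        (percent_decrease, (1.42, 0.42), 70.0, 0.5),
        (percent_decrease, (1.15, 0.31), 73.0, 0.5),
        (percent_decrease, (3.3, 3.3), 0.0, 1e-12),
    ],
)
def test_index_worked_examples(func, args, expected, tol):
    assert func(*args) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "func, args",
    [
        (humification_ratio, (5.0, 0.0)),
        (humification_ratio, (60.0, 50.0)),
        (humification_index, (5.0, -1.0)),
        (percentage_humic_acids, (1.0, 0.0)),
        (polymerisation_rate, (1.0, 0.0)),
        (elemental_ratio, (1.0, 0.0)),
        (percent_decrease, (0.0, 1.0)),
    ],
)
def test_domain_errors(func, args):
    with pytest.raises(ValueError):
        func(*args)


class TestOmLoss:
    def test_no_ash_enrichment_is_zero(self):
        assert om_loss(AshPair(10.0, 10.0)) == pytest.approx(0.0)

    def test_hand_evaluated_example(self):
        assert om_loss(AshPair(20.0, 40.0)) == pytest.approx(62.5)

    def test_ash_depletion_warns_and_is_negative(self):
        with pytest.warns(UserWarning, match="mass-balance"):
            assert om_loss(AshPair(30.0, 15.0)) < 0

    def test_invalid_ash_rejected(self):
        with pytest.raises(ValueError):
            AshPair(0.0, 50.0)
        with pytest.raises(ValueError):
            AshPair(50.0, 100.0)

    @given(
        x1=st.floats(1.0, 99.0),
        d=st.floats(0.1, 30.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_final_ash(self, x1, d):
        x2 = min(x1 + d, 99.5)
        if x2 <= x1:
            return
        assert om_loss(AshPair(x1, x2)) > om_loss(AshPair(x1, x1))

    @given(x=st.floats(0.5, 99.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identity_at_equal_ash(self, x):
        assert om_loss(AshPair(x, x)) == pytest.approx(0.0, abs=1e-9)


@given(
    cfa=st.floats(0.1, 10.0),
    cha=st.floats(0.1, 10.0),
    ct=st.floats(25.0, 60.0),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_pha_hr_hi_algebraic_identity(cfa, cha, ct):
    """Pha * HR / 100 == HI when Cext = Cfa + Cha (exact identity)."""
    fr = HumicFractionSet(cfa=cfa, cha=cha)
    hr = humification_ratio(fr.cext, ct)
    hi = humification_index(fr.cha, ct)
    pha = percentage_humic_acids(fr.cha, fr.cext)
    assert pha * hr / 100.0 == pytest.approx(hi, rel=1e-9)


@given(
    cfa=st.floats(0.5, 8.0),
    cha=st.floats(0.5, 8.0),
    ct=st.floats(30.0, 60.0),
    scale=st.floats(0.1, 10.0),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_scale_invariance(cfa, cha, ct, scale):
    """HR, HI, Pha and Cha/Cfa are unchanged by a common positive rescaling."""
    fr = HumicFractionSet(cfa=cfa, cha=cha)
    base = (
        humification_ratio(fr.cext, ct),
        humification_index(fr.cha, ct),
        percentage_humic_acids(fr.cha, fr.cext),
        polymerisation_rate(fr.cha, fr.cfa),
    )
    fr2 = HumicFractionSet(cfa=cfa * scale, cha=cha * scale)
    scaled = (
        humification_ratio(fr2.cext, ct * scale),
        humification_index(fr2.cha, ct * scale),
        percentage_humic_acids(fr2.cha, fr2.cext),
        polymerisation_rate(fr2.cha, fr2.cfa),
    )
    assert scaled == pytest.approx(base, rel=1e-9)


def test_humic_fraction_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        HumicFractionSet(cfa=2.0, cha=2.0, cext=5.0)
    fr = HumicFractionSet(cfa=2.0, cha=2.0, cext=4.03)
    assert fr.cext == pytest.approx(4.03)


class TestMaturityFlags:
    def _record(self, **kw):
        defaults = dict(pile_id="A", phase="maturity", day=168)
        defaults.update(kw)
        return CompostSampleRecord(**defaults)

    def test_all_mature(self):
        r = self._record(toc=38.4, tn=2.2, wsc=1.10, gi=78.2)
        flags = maturity_flags(r)
        assert flags == {"tocn_mature": True, "wsc_mature": True, "gi_nonphytotoxic": True}

    def test_missing_inputs_are_undetermined_not_false(self):
        flags = maturity_flags(self._record(), tocn=21.9)
        assert flags["tocn_mature"] is False
        assert flags["wsc_mature"] is None
        assert flags["gi_nonphytotoxic"] is None

    def test_wsc_boundary_inclusive(self):
        flags = maturity_flags(self._record(wsc=1.7))
        assert flags["wsc_mature"] is True

    def test_thresholds_configurable(self):
        flags = maturity_flags(self._record(wsc=1.7),
                               MaturityThresholds(wsc_max=1.5))
        assert flags["wsc_mature"] is False


def test_record_validation():
    with pytest.raises(ValueError, match="phase"):
        CompostSampleRecord("A", "cold", 0)
    with pytest.raises(ValueError, match="outside"):
        CompostSampleRecord("A", "initial", 0, toc=120.0)


def test_read_samples_and_index_table_roundtrip(tmp_path):
    src = tmp_path / "samples.csv"
    src.write_text(
        "pile_id,phase,day,toc,tn,wsc,cfa,cha,gi\n"
        "A,initial,0,48.41,2.211,3.14,3.54,2.98,\n"
        "A,maturity,168,45.57,2.619,1.10,1.24,1.16,78.2\n"
    )
    records = read_samples(src)
    assert len(records) == 2 and records[1].gi == 78.2
    table = index_table(records)
    row0 = table.iloc[0]
    assert row0["cha_cfa"] == pytest.approx(0.84, abs=0.005)
    assert row0["pha"] == pytest.approx(45.7, abs=0.1)
    assert row0["hr"] == pytest.approx(100 * 6.52 / 48.41, rel=1e-6)
    assert bool(table.iloc[1]["gi_nonphytotoxic"]) is True
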