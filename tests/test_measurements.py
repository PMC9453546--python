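"""Record types, per-record calculators and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrotraits import (GasExchangeRecord, PotWeightRecord,
                         WaterPotentialRecord, compute_gwc, compute_iwue,
                         compute_plc, compute_rwc, read_table, write_table)
from hydrotraits.errors import InvalidRecordError, SchemaError


def _pot(pot, dry=4.0, wet=6.0):
    return PotWeightRecord(plant_id="p1", day=1, pot=pot, pot_dry=dry, pot_wet=wet)


class TestGWC:
    @pytest.mark.parametrize("pot, expected", [
        (5.0, 50.0),    # midpoint of capacity
        (6.0, 100.0),   # at container capacity
        (4.0, 0.0),     # oven dry
    ])
    def test_closed_form(self, pot, expected):
        assert compute_gwc(_pot(pot)) == pytest.approx(expected, abs=1e-12)

    def test_above_capacity_kept_and_flagged(self):
        rec = _pot(6.2)
        assert compute_gwc(rec) > 100.0
        assert "gwc_above_capacity" in rec.flags

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidRecordError):
            PotWeightRecord("p1", 1, pot=5.0, pot_dry=6.0, pot_wet=6.0)

    @given(pot=st.floats(3.0, 7.0), dry=st.floats(2.0, 4.0),
           cap=st.floats(0.5, 4.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_in_pot(self, pot, dry, cap):
        """GWC is exactly 0 at the dry weight and 100 at capacity."""
        wet = dry + cap
        assert compute_gwc(_pot(dry, dry, wet)) == 0.0
        assert compute_gwc(_pot(wet, dry, wet)) == pytest.approx(100.0, abs=1e-9)


class TestPLC:
    @pytest.mark.parametrize("kh, kmax, expected", [
        (2.0, 2.0, 0.0), (1.0, 2.0, 50.0), (0.0, 2.0, 100.0)])
    def test_closed_form(self, kh, kmax, expected):
        assert compute_plc(kh, kmax) == pytest.approx(expected, abs=1e-12)

    def test_noisy_overshoot_clipped(self):
        assert compute_plc(2.1, 2.0) == 0.0

    def test_nonpositive_kmax_rejected(self):
        with pytest.raises(InvalidRecordError):
            compute_plc(1.0, 0.0)

    @given(frac=st.floats(0.0, 1.0), kmax=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, frac, kmax):
        """PLC plus the retained percentage always totals 100."""
        kh = frac * kmax
        assert compute_plc(kh, kmax) + 100.0 * kh / kmax == pytest.approx(100.0)


class TestIWUE:
    @pytest.mark.parametrize("a_n, e, expected", [
        (10.0, 5.0, 2.0), (0.0, 5.0, 0.0), (12.0, 4.8, 2.5)])
    def test_ratio(self, a_n, e, expected):
        assert compute_iwue(a_n, e) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_transpiration(self):
        with pytest.raises(InvalidRecordError):
            compute_iwue(10.0, 0.0)
        rec = GasExchangeRecord("p1", 1, a_n=10.0, gs=100.0, e=0.0)
        assert "nonpositive_transpiration" in rec.flags
        assert np.isnan(rec.iwue)

    def test_per_record_not_ratio_of_means(self):
        """The mean of individual ratios differs from the ratio of means."""
        recs = [GasExchangeRecord("p", 1, a_n=a, gs=1, e=e)
                for a, e in [(10.0, 5.0), (20.0, 4.0)]]
        per_record = np.mean([r.iwue for r in recs])
        ratio_of_means = np.mean([10, 20]) / np.mean([5, 4])
        assert per_record == pytest.approx(3.5)
        assert per_record != pytest.approx(ratio_of_means)


class TestRWC:
    def test_endpoints_and_swc(self):
        assert compute_rwc(0.6, 0.2, 0.6) == pytest.approx(100.0)
        assert compute_rwc(0.4, 0.2, 0.6) == pytest.approx(50.0)
        assert (0.6 - 0.2) / 0.2 == pytest.approx(2.0)  # SWC definition

    def test_fresh_below_dry_rejected(self):
        with pytest.raises(InvalidRecordError):
            compute_rwc(0.1, 0.2, 0.6)


class TestReadTable:
    def _write(self, tmp_path, text, name="t.csv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    def test_well_formed_water_potential(self, tmp_path):
        path = self._write(tmp_path,
            "plant_id,day,psi_pd,psi_min,cultivar,treatment\n"
            "a,1,-0.2,-1.0,cv,PD\na,2,-0.5,-1.4,cv,PD\nb,1,-0.3,-1.1,cv,PD\n")
        recs = read_table(path, "water_potential")
        assert len(recs) == 3
        assert all(isinstance(r, WaterPotentialRecord) for r in recs)

    def test_inconsistent_record_flagged_not_dropped(self, tmp_path):
        path = self._write(tmp_path,
            "plant_id,day,psi_pd,psi_min\na,1,-1.0,-0.5\n")
        # mixed use: psi_min above psi_pd is physically inconsistent
        recs = read_table(path, "water_potential")
        assert len(recs) == 1
        assert "psi_min_above_psi_pd" in recs[0].flags

    def test_empty_file(self, tmp_path):
        path = self._write(tmp_path, "")
        assert read_table(path, "water_potential") == []

    def test_all_positive_psi_auto_negated(self, tmp_path):
        path = self._write(tmp_path,
            "plant_id,day,psi_pd,psi_min\na,1,0.2,1.0\na,2,0.5,1.4\n")
        recs = read_table(path, "water_potential")
        assert recs[0].psi_pd == -0.2 and recs[0].psi_min == -1.0

    def test_mixed_signs_rejected(self, tmp_path):
        path = self._write(tmp_path,
            "plant_id,day,psi_pd,psi_min\na,1,-0.2,-1.0\na,2,0.5,-1.4\n")
        with pytest.raises(SchemaError):
            read_table(path, "water_potential")

    def test_unknown_column_rejected(self, tmp_path):
        path = self._write(tmp_path,
            "plant_id,day,psi_pd,psi_min,bogus\na,1,-0.2,-1.0,7\n")
        with pytest.raises(SchemaError, match="bogus"):
            read_table(path, "water_potential")

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = self._write(tmp_path,
            "plant_id,day,psi_pd,psi_min\na,1,-0.2,oops\n")
        with pytest.raises(SchemaError, match="psi_min"):
            read_table(path, "water_potential")

    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = [WaterPotentialRecord(f"p{i}", i, -float(rng.uniform(0, 3)),
                                     -float(rng.uniform(1, 4)), "cv", "PD")
                for i in range(20)]
        recs = [r for r in recs if not r.flags]
        path = tmp_path / "wp.csv"
        write_table(recs, path)
        back = read_table(path, "water_potential")
        for a, b in zip(recs, back):
            assert (a.psi_pd, a.psi_min) == (b.psi_pd, b.psi_min)
            assert (a.plant_id, a.day) == (b.plant_id, b.day)
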