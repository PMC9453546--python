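"""Pressure–volume trait extraction: TLP, π_o, ε, capacitance."""

import numpy as np
import pytest
from dataclasses import replace

from hydrotraits import (PVCurve, analyze_pv, compute_capacitance,
                         compute_elasticity, find_tlp, simulate_pv_curve)
from hydrotraits.errors import (InsufficientDataError, InvalidRecordError,
                                NoTurgorLossError)
from hydrotraits.measurements import MOLAR_MASS_WATER


class TestFindTLP:
    def test_ideal_curve_closed_forms(self, ideal_preset):
        """π_o=2, ε=10 ⇒ Ψ_TLP = −π_o·ε/(ε−π_o) = −2.5, RWC_TLP = 80%."""
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0)
        tlp = find_tlp(curve)
        assert tlp.psi_tlp == pytest.approx(-2.5, rel=0.005)
        assert tlp.rwc_tlp == pytest.approx(80.0, rel=0.005)
        assert tlp.pi_o == pytest.approx(2.0, rel=0.005)

    def test_rigid_wall_limit(self, ideal_preset):
        """As ε → ∞ the TLP approaches −π_o and RWC_TLP approaches 100%."""
        rigid = replace(ideal_preset, epsilon=400.0)
        curve = simulate_pv_curve(rigid, n_points=161, noise_sd=0.0,
                                  rwc_min=90.0)
        tlp = find_tlp(curve)
        assert tlp.psi_tlp == pytest.approx(-2.0, rel=0.02)
        assert tlp.rwc_tlp > 99.0

    def test_fully_linear_series_degenerate(self, ideal_preset):
        """A series entirely past turgor loss has no turgid phase."""
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0, n_points=30,
                                  rwc_min=60.0)
        keep = curve.rwc <= 79.0
        sub = PVCurve("tail-only", curve.psi[keep], curve.fresh_mass[keep],
                      curve.dry_mass, curve.sat_mass, curve.leaf_area)
        tlp = find_tlp(sub)
        assert tlp.degenerate
        assert tlp.tail_start == 0

    def test_tlp_magnitude_at_least_pi_o(self, ideal_preset):
        for seed in range(5):
            curve = simulate_pv_curve(ideal_preset, seed=seed, noise_sd=0.01)
            tlp = find_tlp(curve)
            assert abs(tlp.psi_tlp) >= tlp.pi_o * 0.995

    def test_invariant_to_mass_rescaling(self, ideal_preset):
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0)
        scaled = PVCurve("scaled", curve.psi, curve.fresh_mass * 3.7,
                         curve.dry_mass * 3.7, curve.sat_mass * 3.7,
                         curve.leaf_area)
        assert find_tlp(scaled).psi_tlp == pytest.approx(
            find_tlp(curve).psi_tlp, abs=1e-12)

    def test_too_few_points(self, ideal_preset):
        curve = simulate_pv_curve(ideal_preset, n_points=5, noise_sd=0.0)
        with pytest.raises(InsufficientDataError):
            find_tlp(curve)


class TestElasticity:
    def test_ideal_round_trip(self, ideal_preset):
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0)
        tlp = find_tlp(curve)
        assert compute_elasticity(curve, tlp) == pytest.approx(10.0, abs=1e-6)

    def test_noisy_recovery_within_ten_percent(self, ideal_preset):
        """ε recovered within 10% under 2% water-potential noise."""
        stiff = replace(ideal_preset, epsilon=12.91,
                        pi_o=2.01 * 12.91 / (12.91 + 2.01))
        errs = []
        for seed in range(10):
            curve = simulate_pv_curve(stiff, seed=seed, noise_sd=0.02)
            eps = compute_elasticity(curve, find_tlp(curve))
            errs.append(abs(eps - 12.91) / 12.91)
        assert np.median(errs) < 0.10

    def test_flat_turgor_flagged_nonphysical(self, ideal_preset, caplog):
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0)
        tlp = find_tlp(curve)
        # force a flat pressure component: psi equal to the osmotic line
        flat = PVCurve("flat", -ideal_preset.pi_o * 100.0 / curve.rwc,
                       curve.fresh_mass, curve.dry_mass, curve.sat_mass,
                       curve.leaf_area)
        eps = compute_elasticity(flat, tlp)
        assert eps == pytest.approx(0.0, abs=1e-9)


class TestCapacitance:
    def test_unit_arithmetic(self, ideal_preset):
        """slope 0.05 MPa⁻¹ × 0.4 g water / (18.015 g mol⁻¹ × 0.001 m²)."""
        expected = 0.05 * 0.4 / (MOLAR_MASS_WATER * 0.001)
        assert expected == pytest.approx(1.110, abs=5e-4)

    def test_doubling_area_halves_cft(self, ideal_preset):
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0)
        tlp = find_tlp(curve)
        c1 = compute_capacitance(curve, tlp)
        big = PVCurve("big", curve.psi, curve.fresh_mass, curve.dry_mass,
                      curve.sat_mass, curve.leaf_area * 2)
        assert compute_capacitance(big, find_tlp(big)) == pytest.approx(c1 / 2)

    def test_missing_area_raises_with_unnormalized_value(self, ideal_preset):
        curve = simulate_pv_curve(ideal_preset, noise_sd=0.0)
        curve.leaf_area = None
        with pytest.raises(InvalidRecordError, match="unnormalized"):
            compute_capacitance(curve, find_tlp(curve))


class TestAnalyzePV:
    def test_full_trait_set(self, ideal_preset):
        traits = analyze_pv(simulate_pv_curve(ideal_preset, noise_sd=0.0))
        assert traits.pi_o == pytest.approx(2.0, rel=0.005)
        assert traits.psi_tlp == pytest.approx(-2.5, rel=0.005)
        assert traits.rwc_tlp == pytest.approx(80.0, rel=0.005)
        assert traits.epsilon == pytest.approx(10.0, rel=0.005)
        assert traits.swc == pytest.approx(2.0, abs=1e-9)
        assert traits.c_ft > 0

    def test_no_tail_raises(self, ideal_preset):
        rng = np.random.default_rng(0)
        rwc = np.linspace(99, 85, 12)
        psi = -2.0 * 100 / rwc + rng.normal(0, 0.6, 12)  # pure noise, no line
        psi = np.minimum(psi, -0.05)
        fresh = 0.2 + rwc / 100 * 0.4
        curve = PVCurve("noisy", psi, fresh, 0.2, 0.6, 0.001)
        with pytest.raises(NoTurgorLossError):
            find_tlp(curve)
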