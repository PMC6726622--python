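"""Unit and property tests for the proton transport engine.

Oracles are implemented independently of the package code paths:
a standalone Bethe evaluation, step-halved quadrature for ranges, and a
1 um forward-Euler energy-loss integrator for depth-energy and dose.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protodyn import beam_physics as bp
from protodyn.errors import DegenerateInputError, DomainError, InputError

# ------------------------------------------------------------ oracles


def oracle_bethe_water(energy_mev: float) -> float:
    """Independent Bethe evaluation for liquid water, I = 75 eV."""
    me = 0.51099895
    mp = 938.27208816
    K = 0.307075
    m_h2o = 2 * 1.008 + 15.999
    z_over_a = (2 * 1.008 / m_h2o) * 1 / 1.008 + (15.999 / m_h2o) * 8 / 15.999
    gamma = 1.0 + energy_mev / mp
    beta2 = 1.0 - 1.0 / gamma**2
    i_mev = 75e-6
    return K * z_over_a / beta2 * (
        np.log(2 * me * beta2 * gamma**2 / i_mev) - beta2
    )


def oracle_range_water(energy_mev: float, rtol: float = 1e-3) -> float:
    """Step-halved trapezoidal quadrature of 1/S from 0.05 MeV to E."""
    n = 64
    prev = None
    while True:
        e = np.linspace(0.05, energy_mev, n + 1)
        val = np.trapezoid(1.0 / np.array([oracle_bethe_water(x) for x in e]), e)
        if prev is not None and abs(val - prev) <= rtol * abs(val):
            return val
        prev = val
        n *= 2


def forward_euler_energy(medium, e0: float, depth_mm: float, step_um: float = 1.0):
    """Stepwise energy-loss integration dE = -rho * S/rho * dz."""
    e = e0
    dz_cm = step_um * 1e-4
    n = int(round(depth_mm / 10.0 / dz_cm))
    for _ in range(n):
        if e <= bp.ENERGY_MIN_MEV:
            return 0.0
        e -= medium.density * bp.mass_stopping_power(medium, e) * dz_cm
    return max(e, 0.0)


# ------------------------------------------------------- Medium / types


class TestMedium:
    def test_builtins_mass_fractions_sum_to_one(self):
        for med in bp.MEDIA.values():
            assert abs(sum(w for _, w in med.composition) - 1.0) < 1e-6

    def test_bad_fractions_rejected(self):
        with pytest.raises(InputError):
            bp.Medium("bad", 1.0, (("H", 0.5), ("O", 0.6)))

    def test_negative_density_rejected(self):
        with pytest.raises(InputError):
            bp.Medium("bad", -1.0, (("H", 1.0),))

    def test_water_i_override(self, water):
        assert water.i_value_ev == 75.0

    def test_dmso_i_from_ln_additivity(self, dmso):
        # independent recomputation of the ln-additive I value
        els = {"C": (6, 12.011, 78.0), "H": (1, 1.008, 19.2),
               "O": (8, 15.999, 95.0), "S": (16, 32.06, 180.0)}
        m = 2 * 12.011 + 6 * 1.008 + 15.999 + 32.06
        fracs = {"C": 2 * 12.011 / m, "H": 6 * 1.008 / m,
                 "O": 15.999 / m, "S": 32.06 / m}
        num = sum(fracs[s] * z / a * np.log(i) for s, (z, a, i) in els.items())
        den = sum(fracs[s] * z / a for s, (z, a, i) in els.items())
        assert dmso.i_value_ev == pytest.approx(np.exp(num / den), rel=1e-9)

    def test_beam_invariants(self):
        with pytest.raises(InputError):
            bp.ProtonBeam(-1.0)
        with pytest.raises(InputError):
            bp.ProtonBeam(10.0, energy_spread_fwhm_fraction=0.2)
        with pytest.raises(InputError):
            bp.ProtonBeam(10.0, fluence_rate=-1.0)


# ------------------------------------------------- mass_stopping_power


class TestMassStoppingPower:
    @pytest.mark.parametrize("energy", [10.0, 100.0])
    def test_water_matches_closed_form_oracle(self, water, energy):
        assert bp.mass_stopping_power(water, energy) == pytest.approx(
            oracle_bethe_water(energy), rel=1e-9
        )

    @pytest.mark.parametrize(
        "energy,published", [(10.0, 45.67), (100.0, 7.289)]
    )
    def test_water_near_published_tabulations(self, water, energy, published):
        # uncorrected Bethe sits within ~1% of the standard tables here
        assert bp.mass_stopping_power(water, energy) == pytest.approx(
            published, rel=0.01
        )

    def test_monotone_decreasing_above_maximum(self, water):
        e = np.array([1.0, 2.0, 5.0, 12.5, 50.0, 100.0, 200.0])
        s = bp.mass_stopping_power(water, e)
        assert np.all(np.diff(s) < 0)

    def test_compound_equals_weighted_elemental_sum(self, dmso):
        # Bragg additivity: medium value == mass-fraction-weighted sum of
        # single-element media evaluated with their own I values
        energy = 12.5
        total = 0.0
        for sym, w in dmso.composition:
            elem = bp.Medium(sym, 1.0, ((sym, 1.0),))
            total += w * bp.mass_stopping_power(elem, energy)
        assert bp.mass_stopping_power(dmso, energy) == pytest.approx(
            total, rel=1e-9
        )

    def test_domain_error_names_bound(self, water):
        with pytest.raises(DomainError, match="250"):
            bp.mass_stopping_power(water, 300.0)
        with pytest.raises(DomainError, match="0.05"):
            bp.mass_stopping_power(water, 0.01)

    def test_dmso_entrance_value_near_printed_conversion(self, dmso):
        # printed (8e8 /cm^2/s, 5.3 Gy/s) implies S/rho ~ 41; computed
        # DMSO Bethe value is lower but within the ~15% criterion window
        s = bp.mass_stopping_power(dmso, 12.5)
        implied = 5.3 / (8e8 * bp.MEV_PER_G_TO_GY)
        assert abs(s - implied) / implied < 0.15


# ------------------------------------------------------------ csda_range


class TestCsdaRange:
    def test_water_12p5_matches_quadrature_oracle(self, water):
        assert bp.csda_range(water, 12.5) == pytest.approx(
            oracle_range_water(12.5), rel=2e-3
        )

    def test_vanishes_at_lower_bound(self, water, dmso):
        for med in (water, dmso):
            assert 0 < bp.csda_range(med, bp.ENERGY_MIN_MEV) < 1e-3

    def test_strictly_increasing(self, dmso):
        energies = np.geomspace(0.1, 200, 40)
        ranges = [bp.csda_range(dmso, e) for e in energies]
        assert np.all(np.diff(ranges) > 0)

    def test_dmso_range_near_paper_peak_depth(self, dmso):
        depth_mm = bp.csda_range(dmso, 12.5) / dmso.density * 10.0
        assert depth_mm == pytest.approx(1.8, abs=0.1)


# -------------------------------------------------------- energy_at_depth


class TestEnergyAtDepth:
    def test_zero_depth_identity(self, beam_12p5, dmso):
        assert bp.energy_at_depth(beam_12p5, dmso, 0.0) == 12.5

    def test_zero_at_end_of_range(self, beam_12p5, dmso):
        end = bp.csda_range(dmso, 12.5) / dmso.density * 10.0
        assert bp.energy_at_depth(beam_12p5, dmso, end) == pytest.approx(0.0, abs=0.06)
        assert bp.energy_at_depth(beam_12p5, dmso, end + 0.5) == 0.0

    def test_mid_depth_matches_forward_euler(self, beam_12p5, dmso):
        for depth in (0.5, 1.0, 1.5):
            expected = forward_euler_energy(dmso, 12.5, depth)
            got = bp.energy_at_depth(beam_12p5, dmso, depth)
            assert got == pytest.approx(expected, rel=5e-3)

    def test_negative_depth_rejected(self, beam_12p5, dmso):
        with pytest.raises(InputError):
            bp.energy_at_depth(beam_12p5, dmso, -0.1)


# ------------------------------------------------------------- depth_dose


class TestDepthDose:
    def test_grid_validation(self, beam_12p5, dmso):
        with pytest.raises(InputError):
            bp.depth_dose(beam_12p5, dmso, [0.0, 0.2, 0.1])
        with pytest.raises(InputError):
            bp.depth_dose(beam_12p5, dmso, [0.5, 1.0])

    def test_peak_at_1p8_mm(self, dmso_curve):
        assert bp.bragg_peak_depth(dmso_curve) == pytest.approx(1.8, abs=0.1)

    def test_energy_conservation(self, dmso_curve, dmso):
        deposited = (
            np.trapezoid(dmso_curve.dose_per_fluence, dmso_curve.depth_grid / 10.0)
            * dmso.density / bp.MEV_PER_G_TO_GY
        )
        assert deposited == pytest.approx(12.5, rel=0.01)

    def test_no_dose_beyond_range(self, dmso_curve, dmso):
        end = bp.csda_range(dmso, 12.5) / dmso.density * 10.0
        tail = dmso_curve.dose_per_fluence[dmso_curve.depth_grid > end + 0.2]
        assert np.all(tail == 0.0)

    def test_spread_preserves_integral_and_lowers_peak(self, dmso):
        grid = np.arange(0.0, 3.0, 0.002)
        sharp = bp.depth_dose(bp.ProtonBeam(12.5, 0.0), dmso, grid)
        spread = bp.depth_dose(bp.ProtonBeam(12.5, 0.02), dmso, grid)
        i1 = np.trapezoid(sharp.dose_per_fluence, grid)
        i2 = np.trapezoid(spread.dose_per_fluence, grid)
        assert i2 == pytest.approx(i1, rel=5e-3)
        assert spread.dose_per_fluence.max() < sharp.dose_per_fluence.max()

    def test_200mev_peak_at_csda_range(self):
        tissue = bp.MEDIA["soft_tissue"]
        grid = np.arange(0.0, 300.0, 0.2)
        curve = bp.depth_dose(bp.ProtonBeam(200.0), tissue, grid)
        expected = bp.csda_range(tissue, 200.0) / tissue.density * 10.0
        assert bp.bragg_peak_depth(curve) == pytest.approx(expected, rel=0.02)

    def test_forward_euler_oracle_equivalence(self, dmso):
        # no spread, no straggling: dose tracks S/rho(E(z)) from the
        # 1 um step-by-step integrator within 2% before the distal 5%
        grid = np.arange(0.0, 2.0, 0.01)
        curve = bp.depth_dose(
            bp.ProtonBeam(12.5, 0.0), dmso, grid, straggling_fraction=0.0
        )
        end = bp.csda_range(dmso, 12.5) / dmso.density * 10.0
        for i, z in enumerate(grid):
            if z > 0.95 * end:
                break
            e = forward_euler_energy(dmso, 12.5, z)
            expected = bp.mass_stopping_power(dmso, e) * bp.MEV_PER_G_TO_GY
            assert curve.dose_per_fluence[i] == pytest.approx(expected, rel=0.02)


# -------------------------------------------------------------- dose_rate


class TestDoseRate:
    def test_zero_fluence(self):
        assert bp.dose_rate(0.0, 40.0) == 0.0

    def test_paper_conversion_within_15_percent(self, dmso):
        rate = bp.dose_rate(8e8, bp.mass_stopping_power(dmso, 12.5))
        assert abs(rate - 5.3) / 5.3 < 0.15

    @pytest.mark.parametrize("scale", [1e-2, 1e0, 1e2, 1e4, 1e6])
    def test_linearity_over_magnitudes(self, scale):
        base = bp.dose_rate(1e3, 35.0)
        assert bp.dose_rate(1e3 * scale, 35.0) == pytest.approx(
            base * scale, rel=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            bp.dose_rate(-1.0, 10.0)

    @given(st.floats(1e2, 1e12), st.floats(1.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_both_arguments(self, phi, s):
        assert bp.dose_rate(phi, s) == pytest.approx(
            phi * s * 1.602176634e-10, rel=1e-12
        )


class TestExposureTime:
    def test_clinical_dose_time(self):
        assert bp.exposure_time_for_dose(60.0, 0.66) == pytest.approx(90.9, abs=1.0)

    def test_invalid(self):
        with pytest.raises(InputError):
            bp.exposure_time_for_dose(10.0, 0.0)


# -------------------------------------------------------- bragg_peak_depth


class TestBraggPeakDepth:
    def test_triangular_apex_exact(self, dmso):
        z = np.linspace(0, 2, 41)
        y = 1.0 - np.abs(z - 1.0)
        curve = bp.DepthDoseCurve(z, y, dmso)
        assert bp.bragg_peak_depth(curve) == pytest.approx(1.0, abs=1e-12)

    def test_matches_fine_grid_argmax(self, beam_12p5, dmso):
        coarse = bp.depth_dose(beam_12p5, dmso, np.arange(0.0, 3.0, 0.02))
        fine = bp.depth_dose(beam_12p5, dmso, np.arange(0.0, 3.0, 0.002))
        brute = fine.depth_grid[np.argmax(fine.dose_per_fluence)]
        assert abs(bp.bragg_peak_depth(coarse) - brute) < 0.02

    def test_flat_curve_degenerate(self, dmso):
        curve = bp.DepthDoseCurve(np.linspace(0, 1, 11), np.ones(11), dmso)
        with pytest.raises(DegenerateInputError):
            bp.bragg_peak_depth(curve)
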