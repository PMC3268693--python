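"""Dose model: absorption coefficients, dose rates, composition corrections."""

import math

import numpy as np
import pytest

import betaburn as bb
from betaburn.dose import BeamProfile, Composition, concentration_from_asu
from betaburn.exceptions import EnergyRangeError, UnsupportedElementError

# NIST mass energy-absorption coefficients for liquid water, cm^2/g
# (independent oracle for the f''-based coefficient; log-log interpolable)
WATER_MU_EN_RHO = {5.0: 41.88, 10.0: 4.944, 15.0: 1.374, 20.0: 0.5503}


def water_oracle_mm(energy_keV: float) -> float:
    """Log-log interpolation of the tabulated water values, in mm^-1 (rho=1)."""
    es = sorted(WATER_MU_EN_RHO)
    lo = max(e for e in es if e <= energy_keV)
    hi = min(e for e in es if e >= energy_keV)
    if lo == hi:
        return WATER_MU_EN_RHO[lo] / 10.0
    t = (math.log(energy_keV) - math.log(lo)) / (math.log(hi) - math.log(lo))
    val = math.exp(
        (1 - t) * math.log(WATER_MU_EN_RHO[lo]) + t * math.log(WATER_MU_EN_RHO[hi])
    )
    return val / 10.0


class TestDefaultComposition:
    def test_average_protein_crystal_recipe(self):
        comp = bb.default_composition()
        assert comp.solvent_fraction == 0.47
        assert comp.sulfur_per_residue == 0.05
        assert comp.solvent_sulfur_mM == 300.0

    def test_sulfur_density_matches_hand_count(self):
        comp = bb.default_composition()
        NA = 6.02214076e23
        # protein: 0.53 volume at 1.35 g/cm3, ~111.9 g/mol per residue
        m_res = 4.9 * 12.011 + 7.8 * 1.008 + 1.4 * 14.007 + 1.5 * 15.999 + 0.05 * 32.06
        n_res = 0.53 * 1.35 * NA / m_res
        n_s = 0.05 * n_res + 0.300 * NA / 1000.0 * 0.47
        assert comp.number_densities["S"] == pytest.approx(n_s, rel=1e-3)

    def test_density_is_plausible_for_a_protein_crystal(self):
        assert 1.1 < bb.default_composition().density < 1.3


class TestAbsorptionCoefficient:
    def test_vacuum_absorbs_nothing(self):
        assert bb.absorption_coefficient(Composition.vacuum(), 12.4) == 0.0

    def test_photoelectric_scaling_with_energy(self):
        comp = bb.default_composition()
        assert bb.absorption_coefficient(comp, 6.35) > bb.absorption_coefficient(comp, 12.7)

    @pytest.mark.parametrize("energy", [5.0, 10.0, 12.4, 15.0, 20.0])
    def test_water_within_10pct_of_tabulated_reference(self, energy):
        mu = bb.absorption_coefficient(Composition.water(), energy)
        assert mu == pytest.approx(water_oracle_mm(energy), rel=0.10)

    def test_continuous_in_energy_for_light_element_composition(self):
        # H/C/N/O/S have no absorption edges in 5-25 keV, so the log-log
        # slope should stay near the smooth photoelectric ~E^-3 law with no
        # jump anywhere on a fine energy grid
        comp = bb.default_composition()
        es = np.linspace(5.0, 25.0, 201)
        mus = np.array([bb.absorption_coefficient(comp, e) for e in es])
        slopes = np.diff(np.log(mus)) / np.diff(np.log(es))
        assert np.all(slopes < 0)
        assert np.all(np.abs(slopes) < 4.0)
        assert np.max(np.abs(np.diff(slopes))) < 0.1

    def test_higher_z_absorbs_more_at_equal_density(self):
        n = 3e22
        light = Composition({"O": n}, density=1.0)
        heavy = Composition({"S": n}, density=1.0)
        for e in (5.0, 12.4, 25.0):
            assert bb.absorption_coefficient(heavy, e) > bb.absorption_coefficient(light, e)

    def test_energy_out_of_range_rejected(self):
        with pytest.raises(EnergyRangeError):
            bb.absorption_coefficient(bb.default_composition(), 3.0)
        with pytest.raises(EnergyRangeError):
            bb.absorption_coefficient(bb.default_composition(), 30.0)

    def test_unknown_element_rejected(self):
        with pytest.raises(UnsupportedElementError):
            Composition({"Xx": 1e20}, density=1.0)


def _beam(flux=6.2e11, profile=BeamProfile.UNIFORM, energy=12.76):
    return bb.BeamParameters(flux=flux, energy=energy, fwhm_h=45.0, fwhm_v=35.0, profile=profile)


class TestDoseRate:
    def test_zero_flux_zero_dose(self):
        cry = bb.CrystalDescription(50, 50, 50, bb.default_composition())
        assert bb.dose_rate(_beam(flux=0.0), cry).value == 0.0

    def test_linear_in_flux(self, rng):
        cry = bb.CrystalDescription(50, 50, 50, bb.default_composition())
        for _ in range(10):
            flux = float(rng.uniform(1e9, 1e13))
            c = float(rng.uniform(0.1, 10.0))
            d1 = bb.dose_rate(_beam(flux=flux), cry).value
            d2 = bb.dose_rate(_beam(flux=c * flux), cry).value
            assert d2 == pytest.approx(c * d1, rel=1e-12)

    @pytest.mark.parametrize("profile", [BeamProfile.UNIFORM, BeamProfile.GAUSSIAN])
    def test_thin_crystal_matches_voxel_integration(self, profile):
        """Brute-force 3-D voxel sum over the illuminated volume as oracle."""
        comp = bb.default_composition()
        beam = _beam(profile=profile)
        cry = bb.CrystalDescription(30.0, 30.0, 5.0, comp)  # thin: mu*t << 1
        got = bb.dose_rate(beam, cry).value

        mu_um = bb.absorption_coefficient(comp, beam.energy) * 1e-3
        nx = nz = 400
        xs = np.linspace(-cry.size_x / 2, cry.size_x / 2, nx)
        ys = np.linspace(-cry.size_y / 2, cry.size_y / 2, nx)
        zs = np.linspace(0, cry.size_z, nz)
        if profile is BeamProfile.UNIFORM:
            ix = np.where(np.abs(xs) <= beam.fwhm_h / 2, beam.flux / (beam.fwhm_h * beam.fwhm_v), 0.0)
            iy = np.ones_like(ys)
        else:
            sx = beam.fwhm_h / (2 * math.sqrt(2 * math.log(2)))
            sy = beam.fwhm_v / (2 * math.sqrt(2 * math.log(2)))
            ix = beam.flux * np.exp(-xs**2 / (2 * sx**2)) / (2 * math.pi * sx * sy)
            iy = np.exp(-ys**2 / (2 * sy**2))
        dx = xs[1] - xs[0]
        dy = ys[1] - ys[0]
        dz = zs[1] - zs[0]
        photons_per_um2 = np.outer(ix, iy)  # photons/s/um^2 on the entrance face
        absorbed = photons_per_um2.sum() * dx * dy * np.sum(mu_um * np.exp(-mu_um * zs)) * dz
        e_j = beam.energy * 1.602176634e-16
        mass_kg = comp.density * cry.size_x * cry.size_y * cry.size_z * 1e-12 * 1e-3
        expect = absorbed * e_j / mass_kg / 1e6
        assert got == pytest.approx(expect, rel=0.01)

    def test_zero_size_crystal_rejected(self):
        with pytest.raises(ValueError):
            bb.CrystalDescription(0.0, 50, 50, bb.default_composition())

    # beamline setups with known crystal sizes, energies, fluxes and measured
    # dose rates (MGy/s); agreement is a factor-of-2 sanity property only
    TABLE_SETUPS = [
        ((300, 50, 50), 12.76, 6.2e11, 0.15),   # thermolysin
        ((900, 100, 100), 12.76, 9.9e11, 0.24),  # trypsin
        ((400, 200, 200), 7.70, 2.0e11, 0.14),   # A-DNA
        ((400, 40, 40), 12.64, 8.0e11, 0.20),    # FAE
        ((20, 20, 20), 12.75, 7.6e11, 0.17),     # RecR
        ((50, 40, 10), 12.72, 4.3e11, 0.10),     # GPCR
    ]

    @pytest.mark.parametrize("size,energy,flux,expected", TABLE_SETUPS)
    def test_known_beamline_setups_within_factor_two(self, size, energy, flux, expected):
        beam = _beam(flux=flux, energy=energy)
        cry = bb.CrystalDescription(*size, bb.default_composition())
        got = bb.dose_rate(beam, cry).value
        assert expected / 2 < got < expected * 2


class TestBetaCorrection:
    def test_identity_for_same_composition(self):
        comp = bb.default_composition()
        cry = bb.CrystalDescription(100, 100, 100, comp)
        assert bb.beta_correction_factor(comp, comp, _beam(), cry) == pytest.approx(1.0, abs=1e-14)

    def test_heavy_atoms_increase_factor_and_shrink_beta(self):
        default = bb.default_composition()
        selenated = Composition.from_crystal(extra_elements_mM={"Se": 30.0})
        cry = bb.CrystalDescription(100, 100, 100, default)
        r = bb.beta_correction_factor(default, selenated, _beam(), cry)
        assert r > 1.0
        beta = 0.9
        assert beta / r < beta

    def test_factor_equals_dose_rate_ratio(self):
        default = bb.default_composition()
        other = Composition.from_crystal(solvent_fraction=0.60, extra_elements_mM={"Co": 10.0})
        beam = _beam()
        cry = bb.CrystalDescription(80, 60, 40, default)
        r = bb.beta_correction_factor(default, other, beam, cry)
        d_def = bb.dose_rate(beam, bb.CrystalDescription(80, 60, 40, default)).value
        d_true = bb.dose_rate(beam, bb.CrystalDescription(80, 60, 40, other)).value
        assert r == pytest.approx(d_true / d_def, rel=1e-14)


def test_per_asu_concentration_helper():
    # 4 sites per ASU, 8 ASU in a 1e6 A^3 cell -> 32 atoms per 1e-18 cm^3
    mM = concentration_from_asu(4, 1e6, 8)
    atoms_per_cm3 = mM * 1e-3 * 6.02214076e23 / 1000.0
    assert atoms_per_cm3 == pytest.approx(32 / 1e-18, rel=1e-12)
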