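"""Monte Carlo survival engine, low-fluence alpha, LQ fits, Dx% extraction."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq

import nanox
from nanox.engine import (
    LQCoefficients,
    SurvivalCurve,
    alpha_closed_form,
    dose_at_survival,
    lq_fit,
    mean_impact_number,
    simulate_survival,
    survival_one_configuration,
)
from nanox.quality import C_GY

from conftest import make_quality


GEOM = nanox.GeometrySpec(RVs=7.0, LVs=1.0)


def make_cell(elf=None, betar=0.0615, rescale=True, cnorm=1.0, trce=1e-11, geom=GEOM):
    elf = elf or nanox.ELFParams(15_654.0, 549.0, 179_439.0)
    ref = nanox.ReferenceRadiation.from_sf2(0.42, betar)
    gp = nanox.GlobalParams(betaG=nanox.beta_g(betar, 0.8), Cnorm=cnorm, TRCE=trce)
    return nanox.CellLineParams(
        name="test", geom=geom, elf=elf, ref=ref, global_params=gp,
        eta=0.8, penumbra_alpha_rescale=rescale,
    )


def no_global(cell):
    """Variant with betar = 0 (no quadratic/global response)."""
    ref = nanox.ReferenceRadiation(alphar=cell.ref.alphar, betar=0.0)
    gp = replace(cell.global_params, betaG=0.0)
    return replace(cell, ref=ref, global_params=gp)


class TestMeanImpactNumber:
    def test_direct_arithmetic(self):
        ion = nanox.IonSpec("carbon", 10.0, 100.0)
        expected = math.pi * 49.0 / (C_GY * 100.0)  # = 9.609...
        assert mean_impact_number(1.0, ion, GEOM) == pytest.approx(expected, rel=1e-12)
        assert mean_impact_number(1.0, ion, GEOM) == pytest.approx(9.609, abs=5e-4)

    def test_zero_dose(self):
        assert mean_impact_number(0.0, nanox.IonSpec("carbon", 10.0, 100.0), GEOM) == 0.0

    def test_area_scaling(self):
        ion = nanox.IonSpec("carbon", 10.0, 100.0)
        big = nanox.GeometrySpec(RVs=14.0, LVs=1.0)
        assert mean_impact_number(1.0, ion, big) == pytest.approx(
            4.0 * mean_impact_number(1.0, ion, GEOM), rel=1e-12
        )

    def test_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            mean_impact_number(1.0, nanox.IonSpec("photon", 1.25, 0.3), GEOM)


class TestSurvivalOneConfiguration:
    def test_empty_configuration_is_cnorm(self):
        cell = make_cell(cnorm=0.9)
        q = make_quality([100.0], [1.0], 50.0, 0.2)
        assert survival_one_configuration([], cell, q) == 0.9

    def test_uncalibrated_error(self):
        cell = make_cell(cnorm=None)
        q = make_quality([100.0], [1.0], 50.0, 0.2)
        with pytest.raises(nanox.CalibrationError):
            survival_one_configuration([(50.0, 0.2)], cell, q)

    def test_penumbra_only_single_impact(self):
        """h = 0 and betaG = 0: survival is exp(-alpha_p (Vp/Vs) Zp)."""
        cell = no_global(make_cell(elf=nanox.ELFParams(1e4, 1e3, 0.0)))
        zp = 0.37
        q = make_quality([0.0], [1.0], 0.0, zp)
        s = survival_one_configuration([(0.0, zp)], cell, q)
        expected = math.exp(-cell.alpha_p * (GEOM.Vp / GEOM.Vs) * zp)
        assert s == pytest.approx(expected, rel=1e-12)

    def test_two_impacts_brute_force_oracle(self):
        """Explicit loop computation over two impacts, core mean in the local
        term and per-impact energies in the global term."""
        cell = make_cell(cnorm=0.97)
        q = make_quality([16_000.0], [1.0], 55.0, 0.21, ratio_core=(0.9, 0.9), ratio_pen=(0.98, 0.98))
        impacts = [(57.0, 0.20), (51.0, 0.25)]
        fc, fp = GEOM.Vc / GEOM.Vs, GEOM.Vp / GEOM.Vs
        f_mean = nanox.mean_elf(cell.elf, q)
        local = 0.0
        ztilde = 0.0
        for zc, zp in impacts:
            local += fc * f_mean + cell.alpha_p * fp * zp
            ztilde += 0.9 * fc * zc + 0.98 * fp * zp
        g = cell.global_params
        oracle = math.exp(-local) * g.Cnorm * math.exp(-g.betaG * ztilde**2)
        assert survival_one_configuration(impacts, cell, q) == pytest.approx(
            oracle, rel=1e-12
        )


class TestSimulateSurvival:
    def test_zero_dose_exact_unity(self, hsg_calibrated, carbon_quality):
        curve = simulate_survival(hsg_calibrated, carbon_quality, [0.0, 1.0], n_mc=500, seed=1)
        assert curve.mean_survival[0] == 1.0
        assert curve.mc_stderr[0] == 0.0

    def test_poisson_closed_form_equivalence(self):
        """Degenerate quality, betaG = 0: S(D) = exp(<K>(s1 - 1)) exactly
        (Poisson generating function)."""
        cell = no_global(make_cell(elf=nanox.ELFParams(15_654.0, 549.0, 1_900.0)))
        q = make_quality([16_000.0], [1.0], 55.0, 0.21)
        s1 = survival_one_configuration([(55.0, 0.21)], cell, q)
        assert 0.7 < s1 < 0.95  # mild per-impact lethality keeps the MC tame
        for d in (0.5, 2.0, 5.0):
            n_mc = 40_000
            curve = simulate_survival(cell, q, [d], n_mc=n_mc, seed=13)
            k_mean = mean_impact_number(d, q.ion, GEOM)
            analytic = math.exp(k_mean * (s1 - 1.0))
            assert abs(curve.mean_survival[0] - analytic) < 3 * curve.mc_stderr[0]

    def test_monotone_non_increasing(self, hsg_calibrated, carbon_quality):
        curve = simulate_survival(
            hsg_calibrated, carbon_quality, np.linspace(0, 8, 9), n_mc=4000, seed=5
        )
        s, se = curve.mean_survival, curve.mc_stderr
        assert np.all(s[1:] <= s[:-1] + 3 * (se[1:] + se[:-1]))
        assert np.all((s > 0) & (s <= 1))

    def test_determinism(self, hsg_calibrated, carbon_quality):
        c1 = simulate_survival(hsg_calibrated, carbon_quality, [1.0, 3.0], n_mc=500, seed=8)
        c2 = simulate_survival(hsg_calibrated, carbon_quality, [1.0, 3.0], n_mc=500, seed=8)
        np.testing.assert_array_equal(c1.mean_survival, c2.mean_survival)


class TestAlphaClosedForm:
    def test_harmless_impacts_give_zero(self):
        cell = no_global(make_cell(elf=nanox.ELFParams(1e4, 1e3, 0.0)))
        q = make_quality([0.0], [1.0], 0.0, 0.0)
        assert alpha_closed_form(cell, q) == 0.0

    def test_overkill_geometric_limit(self):
        """Always-lethal impacts: alpha saturates at pi RVs^2 / (C LET)."""
        cell = make_cell(elf=nanox.ELFParams(1.0, 0.5, 1e8))
        q = make_quality([5_000.0], [1.0], 500.0, 0.3, let=400.0)
        expected = math.pi * GEOM.RVs**2 / (C_GY * 400.0)
        assert alpha_closed_form(cell, q) == pytest.approx(expected, rel=1e-6)

    def test_matches_low_dose_slope(self, carbon_quality):
        """Closed form agrees with the numerical slope of -ln S at low dose
        within 3 combined standard errors (betaG = 0 variant)."""
        cell = no_global(make_cell())
        a_cf = alpha_closed_form(cell, carbon_quality)
        doses = np.array([0.01, 0.02, 0.05])
        curve = simulate_survival(cell, carbon_quality, doses, n_mc=400_000, seed=17)
        y = -np.log(curve.mean_survival)
        se_y = curve.mc_stderr / curve.mean_survival
        w = doses**2 / se_y**2
        slope = np.sum(w * y / doses) / np.sum(w)
        slope_se = 1.0 / math.sqrt(np.sum(w))
        assert abs(slope - a_cf) < 3 * slope_se


class TestLQFit:
    @staticmethod
    def synthetic_curve(alpha, beta, doses, noise_rng=None, se=1e-3):
        s = np.exp(-alpha * doses - beta * doses**2)
        err = np.full_like(doses, 0.0)
        if noise_rng is not None:
            s = s * np.exp(noise_rng.normal(0.0, se, size=len(doses)))
            err = s * se
        return SurvivalCurve(doses, s, err, n_mc=1, seed=0)

    def test_exact_recovery(self):
        doses = np.linspace(0.0, 6.0, 13)
        curve = self.synthetic_curve(0.3, 0.06, doses)
        lq = lq_fit(curve, 6.0)
        assert lq.alpha == pytest.approx(0.3, abs=1e-6)
        assert lq.beta == pytest.approx(0.06, abs=1e-6)

    def test_pure_exponential(self):
        doses = np.linspace(0.0, 6.0, 13)
        curve = self.synthetic_curve(0.4, 0.0, doses)
        lq = lq_fit(curve, 6.0)
        assert lq.beta == pytest.approx(0.0, abs=1e-9)
        assert lq.alpha == pytest.approx(0.4, abs=1e-9)

    def test_noisy_coverage(self):
        """Fitted +-3 SE interval covers the truth in >= 95% of 100 seeds."""
        doses = np.linspace(0.0, 6.0, 13)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            curve = self.synthetic_curve(0.3, 0.06, doses, noise_rng=rng, se=2e-3)
            lq = lq_fit(curve, 6.0)
            if abs(lq.alpha - 0.3) < 3 * lq.alpha_se and abs(lq.beta - 0.06) < 3 * lq.beta_se:
                hits += 1
        assert hits >= 95

    def test_degenerate_all_ones(self):
        doses = np.linspace(0.0, 6.0, 13)
        curve = SurvivalCurve(doses, np.ones_like(doses), np.zeros_like(doses), 1, 0)
        with pytest.raises(ValueError, match="degenerate"):
            lq_fit(curve, 6.0)

    def test_too_few_points(self):
        curve = self.synthetic_curve(0.3, 0.06, np.array([0.0, 1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="4 dose points"):
            lq_fit(curve, 2.5)


class TestDoseAtSurvival:
    def test_exponential_identity(self):
        lq = LQCoefficients(alpha=math.log(10.0), beta=0.0)
        assert dose_at_survival(lq, 0.1) == pytest.approx(1.0, rel=1e-12)

    def test_hsg_reference_d10(self):
        """HSG reference response (alphar from SF2, betar 0.0615): D10% = 4.093 Gy;
        cross-checked against a bisection oracle on the LQ expression."""
        lq = LQCoefficients(alpha=0.31075028385236153, beta=0.0615)
        d10 = dose_at_survival(lq, 0.1)
        assert d10 == pytest.approx(4.093, abs=2e-3)
        oracle = brentq(
            lambda d: math.exp(-lq.alpha * d - lq.beta * d * d) - 0.1, 0.1, 50.0,
            xtol=1e-10,
        )
        assert d10 == pytest.approx(oracle, abs=1e-8)

    @given(
        alpha=st.floats(min_value=0.01, max_value=2.0),
        beta=st.floats(min_value=0.0, max_value=0.3),
    )
    def test_d1_exceeds_d10(self, alpha, beta):
        lq = LQCoefficients(alpha=alpha, beta=beta)
        assert dose_at_survival(lq, 0.01) > dose_at_survival(lq, 0.1)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dose_at_survival(LQCoefficients(0.3, 0.06), 1.0)
        with pytest.raises(ValueError):
            dose_at_survival(LQCoefficients(0.0, 0.0), 0.1)


class TestCalibrationClosure:
    def test_reference_lq_reproduced(self, hsg_calibrated, reference_q):
        """-ln S for the reference radiation matches alphar*D + betar*D^2
        within 1% over 0.5-6 Gy after calibration."""
        ref = hsg_calibrated.ref
        doses = np.array([0.5, 1.0, 2.0, 4.0, 6.0])
        curve = simulate_survival(hsg_calibrated, reference_q, doses, n_mc=100_000, seed=23)
        model = -np.log(curve.mean_survival)
        target = ref.alphar * doses + ref.betar * doses**2
        assert np.all(np.abs(model - target) / target < 0.01)
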