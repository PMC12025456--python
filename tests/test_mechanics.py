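"""Contact-mechanics unit tests: closed forms, baseline handling, contact
point estimation and modulus round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from fenestra import mechanics as mech
from fenestra.mechanics import ForceCurve, IndenterModel, NoContactError

from conftest import hertz_curve, pyramid_curve


class TestClosedForms:
    def test_zero_indentation_gives_zero_force(self):
        assert mech.hertz_force_sphere(0.0, 1000.0) == 0.0
        assert mech.sneddon_force_pyramid(0.0, 1000.0) == 0.0

    def test_force_linear_in_modulus(self):
        f1 = mech.hertz_force_sphere(200.0, 1000.0)
        f2 = mech.hertz_force_sphere(200.0, 2000.0)
        assert f2 == pytest.approx(2 * f1)

    def test_pyramid_quadratic_law(self):
        f1 = mech.sneddon_force_pyramid(100.0, 5000.0)
        f2 = mech.sneddon_force_pyramid(200.0, 5000.0)
        assert f2 == pytest.approx(4 * f1)

    def test_negative_indentation_rejected(self):
        with pytest.raises(ValueError):
            mech.hertz_force_sphere(-1.0, 1000.0)
        with pytest.raises(ValueError):
            mech.sneddon_force_pyramid(-1.0, 1000.0)

    def test_soft_gel_worked_example(self):
        """100 pN on an 0.8 kPa gel with a 20 nm tip indents ~0.6 um."""
        delta_nm = mech.invert_indentation(100.0, 800.0, 0.5, 20.0)
        assert round(delta_nm / 1000.0, 1) == 0.6

    def test_inversion_matches_root_finding_oracle(self):
        # independent oracle: numerically invert the forward model
        delta_oracle = brentq(
            lambda d: mech.hertz_force_sphere(d, 800.0, 0.5, 20.0) - 100.0, 1.0, 5000.0
        )
        assert mech.invert_indentation(100.0, 800.0, 0.5, 20.0) == pytest.approx(
            delta_oracle, rel=1e-9
        )

    @given(st.floats(min_value=1.0, max_value=2000.0))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_inverse_identity(self, delta):
        f = mech.hertz_force_sphere(delta, 5000.0, 0.5, 25.0)
        assert mech.invert_indentation(f, 5000.0, 0.5, 25.0) == pytest.approx(
            delta, rel=1e-9
        )

    def test_zero_force_zero_indentation(self):
        assert mech.invert_indentation(0.0, 800.0) == 0.0


class TestIndenterModel:
    def test_kind_field_consistency(self):
        with pytest.raises(ValueError):
            IndenterModel(kind="sphere", tip_radius=None)
        with pytest.raises(ValueError):
            IndenterModel(kind="pyramid", half_angle=120.0)
        with pytest.raises(ValueError):
            IndenterModel(kind="sphere", tip_radius=25.0, poisson_ratio=0.7)


class TestBaseline:
    def test_zero_curve_unchanged(self):
        z = np.linspace(0, 500, 64)
        c = ForceCurve(z=z, force=np.zeros_like(z), spring_constant=0.1)
        out = mech.correct_baseline(c)
        assert np.allclose(out.force, 0.0)

    def test_linear_drift_removed(self):
        c = hertz_curve()
        drift = 5.0 + 0.03 * c.z
        noisy = ForceCurve(z=c.z, force=c.force + drift, spring_constant=0.1)
        out = mech.correct_baseline(noisy)
        pre = out.force[out.z < 250.0]
        assert abs(pre.mean()) < 0.5

    def test_fit_recovers_modulus_after_drift(self, sphere_model):
        c = hertz_curve(E=5000.0)
        drifted = ForceCurve(z=c.z, force=c.force + 10.0 + 0.02 * c.z, spring_constant=0.1)
        fit = mech.fit_apparent_modulus(
            mech.correct_baseline(drifted), sphere_model, (20.0, 250.0)
        )
        assert fit.E_app == pytest.approx(5000.0, rel=0.03)

    def test_invalid_fraction_rejected(self):
        c = hertz_curve()
        with pytest.raises(ValueError):
            mech.correct_baseline(c, baseline_fraction=0.95)


class TestContactPoint:
    def test_all_zero_force_raises(self):
        z = np.linspace(0, 500, 64)
        c = ForceCurve(z=z, force=np.zeros_like(z), spring_constant=0.1)
        with pytest.raises(NoContactError):
            mech.estimate_contact_point(c, "threshold")

    def test_residual_search_recovers_noiseless_contact(self, sphere_model):
        c = hertz_curve(E=5000.0, z_c=300.0)
        zc = mech.estimate_contact_point(
            c, "residual_search", model=sphere_model, fit_window=(10.0, 250.0)
        )
        assert abs(zc - 300.0) <= c.sample_spacing

    def test_threshold_matches_oracle_on_phantom_population(
        self, default_phantom, sphere_model
    ):
        """Threshold and brute-force residual-search contact points agree
        to within 2 sample spacings (median) on noisy phantom curves."""
        _, _, fv = default_phantom
        dz = fv.z[1] - fv.z[0]
        rng = np.random.default_rng(0)
        discrepancies = []
        for flat_idx in rng.choice(fv.shape[0] * fv.shape[1], 100, replace=False):
            c = fv.curve(flat_idx // fv.shape[1], flat_idx % fv.shape[1])
            try:
                zt = mech.estimate_contact_point(c, "threshold")
                zr = mech.estimate_contact_point(
                    c, "residual_search", model=sphere_model, fit_window=(10.0, 250.0)
                )
            except NoContactError:
                continue
            discrepancies.append(abs(zt - zr) / dz)
        assert len(discrepancies) >= 90
        assert np.median(discrepancies) <= 2.0


class TestIndentation:
    def test_rigid_surface_zero_indentation(self):
        z = np.linspace(0, 500, 128)
        z_c = 200.0
        k_pn = 0.1 * 1e3
        force = np.where(z > z_c, k_pn * (z - z_c), 0.0)
        c = ForceCurve(z=z, force=force, spring_constant=0.1)
        delta = mech.compute_indentation(c, z_c)
        assert np.allclose(delta, 0.0, atol=1e-9)

    def test_zero_force_indentation_equals_travel(self):
        z = np.linspace(0, 500, 128)
        c = ForceCurve(z=z, force=np.zeros_like(z), spring_constant=0.1)
        delta = mech.compute_indentation(c, 200.0)
        expected = np.clip(z - 200.0, 0.0, None)
        assert np.allclose(delta, expected)

    def test_contact_point_outside_range_rejected(self):
        z = np.linspace(0, 500, 64)
        c = ForceCurve(z=z, force=np.zeros_like(z), spring_constant=0.1)
        with pytest.raises(ValueError):
            mech.compute_indentation(c, 600.0)

    def test_phantom_indentation_matches_truth(self, flat_soft_phantom):
        """Indentation at 100 pN on the soft-gel phantom matches the
        closed-form inversion to within 1 nm."""
        spec, truth, fv = flat_soft_phantom
        c = fv.curve(4, 4)
        z_c = fv.metadata["z_offset_nm"]
        delta = mech.compute_indentation(c, z_c)
        d100 = np.interp(100.0, c.force, delta)
        expected = mech.invert_indentation(
            100.0, spec.substrate_modulus, spec.poisson_ratio, spec.tip_radius
        )
        assert abs(d100 - expected) < 1.0


class TestModulusFit:
    @pytest.mark.parametrize("E_true", [800.0, 5000.0, 52000.0])
    def test_sphere_round_trip(self, sphere_model, E_true):
        c = hertz_curve(E=E_true)
        fit = mech.fit_apparent_modulus(c, sphere_model, (20.0, 250.0))
        assert fit.E_app == pytest.approx(E_true, rel=0.005)
        assert abs(fit.contact_point - 300.0) <= c.sample_spacing

    def test_pyramid_round_trip(self):
        model = IndenterModel(kind="pyramid", half_angle=17.5)
        c = pyramid_curve(E=5000.0)
        fit = mech.fit_apparent_modulus(c, model, (20.0, 250.0))
        assert fit.E_app == pytest.approx(5000.0, rel=0.005)

    @pytest.mark.parametrize(
        "builder,expected",
        [(hertz_curve, 1.5), (pyramid_curve, 2.0)],
        ids=["sphere", "pyramid"],
    )
    def test_power_law_exponent(self, builder, expected):
        """Log-log regression of noiseless curves recovers the contact-law
        exponent (3/2 sphere, 2 pyramid)."""
        c = builder(E=5000.0, z_c=300.0)
        delta = mech.compute_indentation(c, 300.0)
        use = (delta > 20.0) & (delta < 350.0)
        slope = np.polyfit(np.log(delta[use]), np.log(c.force[use]), 1)[0]
        assert slope == pytest.approx(expected, abs=0.01)

    def test_narrow_window_rejected(self, sphere_model):
        c = hertz_curve()
        with pytest.raises(ValueError):
            mech.fit_apparent_modulus(c, sphere_model, (399.0, 400.0))

    def test_deflection_and_force_representations_agree(self, sphere_model):
        """A curve given as force or as deflection x spring-constant yields
        the same modulus (unit-handling consistency)."""
        c = hertz_curve(E=5000.0, k=0.1)
        deflection_nm = c.force / (0.1 * 1e3)
        rebuilt = ForceCurve(z=c.z, force=deflection_nm * (0.1 * 1e3), spring_constant=0.1)
        f1 = mech.fit_apparent_modulus(c, sphere_model, (20.0, 250.0), z_c=300.0)
        f2 = mech.fit_apparent_modulus(rebuilt, sphere_model, (20.0, 250.0), z_c=300.0)
        assert f1.E_app == pytest.approx(f2.E_app, rel=1e-12)

    def test_map_recovery_on_phantom(self, default_phantom, sphere_model):
        """Median fitted modulus within 5% of truth per phase at default noise."""
        spec, truth, fv = default_phantom
        E, zc, rms = mech.fit_force_volume(fv, sphere_model, (20.0, 250.0))
        cell = truth.cell_mask & truth.pure_phase_mask & ~truth.pore_mask
        substrate = ~truth.cell_mask
        assert np.nanmedian(E[cell]) == pytest.approx(spec.cell_modulus, rel=0.05)
        assert np.nanmedian(E[substrate]) == pytest.approx(spec.substrate_modulus, rel=0.05)

    def test_stiffness_regimes_separate(self, sphere_model):
        """Soft-gel-like (0.8 kPa) and stiff-gel-like (52 kPa) fits do not
        overlap at study noise levels."""
        rng = np.random.default_rng(5)
        soft, stiff = [], []
        for i in range(30):
            for E_true, out, window in ((800.0, soft, (100.0, 900.0)), (52000.0, stiff, (20.0, 250.0))):
                c = hertz_curve(E=E_true, dmax=1000.0 if E_true < 1000 else 400.0)
                noisy = ForceCurve(
                    z=c.z,
                    force=c.force + rng.normal(0, 15.0, c.force.size),
                    spring_constant=0.1,
                )
                fit = mech.fit_apparent_modulus(noisy, sphere_model, window, z_c=300.0)
                out.append(fit.E_app)
        assert max(soft) < min(stiff)
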