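"""Von Mises orientation densities, dispersion parameters, and profile fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import fiberwall as fw
from fiberwall.dispersion import ImageOrientation, aggregate_stack


def wedge_profile_ip(a, alpha_deg, width=5.0, mixture=False):
    centers = np.arange(0.0, 180.0, width)
    density = fw.rho_ip_mixture if mixture else fw.rho_ip
    return fw.AngularDistribution(
        centers, density(np.deg2rad(centers), a, np.deg2rad(alpha_deg))
    )


def wedge_profile_op(b, width=5.0):
    # image-plane convention: 0 deg = circumferential axis, elevations wrap
    centers = np.arange(0.0, 180.0, width)
    theta = np.deg2rad((centers + 90.0) % 180.0 - 90.0)
    return fw.AngularDistribution(centers, fw.rho_op(theta, b))


class TestDensities:
    def test_inplane_point_values(self):
        # a=0 is the flat density; at the peak the value is e^a / I0(a)
        assert fw.rho_ip(1.234, 0.0) == pytest.approx(1.0)
        assert fw.rho_ip(np.deg2rad(40.0), 1.0, np.deg2rad(40.0)) == pytest.approx(
            2.1470, abs=1e-4
        )

    def test_outofplane_point_value(self):
        assert fw.rho_op(0.0, 5.0) == pytest.approx(3.5683, abs=1e-4)

    def test_outofplane_flat_limit(self):
        theta = np.linspace(-np.pi / 2, np.pi / 2, 7)
        assert fw.rho_op(theta, 0.0) == pytest.approx(np.ones(7))

    @given(a=st.floats(0.0, 50.0), alpha=st.floats(0.0, np.pi / 2),
           phi=st.floats(0.0, 2.0 * np.pi))
    @settings(deadline=None, derandomize=True)
    def test_inplane_pi_periodic(self, a, alpha, phi):
        assert fw.rho_ip(phi, a, alpha) == pytest.approx(
            fw.rho_ip(phi + np.pi, a, alpha), rel=1e-12
        )

    @given(b=st.floats(0.0, 50.0), theta=st.floats(-np.pi / 2, np.pi / 2))
    @settings(deadline=None, derandomize=True)
    def test_outofplane_even(self, b, theta):
        assert fw.rho_op(theta, b) == pytest.approx(fw.rho_op(-theta, b), rel=1e-12)

    @pytest.mark.parametrize("c", [0.1, 0.5, 1.0, 2.0, 10.0, 100.0])
    def test_normalization_by_quadrature(self, c):
        ip = quad(lambda p: fw.rho_ip(p, c, 0.3), 0.0, 2.0 * np.pi, limit=200)[0]
        assert ip / (2.0 * np.pi) == pytest.approx(1.0, abs=1e-8)
        op = quad(lambda t: fw.rho_op(t, c) * np.cos(t), -np.pi / 2, np.pi / 2,
                  limit=200)[0]
        assert op / 2.0 == pytest.approx(1.0, abs=1e-8)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            fw.rho_ip(0.0, -1.0)
        with pytest.raises(ValueError):
            fw.rho_op(0.0, -0.5)
        with pytest.raises(ValueError):
            fw.kappa_ip(-1.0)
        with pytest.raises(ValueError):
            fw.kappa_op(-1.0)

    def test_theta_domain_enforced(self):
        with pytest.raises(ValueError):
            fw.rho_op(2.0, 1.0)


class TestDispersionParameters:
    def test_kappa_ip_values(self):
        assert fw.kappa_ip(0.0) == pytest.approx(0.5)
        assert fw.kappa_ip(1.0) == pytest.approx(0.2768, abs=1e-4)
        # perfect alignment limit
        assert fw.kappa_ip(1e6) == pytest.approx(0.0, abs=1e-3)

    def test_kappa_op_values(self):
        assert fw.kappa_op(5.0) == pytest.approx(0.4750, abs=1e-4)
        assert fw.kappa_op(0.0) == pytest.approx(1.0 / 3.0)
        assert fw.kappa_op(1e6) == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("b", [0.3, 2.0, 8.0])
    def test_kappa_op_matches_quadrature_definition(self, b):
        # closed form agrees with the density moment (1/4) int rho_op cos^3
        moment = quad(
            lambda t: fw.rho_op(t, b) * np.cos(t) ** 3,
            -np.pi / 2, np.pi / 2, limit=200,
        )[0]
        assert fw.kappa_op(b) == pytest.approx(moment / 4.0, abs=1e-10)

    def test_monotonicity_and_bounds(self):
        a = np.logspace(-3, 4, 60)
        k_ip = fw.kappa_ip(a)
        assert np.all(np.diff(k_ip) < 0)
        assert np.all((k_ip >= 0.0) & (k_ip <= 1.0))
        b = np.logspace(-3, 4, 60)
        k_op = fw.kappa_op(b)
        assert np.all(np.diff(k_op) > 0)
        assert np.all((k_op >= 0.0) & (k_op <= 0.5))


class TestProfileFits:
    def test_inplane_round_trip(self):
        model, info = fw.fit_inplane(wedge_profile_ip(3.0, 40.0))
        assert model.a == pytest.approx(3.0, abs=0.05)
        assert info["alpha_deg"] == pytest.approx(40.0, abs=0.5)

    def test_inplane_mixture_round_trip(self):
        model, info = fw.fit_inplane(wedge_profile_ip(4.0, 50.0, mixture=True),
                                     symmetric=True)
        assert model.a == pytest.approx(4.0, abs=0.1)
        assert info["alpha_deg"] == pytest.approx(50.0, abs=0.5)

    def test_uniform_profile_gives_zero_concentration(self):
        dist = fw.AngularDistribution(np.arange(0.0, 180.0, 5.0), np.ones(36))
        model, info = fw.fit_inplane(dist)
        assert model.a < 1e-3
        assert info["alpha_deg"] is None

    def test_mirrored_peaks_fold_to_alpha(self):
        # two mirrored peaks at +/-50 degrees -> alpha = 50
        model, info = fw.fit_inplane(wedge_profile_ip(6.0, 130.0))
        assert info["alpha_deg"] == pytest.approx(50.0, abs=0.5)

    def test_all_zero_profile_rejected(self):
        dist = fw.AngularDistribution(np.arange(0.0, 180.0, 5.0), np.zeros(36))
        with pytest.raises(ValueError):
            fw.fit_inplane(dist)
        with pytest.raises(ValueError):
            fw.fit_outofplane(dist)

    def test_outofplane_round_trip(self):
        model, _ = fw.fit_outofplane(wedge_profile_op(8.0))
        assert model.b == pytest.approx(8.0, abs=0.1)

    def test_outofplane_uniform_gives_zero(self):
        dist = fw.AngularDistribution(np.arange(0.0, 180.0, 5.0), np.ones(36))
        model, info = fw.fit_outofplane(dist)
        assert model.b < 1e-3

    def test_outofplane_noisy_recovery(self):
        # 1% multiplicative noise, 10 replicates: mean fitted b within 5% of 2
        rng = np.random.default_rng(7)
        centers = np.arange(0.0, 180.0, 5.0)
        clean = fw.rho_op(np.deg2rad((centers + 90.0) % 180.0 - 90.0), 2.0)
        fitted = []
        for _ in range(10):
            amps = clean * (1.0 + rng.normal(0.0, 0.01, clean.size))
            model, _ = fw.fit_outofplane(fw.AngularDistribution(centers, amps))
            fitted.append(model.b)
        assert np.mean(fitted) == pytest.approx(2.0, rel=0.05)


class TestIsotropyClassification:
    def test_exactly_uniform_is_isotropic(self):
        dist = fw.AngularDistribution(np.arange(0.0, 180.0, 5.0), np.ones(36))
        assert fw.classify_isotropy(dist)

    def test_peaked_profile_is_anisotropic(self):
        assert not fw.classify_isotropy(wedge_profile_ip(5.0, 30.0))

    def test_zero_threshold_accepts_everything(self):
        assert fw.classify_isotropy(wedge_profile_ip(5.0, 30.0), r2_threshold=0.0)


class TestAggregation:
    def test_single_image_identity(self):
        ds = aggregate_stack([ImageOrientation(40.0, 3.0), ImageOrientation(b=6.0)])
        assert ds.alpha_deg == pytest.approx(40.0)
        assert ds.kappa_ip == pytest.approx(fw.kappa_ip(3.0))
        assert ds.kappa_op == pytest.approx(fw.kappa_op(6.0))

    def test_means_over_images(self):
        ds = aggregate_stack([ImageOrientation(30.0, 2.0), ImageOrientation(50.0, 4.0)])
        assert ds.alpha_deg == pytest.approx(40.0)
        assert ds.alpha_sd_deg == pytest.approx(np.std([30.0, 50.0], ddof=1))
        assert ds.kappa_ip == pytest.approx(fw.kappa_ip(3.0))

    def test_isotropic_images_enter_means_as_zero(self):
        ds = aggregate_stack([
            ImageOrientation(a=0.0, isotropic=True),
            ImageOrientation(45.0, 4.0),
        ])
        assert ds.a_mean == pytest.approx(2.0)
        assert ds.n_isotropic == 1

    def test_isotropic_exclusion_option(self):
        ds = aggregate_stack(
            [ImageOrientation(a=0.0, isotropic=True), ImageOrientation(45.0, 4.0)],
            include_isotropic_in_means=False,
        )
        assert ds.a_mean == pytest.approx(4.0)

    def test_all_isotropic_flags_alpha_undefined(self):
        ds = aggregate_stack([ImageOrientation(a=0.0, isotropic=True)])
        assert ds.alpha_deg is None

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            aggregate_stack([])
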