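"""Guinier analysis, P(r) inversion, Dmax estimation and elongation metrics.

Analytic bodies provide the oracles: a uniform sphere of radius R has
Rg = sqrt(3/5)*R and Dmax = 2R; a two-sphere dumbbell with centers d apart
has Dmax = d + 2R.
"""

import numpy as np
import pytest

import ptenkin as pk
from ptenkin.exceptions import DomainError, FitError
from ptenkin.synth import sphere_intensity

from conftest import SPHERE_R, SPHERE_RG


class TestGuinier:
    def test_sphere_radius_of_gyration(self, sphere_curve):
        fit = pk.guinier_fit(sphere_curve)
        assert fit.Rg == pytest.approx(SPHERE_RG, rel=0.01)
        assert fit.qRg_max <= 1.3 + 1e-9

    def test_intensity_rescaling_leaves_rg(self, sphere_curve):
        scaled = pk.ScatteringCurve(
            q=sphere_curve.q, I=sphere_curve.I * 42.0, sigma=sphere_curve.sigma * 42.0
        )
        a, b = pk.guinier_fit(sphere_curve), pk.guinier_fit(scaled)
        assert b.Rg == pytest.approx(a.Rg, rel=1e-9)
        assert b.I0 == pytest.approx(a.I0 * 42.0, rel=1e-6)

    def test_flat_profile_flagged_point_like(self, q_grid):
        curve = pk.ScatteringCurve(q=q_grid, I=np.ones_like(q_grid))
        fit = pk.guinier_fit(curve)
        assert fit.point_like and fit.Rg == 0.0

    def test_aggregation_like_upturn_raises(self, q_grid):
        curve = pk.ScatteringCurve(q=q_grid, I=np.exp(+(q_grid * 30) ** 2 / 3))
        with pytest.raises(FitError, match="positive"):
            pk.guinier_fit(curve)

    def test_sphere_first_minimum_location(self, q_grid):
        """The sphere form factor's first zero sits at qR ~ 4.493."""
        I = sphere_intensity(np.linspace(4.0 / SPHERE_R, 5.0 / SPHERE_R, 2000), SPHERE_R)
        qmin = np.linspace(4.0, 5.0, 2000)[np.argmin(I)]
        assert qmin == pytest.approx(4.493, abs=0.01)


class TestPairDistribution:
    def test_sphere_real_space_rg(self, sphere_curve):
        res = pk.pair_distribution(sphere_curve, Dmax=2 * SPHERE_R, alpha=1.0)
        assert res.Rg_real == pytest.approx(SPHERE_RG, rel=0.02)
        # unimodal up to discretization: a single dominant interior maximum
        peak = np.argmax(res.Pr)
        assert 0 < peak < len(res.r) - 1

    def test_endpoints_and_nonnegativity(self, sphere_curve):
        res = pk.pair_distribution(sphere_curve, Dmax=2 * SPHERE_R, alpha=1.0)
        assert res.Pr[0] == 0.0 and res.Pr[-1] == 0.0
        assert res.Pr.min() > -0.02 * res.Pr.max()

    def test_round_trip_reproduces_intensities(self, sphere_curve):
        """Forward-transforming the fitted P(r) matches the input I(q)."""
        res = pk.pair_distribution(sphere_curve, Dmax=2 * SPHERE_R, alpha=1.0)
        qr = np.outer(sphere_curve.q, res.r)
        sinc = np.ones_like(qr)
        sinc[qr != 0] = np.sin(qr[qr != 0]) / qr[qr != 0]
        I_back = 4 * np.pi * np.trapezoid(sinc * res.Pr[None, :], res.r, axis=1)
        chi = (I_back - sphere_curve.I) / sphere_curve.sigma
        assert np.mean(chi**2) < 1.0

    def test_zero_angle_identity(self, sphere_curve):
        """4*pi*integral(P) equals the Guinier forward scattering within 5%."""
        res = pk.pair_distribution(sphere_curve, Dmax=2 * SPHERE_R, alpha=1.0)
        g = pk.guinier_fit(sphere_curve)
        assert res.I0 == pytest.approx(g.I0, rel=0.05)

    def test_alpha_stability(self, sphere_curve):
        """Halving/doubling the default alpha moves Rg_real by < 1%."""
        rgs = [
            pk.pair_distribution(sphere_curve, Dmax=2 * SPHERE_R, alpha=a).Rg_real
            for a in (0.5, 1.0, 2.0)
        ]
        assert max(rgs) / min(rgs) - 1 < 0.01

    def test_guinier_and_real_space_agree(self, sphere_curve):
        g = pk.guinier_fit(sphere_curve)
        res = pk.pair_distribution(sphere_curve, Dmax=2 * SPHERE_R, alpha=1.0)
        assert g.Rg == pytest.approx(res.Rg_real, rel=0.02)

    def test_invalid_alpha_raises(self, sphere_curve):
        with pytest.raises(DomainError):
            pk.pair_distribution(sphere_curve, Dmax=60.0, alpha=0.0)

    def test_truncation_warning_for_high_qmin(self):
        q = np.linspace(0.08, 0.5, 150)
        curve = pk.gen_scattering("sphere", q, pk.quiet(0), R=SPHERE_R)
        with pytest.warns(UserWarning, match="qmin"):
            pk.pair_distribution(curve, Dmax=60.0, alpha=1.0)


class TestDmax:
    def test_sphere_diameter(self, sphere_curve):
        scan = pk.estimate_dmax(sphere_curve, r_scan=(30, 100))
        assert scan.Dmax == pytest.approx(2 * SPHERE_R, rel=0.05)

    def test_dumbbell_extent(self, q_grid):
        curve = pk.gen_scattering("two_sphere", q_grid, pk.quiet(2), d=40.0, R=10.0)
        scan = pk.estimate_dmax(curve, r_scan=(30, 100))
        assert scan.Dmax == pytest.approx(60.0, rel=0.10)

    def test_scan_widening_stability(self, sphere_curve):
        narrow = pk.estimate_dmax(sphere_curve, r_scan=(30, 100))
        wide = pk.estimate_dmax(sphere_curve, r_scan=(20, 150))
        grid_step = (150 - 20) / 24
        assert abs(wide.Dmax - narrow.Dmax) <= grid_step + 1e-9

    def test_narrow_scan_warns_at_boundary(self, sphere_curve):
        with pytest.warns(UserWarning, match="scan"):
            pk.estimate_dmax(sphere_curve, r_scan=(70, 120))


class TestElongation:
    def test_identical_inputs_zero_deltas(self, sphere_curve):
        res = pk.pair_distribution(sphere_curve, Dmax=60.0, alpha=1.0)
        rep = pk.elongation_report(res, res)
        assert rep["delta_Rg"] == 0.0
        assert rep["delta_Dmax"] == 0.0
        assert rep["delta_shoulder"] == 0.0

    def test_dumbbell_has_larger_shoulder_than_sphere(self, q_grid, sphere_curve):
        dumbbell = pk.gen_scattering("two_sphere", q_grid, pk.quiet(3), d=40.0, R=10.0)
        res_d = pk.pair_distribution(dumbbell, Dmax=60.0, alpha=1.0)
        res_s = pk.pair_distribution(sphere_curve, Dmax=60.0, alpha=1.0)
        rep = pk.elongation_report(res_d, res_s)
        assert rep["delta_shoulder"] > 0
        assert res_d.Rg_real > 0

    def test_elongated_body_has_larger_rg(self, q_grid):
        compact = pk.gen_scattering("sphere", q_grid, pk.quiet(4), R=20.0)
        elongated = pk.gen_scattering("two_sphere", q_grid, pk.quiet(5), d=50.0, R=15.0)
        rg_c = pk.pair_distribution(compact, Dmax=40.0, alpha=1.0).Rg_real
        rg_e = pk.pair_distribution(elongated, Dmax=80.0, alpha=1.0).Rg_real
        assert rg_e > rg_c
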