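"""Interfacial rate law, apparent fits, truncation and parameter combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ptenkin as pk
from ptenkin.exceptions import (
    DesignError,
    DomainError,
    InconsistentFitsError,
    SubstrateInhibitionError,
)
from ptenkin.interfacial import ApparentMMFit, apparent_bd, apparent_sd


class TestVelocity:
    def test_worked_value(self, truth_params):
        # Vmax*Xs*S0/(iKm*Ks+iKm*S0+Xs*S0) = 0.03*50/(80+100+50) = 1.5/230
        assert pk.interfacial_velocity(truth_params, Xs=1, S0=50) == pytest.approx(1.5 / 230)

    @pytest.mark.parametrize("Xs,S0", [(0, 50), (1, 0), (0, 0)])
    def test_zero_substrate_gives_zero(self, truth_params, Xs, S0):
        assert pk.interfacial_velocity(truth_params, Xs, S0) == 0.0

    def test_saturating_bulk_limit(self, truth_params):
        # S0 -> inf at fixed Xs: v -> Vmax*Xs/(iKm+Xs)
        v = pk.interfacial_velocity(truth_params, Xs=1, S0=1e7)
        limit = truth_params.Vmax * 1 / (truth_params.iKm + 1)
        assert v == pytest.approx(limit, rel=1e-4)

    @pytest.mark.parametrize("bad", [dict(Xs=-1, S0=50), dict(Xs=1, S0=-5), dict(Xs=np.nan, S0=1)])
    def test_invalid_inputs_raise(self, truth_params, bad):
        with pytest.raises(DomainError):
            pk.interfacial_velocity(truth_params, **bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        kcat=st.floats(0.1, 100), iKm=st.floats(0.1, 50), Ks=st.floats(0.1, 500),
        s_lo=st.floats(0.1, 100), s_hi=st.floats(0.1, 100),
        x_lo=st.floats(0.01, 50), x_hi=st.floats(0.01, 50),
    )
    def test_monotone_and_bounded(self, kcat, iKm, Ks, s_lo, s_hi, x_lo, x_hi):
        """Velocity is nondecreasing in S0 and Xs and bounded by kcat*ET."""
        p = pk.InterfacialParams(kcat=kcat, iKm=iKm, Ks=Ks, ET=0.01)
        s1, s2 = sorted((s_lo, s_hi))
        x1, x2 = sorted((x_lo, x_hi))
        assert pk.interfacial_velocity(p, x1, s1) <= pk.interfacial_velocity(p, x1, s2) + 1e-15
        assert pk.interfacial_velocity(p, x1, s1) <= pk.interfacial_velocity(p, x2, s1) + 1e-15
        assert pk.interfacial_velocity(p, x2, s2) < p.Vmax

    def test_params_must_be_positive(self):
        with pytest.raises(DomainError):
            pk.InterfacialParams(kcat=-1, iKm=2, Ks=40, ET=0.01)


class TestTruncation:
    @pytest.fixture
    def sd8(self, truth_params):
        return pk.gen_interfacial(
            truth_params, "surface_dilution", [0.25, 0.5, 1, 2, 4, 6, 8, 10],
            pk.quiet(0), substrate_inhibition=True,
        )

    def test_keeps_lowest_four(self, sd8):
        out = pk.truncate_substrate_inhibition(sd8, 4)
        assert sorted(set(p.Xs for p in out.points)) == [0.25, 0.5, 1, 2]

    def test_all_replicates_retained_and_order_preserved(self, sd8):
        out = pk.truncate_substrate_inhibition(sd8, 4)
        expected = [p for p in sd8.points if p.Xs <= 2]  # brute-force filter
        assert out.points == expected

    def test_identity_when_keeping_all(self, sd8):
        out = pk.truncate_substrate_inhibition(sd8, 8)
        assert out.points == sd8.points

    def test_too_few_kept_raises(self, sd8):
        with pytest.raises(DesignError):
            pk.truncate_substrate_inhibition(sd8, 2)

    def test_wrong_design_raises(self, truth_params):
        bd = pk.gen_interfacial(truth_params, "bulk_dilution", [5, 10, 25, 50], pk.quiet(0))
        with pytest.raises(DesignError):
            pk.truncate_substrate_inhibition(bd, 3)


class TestApparentFits:
    def test_bulk_dilution_closed_form(self, truth_params):
        ds = pk.gen_interfacial(truth_params, "bulk_dilution", [5, 10, 25, 50, 100, 200], pk.quiet(0))
        fit = pk.fit_apparent_mm(ds)
        vm, km = apparent_bd(truth_params, 1.0)  # 0.01, 26.667
        assert fit.Vmax_app == pytest.approx(vm, rel=1e-6)
        assert fit.Km_app == pytest.approx(km, rel=1e-6)

    def test_surface_dilution_closed_form(self, truth_params):
        ds = pk.gen_interfacial(truth_params, "surface_dilution", [0.25, 0.5, 1, 2, 4], pk.quiet(0))
        fit = pk.fit_apparent_mm(ds)
        vm, km = apparent_sd(truth_params, 50.0)  # 0.03, 3.6
        assert fit.Vmax_app == pytest.approx(vm, rel=1e-6)
        assert fit.Km_app == pytest.approx(km, rel=1e-6)

    def test_single_level_design_raises(self, truth_params):
        pts = [pk.VelocityPoint(S0=50, Xs=1, V0=0.005, replicate_id=str(i)) for i in range(5)]
        ds = pk.VelocityDataset(points=pts, design="bulk_dilution", ET=0.01)
        with pytest.raises(DesignError):
            pk.fit_apparent_mm(ds)

    def test_decreasing_data_suggest_truncation(self, truth_params):
        pts = [
            pk.VelocityPoint(S0=50, Xs=x, V0=v)
            for x, v in zip([1, 2, 4, 8, 16], [0.03, 0.02, 0.012, 0.006, 0.003])
        ]
        ds = pk.VelocityDataset(points=pts, design="surface_dilution", ET=0.01)
        with pytest.raises(SubstrateInhibitionError):
            pk.fit_apparent_mm(ds)


class TestCombine:
    def test_worked_combination(self):
        bd = ApparentMMFit(0.01, 80.0 / 3.0, 1e-4, 0.1, "bulk_dilution", 12)
        sd = ApparentMMFit(0.03, 3.6, 1e-4, 0.1, "surface_dilution", 12)
        p = pk.combine_interfacial(bd, sd, Xs_fixed=1.0, ET=0.01)
        assert p.iKm == pytest.approx(2.0)
        assert p.Ks == pytest.approx(40.0)
        assert p.kcat == pytest.approx(3.0)
        assert p.se_kcat > 0 and p.se_iKm > 0 and p.se_Ks > 0

    def test_equal_vmax_is_error(self):
        bd = ApparentMMFit(0.01, 26.7, 1e-4, 0.1, "bulk_dilution", 12)
        sd = ApparentMMFit(0.01, 3.6, 1e-4, 0.1, "surface_dilution", 12)
        with pytest.raises(InconsistentFitsError, match="no interfacial saturation"):
            pk.combine_interfacial(bd, sd, Xs_fixed=1.0, ET=0.01)

    def test_vmax_sd_below_bd_is_error(self):
        bd = ApparentMMFit(0.02, 26.7, 1e-4, 0.1, "bulk_dilution", 12)
        sd = ApparentMMFit(0.01, 3.6, 1e-4, 0.1, "surface_dilution", 12)
        with pytest.raises(InconsistentFitsError):
            pk.combine_interfacial(bd, sd, Xs_fixed=1.0, ET=0.01)

    @pytest.mark.parametrize("kcat,iKm,Ks", [(3, 2, 40), (0.5, 8, 5), (20, 0.3, 300)])
    def test_noise_free_round_trip(self, kcat, iKm, Ks):
        """Forward-simulate BD+SD, fit, combine: recovers the truth."""
        truth = pk.InterfacialParams(kcat=kcat, iKm=iKm, Ks=Ks, ET=0.01)
        bd_ds = pk.gen_interfacial(truth, "bulk_dilution", [5, 10, 25, 50, 100, 200, 400], pk.quiet(0))
        sd_ds = pk.gen_interfacial(truth, "surface_dilution", [0.1, 0.25, 0.5, 1, 2], pk.quiet(0))
        p = pk.combine_interfacial(
            pk.fit_apparent_mm(bd_ds), pk.fit_apparent_mm(sd_ds), Xs_fixed=1.0, ET=0.01
        )
        assert p.kcat == pytest.approx(kcat, rel=1e-6)
        assert p.iKm == pytest.approx(iKm, rel=1e-6)
        assert p.Ks == pytest.approx(Ks, rel=1e-6)


class TestBootstrap:
    def test_bootstrap_se_matches_delta_method_scale(self, truth_params):
        """Replicate-resampling SEs agree with the delta method within a
        factor of ~3 and are reproducible for a fixed seed."""
        bd = pk.gen_interfacial(truth_params, "bulk_dilution", [5, 10, 25, 50, 100, 200], pk.default_noise(1))
        sd = pk.gen_interfacial(truth_params, "surface_dilution", [0.25, 0.5, 1, 2], pk.default_noise(2))
        p = pk.combine_interfacial(
            pk.fit_apparent_mm(bd), pk.fit_apparent_mm(sd), Xs_fixed=1.0, ET=truth_params.ET
        )
        boot = pk.bootstrap_interfacial(bd, sd, n_boot=100, seed=0)
        assert boot == pk.bootstrap_interfacial(bd, sd, n_boot=100, seed=0)
        for name in ("se_kcat", "se_iKm", "se_Ks"):
            assert boot[name] / getattr(p, name) < 3.5
            assert getattr(p, name) / boot[name] < 3.5


class TestActivityRatio:
    def test_identical_params_give_unity(self, truth_params):
        assert pk.activity_rate_ratio(truth_params, truth_params, 1, 50) == pytest.approx(1.0)

    def test_weaker_membrane_binding_lowers_low_substrate_activity(self, truth_params):
        weak = pk.InterfacialParams(kcat=3.0, iKm=2.0, Ks=120.0, ET=0.01)
        # differential is large at low S0 and vanishes as S0 -> inf
        low = pk.activity_rate_ratio(weak, truth_params, Xs=1, S0=0.1)
        high = pk.activity_rate_ratio(weak, truth_params, Xs=1, S0=1e7)
        assert low < 0.5
        assert high == pytest.approx(1.0, rel=1e-3)

    def test_zero_denominator_raises(self, truth_params):
        with pytest.raises(DomainError):
            pk.activity_rate_ratio(truth_params, truth_params, Xs=1, S0=0)
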