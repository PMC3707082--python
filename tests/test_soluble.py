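"""Soluble Michaelis-Menten, linear-efficiency, IC50 and fold-change analysis."""

import numpy as np
import pandas as pd
import pytest

import ptenkin as pk
from ptenkin.exceptions import CurvatureError, DesignError, DomainError, FitError, NoSaturationError

S_LEVELS = [5, 10, 25, 50, 100, 200, 400]


class TestMichaelisMenten:
    def test_noise_free_recovery(self):
        ds = pk.gen_mm(2.9, 33.0, 0.01, S_LEVELS, pk.quiet(0))
        mm = pk.fit_michaelis_menten(ds)
        assert mm.kcat == pytest.approx(2.9, rel=1e-6)
        assert mm.Km == pytest.approx(33.0, rel=1e-6)

    def test_half_saturation_identity(self):
        """V at S = Km equals Vmax/2 for the fitted parameters."""
        ds = pk.gen_mm(2.6, 67.0, 0.01, S_LEVELS, pk.quiet(1))
        mm = pk.fit_michaelis_menten(ds)
        v_at_km = mm.kcat * ds.ET * mm.Km / (mm.Km + mm.Km)
        assert v_at_km == pytest.approx(mm.kcat * ds.ET / 2)

    def test_fit_invariant_under_reordering(self):
        ds = pk.gen_mm(2.6, 67.0, 0.01, S_LEVELS, pk.default_noise(7))
        rev = pk.VelocityDataset(
            points=list(reversed(ds.points)), design="soluble", ET=ds.ET
        )
        a, b = pk.fit_michaelis_menten(ds), pk.fit_michaelis_menten(rev)
        assert a.kcat == pytest.approx(b.kcat, rel=1e-8)
        assert a.Km == pytest.approx(b.Km, rel=1e-8)

    def test_unit_rescaling_scales_km(self):
        """Rescaling substrate units rescales Km and leaves kcat unchanged."""
        ds = pk.gen_mm(2.6, 67.0, 0.01, S_LEVELS, pk.default_noise(8))
        scaled = pk.VelocityDataset(
            points=[
                pk.VelocityPoint(S0=p.S0 * 1000.0, Xs=p.Xs, V0=p.V0, replicate_id=p.replicate_id)
                for p in ds.points
            ],
            design="soluble",
            ET=ds.ET,
        )
        a, b = pk.fit_michaelis_menten(ds), pk.fit_michaelis_menten(scaled)
        assert b.Km == pytest.approx(a.Km * 1000.0, rel=1e-6)
        assert b.kcat == pytest.approx(a.kcat, rel=1e-6)

    def test_no_saturation_directs_to_linear(self):
        ds = pk.gen_mm(2.6, 5000.0, 0.01, [1, 2, 5, 10, 20], pk.quiet(2))
        with pytest.raises(NoSaturationError, match="fit_linear_efficiency"):
            pk.fit_michaelis_menten(ds)


class TestLinearEfficiency:
    def test_exact_on_noise_free_line(self):
        pts = [pk.VelocityPoint(S0=s, Xs=0, V0=0.005 * 0.01 * s) for s in [1, 2, 4, 8]]
        ds = pk.VelocityDataset(points=pts, design="soluble", ET=0.01)
        eff, _ = pk.fit_linear_efficiency(ds)
        assert eff == pytest.approx(0.005)

    def test_sub_saturating_mm_data_give_efficiency(self):
        # analytic low-S limit of MM at kcat=2.6, Km=67 is 0.0388 /min/uM
        ds = pk.gen_mm(2.6, 67.0, 0.01, [0.5, 1, 2, 3, 5], pk.quiet(3))
        eff, _ = pk.fit_linear_efficiency(ds)
        assert eff == pytest.approx(2.6 / 67.0, rel=0.05)

    def test_error_decreases_toward_low_substrate_limit(self):
        """Estimator converges to kcat/Km as max(S)/Km -> 0."""
        errs = []
        for ratio in (0.2, 0.1, 0.05):
            S = np.array([0.25, 0.5, 0.75, 1.0]) * 67.0 * ratio
            ds = pk.gen_mm(2.6, 67.0, 0.01, S, pk.quiet(4))
            eff, _ = pk.fit_linear_efficiency(ds)
            errs.append(abs(eff - 2.6 / 67.0))
        assert errs[0] > errs[1] > errs[2]

    def test_negative_slope_raises(self):
        pts = [pk.VelocityPoint(S0=s, Xs=0, V0=v) for s, v in zip([1, 2, 4, 8], [0.04, 0.03, 0.02, 0.01])]
        ds = pk.VelocityDataset(points=pts, design="soluble", ET=0.01)
        with pytest.raises(FitError):
            pk.fit_linear_efficiency(ds)

    def test_saturating_data_raise_curvature_error(self):
        ds = pk.gen_mm(2.6, 10.0, 0.01, [5, 10, 25, 50, 100], pk.quiet(5))
        with pytest.raises(CurvatureError):
            pk.fit_linear_efficiency(ds)


class TestEfficiencyAndFoldChange:
    @pytest.mark.parametrize(
        "kcat,Km,expected_2sf",
        [(2.9, 33.0, 0.088), (3.0, 112.0, 0.027), (1.0, 1.0, 1.0)],
    )
    def test_catalytic_efficiency(self, kcat, Km, expected_2sf):
        mm = pk.MMParams(kcat=kcat, Km=Km, se_kcat=0.1, se_Km=2.0)
        eff, se = pk.catalytic_efficiency(mm)
        assert float(f"{eff:.2g}") == pytest.approx(expected_2sf)
        assert se > 0

    @pytest.mark.parametrize(
        "a,b,expected", [(0.038, 0.005, 7.6), (0.088, 0.006, pytest.approx(14.7, abs=0.05)), (0.3, 0.3, 1.0)]
    )
    def test_fold_change(self, a, b, expected):
        assert pk.fold_change(a, b) == pytest.approx(expected, rel=1e-6)

    def test_fold_change_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            pk.fold_change(0.1, 0.0)


class TestIC50:
    I_LEVELS = [0, 0.03, 0.1, 0.3, 1, 3, 10, 30]

    def test_noise_free_recovery(self):
        dr = pk.gen_dose_response(1.0, 1.0, 0.0, self.I_LEVELS, pk.quiet(0))
        fit = pk.fit_ic50(dr)
        assert fit.inhibition_detected
        assert fit.IC50 == pytest.approx(1.0, rel=1e-4)

    def test_midpoint_identity(self):
        dr = pk.gen_dose_response(2.5, 0.8, 0.1, self.I_LEVELS, pk.quiet(1))
        fit = pk.fit_ic50(dr, anchor_top=False)
        mid = fit.predict(fit.IC50)
        assert mid == pytest.approx((fit.top + fit.bottom) / 2)

    def test_activity_axis_rescaling_leaves_ic50(self):
        dr = pk.gen_dose_response(1.0, 1.0, 0.0, self.I_LEVELS, pk.default_noise(2))
        scaled = dr.assign(activity=dr["activity"] * 37.0)
        a, b = pk.fit_ic50(dr), pk.fit_ic50(scaled)
        assert b.IC50 == pytest.approx(a.IC50, rel=1e-6)
        assert b.top == pytest.approx(a.top * 37.0, rel=1e-6)

    def test_flat_response_reports_no_inhibition(self):
        """An inactive inhibitor yields a no-inhibition result, not an error."""
        dr = pk.gen_dose_response(1.0, 1.0, 1.0, self.I_LEVELS, pk.default_noise(3))
        fit = pk.fit_ic50(dr)
        assert not fit.inhibition_detected
        assert fit.IC50 == np.inf

    def test_design_requirements(self):
        df = pd.DataFrame({"I_uM": [0, 1, 2, 3, 4], "activity": [1, 0.9, 0.8, 0.7, 0.6]})
        with pytest.raises(DesignError, match="log units"):
            pk.fit_ic50(df)
        df2 = pd.DataFrame({"I_uM": [0.1, 1, 10, 100, 1000], "activity": [1, 0.9, 0.5, 0.2, 0.1]})
        with pytest.raises(DesignError, match="zero"):
            pk.fit_ic50(df2)
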