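import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavlipid import fluorescence as fl
from cavlipid import synth


class TestGFactor:
    def test_equal_intensities_give_one(self):
        assert fl.g_factor(5.0, 5.0) == 1.0

    def test_ratio(self):
        assert fl.g_factor(6.0, 5.0) == pytest.approx(1.2)

    @pytest.mark.parametrize("pair", [(5.0, 0.0), (0.0, 5.0), (-1.0, 2.0)])
    def test_non_positive_rejected(self, pair):
        with pytest.raises(ValueError):
            fl.g_factor(*pair)


class TestAnisotropy:
    def test_isotropic_case(self):
        assert fl.anisotropy(fl.PolarizedIntensities(3.0, 3.0, g=1.0)) == 0.0

    def test_direct_arithmetic(self):
        assert fl.anisotropy(fl.PolarizedIntensities(2.0, 1.0, g=1.0)) == pytest.approx(0.25)

    def test_fully_polarized(self):
        assert fl.anisotropy(fl.PolarizedIntensities(4.0, 0.0, g=1.0)) == 1.0

    def test_zero_total_intensity_rejected(self):
        with pytest.raises(ValueError, match="total intensity"):
            fl.anisotropy(fl.PolarizedIntensities(0.0, 0.0, g=1.0))

    def test_g_from_90_degree_pair(self):
        p = fl.PolarizedIntensities(2.0, 1.0, i_90_0=6.0, i_90_90=5.0)
        assert p.grating_factor() == pytest.approx(1.2)
        expected = (2.0 - 1.2) / (2.0 + 2 * 1.2)
        assert fl.anisotropy(p) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        i_par=st.floats(min_value=0.01, max_value=1e6),
        i_perp=st.floats(min_value=0.01, max_value=1e6),
        g=st.floats(min_value=0.5, max_value=2.0),
        scale=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, i_par, i_perp, g, scale):
        r1 = fl.anisotropy(fl.PolarizedIntensities(i_par, i_perp, g=g))
        r2 = fl.anisotropy(
            fl.PolarizedIntensities(scale * i_par, scale * i_perp, g=g)
        )
        assert r2 == pytest.approx(r1, rel=1e-9, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        r=st.floats(min_value=-0.49, max_value=0.99),
        total=st.floats(min_value=1.0, max_value=1e5),
        g=st.floats(min_value=0.5, max_value=2.0),
    )
    def test_round_trip_from_target_anisotropy(self, r, total, g):
        p = fl.polarized_from_anisotropy(r, total=total, g=g)
        assert fl.anisotropy(p) == pytest.approx(r, abs=1e-12)


def make_series(kind, baseline, p1, kd, n=8, x_max=3.0, sigma=0.0, rng=None):
    x = np.linspace(0.0, x_max, n)
    sign = 1.0 if kind.increasing else -1.0
    y = baseline + sign * p1 * x / (kd + x)
    if sigma > 0:
        y = y + rng.normal(0, sigma, y.shape)
    return fl.TitrationSeries(x=x, y=y, observable_kind=kind)


class TestFitHyperbolic:
    def test_noiseless_decrease_recovers_parameters(self):
        series = make_series(fl.ObservableKind.ANISOTROPY_DECREASE, 0.21, 0.04, 0.48)
        fit = fl.fit_hyperbolic(series)
        assert fit.kd == pytest.approx(0.48, abs=1e-6)
        assert fit.p1 == pytest.approx(0.04, abs=1e-6)
        assert fit.baseline == pytest.approx(0.21, abs=1e-6)
        assert fit.plateau == pytest.approx(0.17, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_increase_recovers_kd(self):
        series = make_series(fl.ObservableKind.FLUORESCENCE_INCREASE, 100.0, 50.0, 0.75)
        fit = fl.fit_hyperbolic(series)
        assert fit.kd == pytest.approx(0.75, abs=1e-6)
        assert fit.plateau == pytest.approx(150.0, abs=1e-4)

    def test_constant_series_flags_zero_amplitude(self):
        series = fl.TitrationSeries(
            x=np.linspace(0, 3, 8),
            y=np.full(8, 0.21),
            observable_kind=fl.ObservableKind.ANISOTROPY_DECREASE,
        )
        fit = fl.fit_hyperbolic(series)
        assert fit.amplitude_zero
        assert fit.kd is None

    def test_fix_baseline_pins_y0(self):
        series = make_series(fl.ObservableKind.ANISOTROPY_DECREASE, 0.21, 0.04, 0.48)
        fit = fl.fit_hyperbolic(series, fix_baseline=True)
        assert fit.baseline == 0.21
        assert fit.kd == pytest.approx(0.48, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 points"):
            fl.fit_hyperbolic(
                fl.TitrationSeries(
                    x=np.array([0.0, 1.0, 2.0, 3.0]),
                    y=np.array([0.0, 1.0, 1.5, 1.8]),
                    observable_kind=fl.ObservableKind.FLUORESCENCE_INCREASE,
                )
            )

    def test_median_kd_recovery_under_noise(self):
        """sigma = 5% of amplitude, 8 points, 0-3 uM: median Kd error < 15%."""
        for kd_true in (0.3, 0.48, 0.75, 1.0):
            rng = np.random.default_rng(42)
            recovered = []
            for _ in range(100):
                series = make_series(
                    fl.ObservableKind.ANISOTROPY_DECREASE,
                    0.21,
                    0.04,
                    kd_true,
                    sigma=0.05 * 0.04,
                    rng=rng,
                )
                fit = fl.fit_hyperbolic(series)
                if fit.kd is not None:
                    recovered.append(fit.kd)
            median = float(np.median(recovered))
            assert abs(median - kd_true) / kd_true < 0.15


class TestFretEfficiency:
    def test_no_transfer(self):
        assert fl.fret_efficiency(100.0, 100.0) == 0.0

    def test_complete_transfer(self):
        assert fl.fret_efficiency(0.0, 100.0) == 1.0

    def test_sixteen_percent(self):
        assert fl.fret_efficiency(84.0, 100.0) == pytest.approx(0.16)

    def test_enhancement_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="enhancement"):
            assert fl.fret_efficiency(110.0, 100.0) == 0.0

    def test_non_positive_donor_rejected(self):
        with pytest.raises(ValueError):
            fl.fret_efficiency(10.0, 0.0)


class TestQuenchingCurve:
    def make_curve(self):
        art = synth.generate(synth.GeneratorConfig(seed=0, scenario="dph_quenching"))
        return fl.quenching_curve(art.data)

    def test_evaluate_at_2um_matches_construction(self):
        assert self.make_curve().evaluate(2.0) == pytest.approx(60.0, abs=1e-6)

    def test_evaluate_at_zero_is_zero(self):
        assert self.make_curve().evaluate(0.0) == 0.0

    def test_asymptote_approaches_max_quenching(self):
        qc = self.make_curve()
        assert qc.evaluate(1e6) == pytest.approx(100.0 * qc.fit.p1, rel=1e-4)

    def test_series_without_zero_point_rejected(self):
        series = fl.TitrationSeries(
            x=np.linspace(0.5, 4, 8),
            y=np.linspace(100, 60, 8),
            observable_kind=fl.ObservableKind.DONOR_QUENCHING,
        )
        with pytest.raises(ValueError, match="x = 0"):
            fl.quenching_curve(series)


class TestTitrationIO:
    def test_tsv_round_trip(self, tmp_path):
        series = make_series(fl.ObservableKind.ANISOTROPY_DECREASE, 0.21, 0.04, 0.48)
        series = fl.TitrationSeries(
            series.x, series.y, series.observable_kind, condition="30% cholesterol"
        )
        path = tmp_path / "t.tsv"
        fl.write_titration_tsv(series, path)
        back = fl.read_titration_tsv(path)
        assert back.observable_kind is fl.ObservableKind.ANISOTROPY_DECREASE
        assert back.condition == "30% cholesterol"
        assert np.array_equal(back.x, series.x)
        assert np.array_equal(back.y, series.y)

    def test_polarized_tsv(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("x_uM\ti_par\ti_perp\ti_90_0\ti_90_90\n0.0\t2.0\t1.0\t6.0\t5.0\n")
        [(x, p)] = fl.read_polarized_tsv(path)
        assert x == 0.0
        assert p.grating_factor() == pytest.approx(1.2)
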