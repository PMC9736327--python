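import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavlipid import cd

WL = np.arange(195.0, 256.0, 1.0)


def gaussian_trough_spectrum(centers, depths, widths=None, wl=WL):
    widths = widths or [4.0] * len(centers)
    el = np.zeros_like(wl)
    for c, d, w in zip(centers, depths, widths):
        el = el - d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return cd.CDSpectrum(wl, el)


class TestUnitConversion:
    def test_zero_raw_gives_zero_mre(self):
        spec = cd.to_mean_residue_ellipticity(WL, np.zeros_like(WL), 0.01, 64e-6, 162)
        assert np.all(spec.ellipticity == 0)

    def test_doubling_concentration_halves_mre(self):
        raw = np.full_like(WL, 10.0)
        a = cd.to_mean_residue_ellipticity(WL, raw, 0.01, 64e-6, 162)
        b = cd.to_mean_residue_ellipticity(WL, raw, 0.01, 128e-6, 162)
        assert np.allclose(a.ellipticity, 2 * b.ellipticity)

    def test_hand_computed_value(self):
        # 10 mdeg, 0.01 cm, 64 uM, 162 residues:
        # 10 / (10 * 0.01 * 64e-6 * 162) = 9645.06... deg cm^2 dmol^-1
        spec = cd.to_mean_residue_ellipticity(
            WL, np.full_like(WL, 10.0), 0.01, 64e-6, 162
        )
        expected = 10.0 / (10.0 * 0.01 * 64e-6 * 162)
        assert spec.ellipticity[0] == pytest.approx(expected)
        assert expected == pytest.approx(9645.0617, abs=1e-3)

    @pytest.mark.parametrize("kwargs", [
        {"path_length_cm": 0}, {"concentration_m": -1}, {"n_residues": 0},
    ])
    def test_non_positive_parameters_rejected(self, kwargs):
        full = {"path_length_cm": 0.01, "concentration_m": 64e-6, "n_residues": 162}
        full.update(kwargs)
        with pytest.raises(ValueError):
            cd.to_mean_residue_ellipticity(WL, np.zeros_like(WL), **full)


class TestHelixRatio:
    def make_pair(self, t222, t208):
        """Spectrum hitting the requested values exactly at 222 and 208 nm."""
        el = np.interp(WL, [WL[0], 208.0, 222.0, WL[-1]], [0.0, t208, t222, 0.0])
        return cd.CDSpectrum(WL, el)

    def test_ratio_below_one_is_isolated_helices(self):
        diag = cd.helix_ratio(self.make_pair(-9.6, -10.0))
        assert diag.ratio == pytest.approx(0.96)
        assert diag.classification is cd.CoiledCoilClass.ISOLATED_HELICES

    def test_ratio_above_one_is_coiled_coil(self):
        diag = cd.helix_ratio(self.make_pair(-11.2, -10.0))
        assert diag.ratio == pytest.approx(1.12)
        assert diag.classification is cd.CoiledCoilClass.COILED_COIL

    def test_boundary_ratio_one_is_isolated_helices(self):
        diag = cd.helix_ratio(self.make_pair(-10.0, -10.0))
        assert diag.ratio == pytest.approx(1.0)
        assert diag.classification is cd.CoiledCoilClass.ISOLATED_HELICES

    def test_positive_ellipticity_yields_no_ratio(self):
        diag = cd.helix_ratio(self.make_pair(5.0, -10.0))
        assert diag.ratio is None
        assert diag.classification is cd.CoiledCoilClass.OTHER

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e4))
    def test_ratio_scale_invariant(self, scale):
        base = gaussian_trough_spectrum([208, 222], [10.0, 9.0])
        scaled = cd.CDSpectrum(base.wavelengths, scale * base.ellipticity)
        assert cd.helix_ratio(scaled).ratio == pytest.approx(
            cd.helix_ratio(base).ratio
        )

    def test_classification_flips_as_ratio_crosses_one(self):
        below = cd.helix_ratio(self.make_pair(-9.99, -10.0))
        above = cd.helix_ratio(self.make_pair(-10.01, -10.0))
        assert below.classification is cd.CoiledCoilClass.ISOLATED_HELICES
        assert above.classification is cd.CoiledCoilClass.COILED_COIL

    def test_grid_not_covering_rejected(self):
        wl = np.arange(225.0, 256.0)
        with pytest.raises(ValueError, match="cover"):
            cd.helix_ratio(cd.CDSpectrum(wl, -np.ones_like(wl)))


class TestShapeClassification:
    def test_two_trough_spectrum_is_w(self):
        spec = gaussian_trough_spectrum([208, 222], [10.0, 9.0])
        assert cd.classify_shape(spec) is cd.SpectralShape.W_SHAPED

    def test_single_trough_at_218_is_v(self):
        spec = gaussian_trough_spectrum([218], [10.0], [6.0])
        assert cd.classify_shape(spec) is cd.SpectralShape.V_SHAPED

    def test_monotone_spectrum_is_other(self):
        spec = cd.CDSpectrum(WL, np.linspace(-5, 5, len(WL)))
        assert cd.classify_shape(spec) is cd.SpectralShape.OTHER

    def test_helix_ratio_attaches_shape(self):
        spec = gaussian_trough_spectrum([208, 222], [10.0, 9.0])
        assert cd.helix_ratio(spec).shape is cd.SpectralShape.W_SHAPED


class TestDeconvolution:
    def test_identity_on_a_basis_member(self):
        basis = cd.default_basis()
        spec = cd.CDSpectrum(basis.wavelengths, basis.spectra["regular_helix"])
        dec = cd.deconvolve(spec, basis)
        assert dec.fractions["regular_helix"] == pytest.approx(1.0, abs=1e-9)
        assert dec.residual_norm == pytest.approx(0.0, abs=1e-6)

    def test_exact_two_class_mixture_recovered(self):
        basis = cd.default_basis()
        spec = basis.mix({"regular_helix": 0.6, "right_twist": 0.4})
        dec = cd.deconvolve(spec, basis)
        assert dec.fractions["regular_helix"] == pytest.approx(0.6, abs=1e-6)
        assert dec.fractions["right_twist"] == pytest.approx(0.4, abs=1e-6)

    def test_fractions_nonnegative_and_sum_to_one(self):
        basis = cd.default_basis()
        rng = np.random.default_rng(5)
        spec = cd.CDSpectrum(
            basis.wavelengths, rng.normal(0, 5000, len(basis.wavelengths))
        )
        dec = cd.deconvolve(spec, basis)
        fr = dec.fraction_array(basis.names)
        assert np.all(fr >= 0)
        assert fr.sum() == pytest.approx(1.0)

    def test_mean_recovery_under_2pct_noise(self, rng):
        """Mean absolute fraction error < 0.05 at 2% noise over 50 seeds."""
        basis = cd.default_basis()
        names = basis.names
        errors = []
        for _ in range(50):
            true = rng.dirichlet(np.ones(len(names)))
            spec = basis.mix(dict(zip(names, true)))
            noisy = cd.CDSpectrum(
                spec.wavelengths,
                spec.ellipticity
                + rng.normal(0, 0.02 * np.abs(spec.ellipticity).max(), len(spec.wavelengths)),
            )
            dec = cd.deconvolve(noisy, basis)
            errors.append(np.abs(dec.fraction_array(names) - true).mean())
        assert np.mean(errors) < 0.05

    def test_collinear_basis_rejected(self):
        wl = WL
        a = -np.exp(-0.5 * ((wl - 210) / 5) ** 2)
        basis = cd.BasisSet(wl, {"a": a, "b": 2 * a})
        spec = cd.CDSpectrum(wl, a)
        with pytest.raises(ValueError, match="collinear"):
            cd.deconvolve(spec, basis)

    def test_non_overlapping_grids_rejected(self):
        basis = cd.default_basis()
        wl = np.arange(300.0, 320.0)
        with pytest.raises(ValueError, match="overlap"):
            cd.deconvolve(cd.CDSpectrum(wl, -np.ones_like(wl)), basis)


class TestIO:
    def test_spectrum_tsv_round_trip(self, tmp_path):
        spec = gaussian_trough_spectrum([208, 222], [10.0, 9.0])
        path = tmp_path / "s.tsv"
        cd.write_spectrum_tsv(spec, path)
        back = cd.read_spectrum_tsv(path)
        assert np.allclose(back.wavelengths, spec.wavelengths)
        assert np.allclose(back.ellipticity, spec.ellipticity)

    def test_basis_tsv_round_trip(self, tmp_path):
        basis = cd.default_basis()
        path = tmp_path / "b.tsv"
        cd.write_basis_tsv(basis, path)
        back = cd.read_basis_tsv(path)
        assert back.names == basis.names
        for n in basis.names:
            assert np.allclose(back.spectra[n], basis.spectra[n])
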