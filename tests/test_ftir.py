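import numpy as np
import pytest

from peptopo.ftir import (
    AssignmentWindows,
    Band,
    Spectrum,
    SpectrumError,
    StructureFractions,
    assign_fractions,
    classify_beta_polymorph,
    fit_bands,
    fit_bands_auto,
    helix_residue_count,
    pick_bands,
    read_spectrum,
    subtract_reference,
    write_spectrum,
)
from peptopo.simulate import SyntheticSpec, gen_amide_spectrum, preset_spec


def make_spectrum(bands, noise_sd=0.0, seed=0, baseline=(0.0, 0.0)):
    spec = SyntheticSpec(seed=seed, bands=tuple(bands), noise_sd=noise_sd, baseline=baseline)
    return gen_amide_spectrum(spec)


class TestSpectrum:
    def test_grid_must_be_monotone(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([1.0, 3.0, 2.0]), np.array([0.0, 0.0, 0.0]))

    def test_nonfinite_absorbance_rejected(self):
        with pytest.raises(SpectrumError):
            Spectrum(np.array([1.0, 2.0]), np.array([0.0, np.nan]))

    def test_csv_round_trip(self, tmp_path):
        s, _ = make_spectrum([Band(1655.0, 15.0, 1.0)])
        path = tmp_path / "s.csv"
        write_spectrum(s, path)
        back = read_spectrum(path)
        assert np.allclose(back.wavenumbers, s.wavenumbers)
        assert np.allclose(back.absorbance, s.absorbance, atol=1e-7)

    def test_tsv_and_whitespace_accepted(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("1600\t0.1\n1602\t0.2\n1604\t0.15\n")
        s = read_spectrum(path)
        assert s.wavenumbers.tolist() == [1600.0, 1602.0, 1604.0]

    def test_jcamp_xydata(self, tmp_path):
        path = tmp_path / "s.jdx"
        path.write_text(
            "##TITLE=test\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
            "##XFACTOR=1\n##YFACTOR=0.001\n##FIRSTX=1600\n##LASTX=1608\n##NPOINTS=5\n"
            "##XYDATA=(X++(Y..Y))\n1600 100 200 300\n1606 400 500\n##END=\n"
        )
        s = read_spectrum(path)
        assert s.wavenumbers.tolist() == [1600, 1602, 1604, 1606, 1608]
        assert s.absorbance == pytest.approx([0.1, 0.2, 0.3, 0.4, 0.5])


class TestSubtractReference:
    def test_self_subtraction_zero(self):
        s, _ = make_spectrum([Band(1655.0, 15.0, 1.0)])
        out = subtract_reference(s, s)
        assert np.allclose(out.absorbance, 0.0)

    def test_scale_zero_identity(self):
        s, _ = make_spectrum([Band(1655.0, 15.0, 1.0)])
        out = subtract_reference(s, s, scale=0.0)
        assert np.allclose(out.absorbance, s.absorbance)

    def test_grid_mismatch_rejected(self):
        a, _ = make_spectrum([Band(1655.0, 15.0, 1.0)])
        b = Spectrum(a.wavenumbers[:-1], a.absorbance[:-1])
        with pytest.raises(SpectrumError):
            subtract_reference(a, b)

    def test_recovers_peptide_from_peptide_plus_lipid(self):
        # [DERIVED] synthetic lipid band at 1735 is removed by subtraction
        grid = (1590.0, 1760.0, 2.0)
        pep = SyntheticSpec(seed=1, bands=(Band(1655.0, 16.0, 0.8),),
                            noise_sd=0.002, grid=grid)
        lipid_band = Band(1735.0, 20.0, 1.2)
        mix = SyntheticSpec(seed=1, bands=(Band(1655.0, 16.0, 0.8), lipid_band),
                            noise_sd=0.002, grid=grid)
        s_mix, _ = gen_amide_spectrum(mix)
        s_lipid, _ = gen_amide_spectrum(
            SyntheticSpec(seed=1, bands=(lipid_band,), noise_sd=0.0, grid=grid)
        )
        out = subtract_reference(s_mix, s_lipid)
        pure, _ = gen_amide_spectrum(pep)
        assert np.allclose(out.absorbance, pure.absorbance, atol=0.02)


class TestPickBands:
    def test_single_gaussian_at_1655(self):
        s, _ = make_spectrum([Band(1655.0, 15.0, 1.0, 1.0)], noise_sd=0.004, seed=2)
        candidates = pick_bands(s)
        assert len(candidates) >= 1
        assert min(abs(b.center - 1655.0) for b in candidates) <= 2.0

    def test_two_resolved_bands(self):
        s, _ = make_spectrum(
            [Band(1630.0, 12.0, 1.0), Band(1657.0, 14.0, 0.8)], noise_sd=0.004, seed=3
        )
        centers = [b.center for b in pick_bands(s)]
        assert min(abs(c - 1630) for c in centers) <= 2.5
        assert min(abs(c - 1657) for c in centers) <= 2.5

    def test_pure_noise_raises(self):
        rng = np.random.default_rng(0)
        wn = np.arange(1590.0, 1721.0, 2.0)
        s = Spectrum(wn, rng.normal(0.0, 1e-4, wn.size))
        with pytest.raises(SpectrumError):
            pick_bands(s)

    def test_too_few_points_rejected(self):
        wn = np.linspace(1600, 1700, 10)
        s = Spectrum(wn, np.exp(-((wn - 1650) / 10) ** 2))
        with pytest.raises(SpectrumError):
            pick_bands(s)


class TestFitBands:
    def test_noiseless_single_band_recovered(self):
        truth = Band(1655.0, 16.0, 0.9, 0.6)
        s, _ = make_spectrum([truth])
        fitted, diag = fit_bands(s, [Band(1653.0, 12.0, 0.7, 0.5)])
        assert diag["success"]
        b = fitted[0]
        assert b.center == pytest.approx(truth.center, rel=1e-3)
        assert b.fwhm == pytest.approx(truth.fwhm, rel=1e-3)
        assert b.amplitude == pytest.approx(truth.amplitude, rel=1e-3)
        assert b.area == pytest.approx(truth.area, rel=1e-2)

    def test_four_band_areas_within_5pct(self):
        # [DERIVED] generator truth at SNR 50. The Gaussian/Lorentzian mix
        # fraction is frozen at the generating value: it is weakly identified
        # at this SNR and trades off against area (see module docstring).
        bands = [
            Band(1618.0, 11.0, 0.9, 0.5),
            Band(1644.0, 12.0, 0.8, 0.5),
            Band(1668.0, 12.0, 1.0, 0.5),
            Band(1695.0, 10.0, 0.85, 0.5),
        ]
        s, truth = make_spectrum(bands, noise_sd=1.0 / 50.0, seed=7)
        initial = [Band(b.center + 1.0, 13.0, b.amplitude * 0.8, 0.5) for b in bands]
        fitted, _ = fit_bands(s, initial, vary_shape=False)
        for got, want in zip(fitted, bands):
            assert got.area == pytest.approx(want.area, rel=0.05)

    def test_initial_band_outside_region_rejected(self):
        s, _ = make_spectrum([Band(1655.0, 15.0, 1.0)])
        with pytest.raises(SpectrumError):
            fit_bands(s, [Band(1500.0, 12.0, 1.0)], region=(1600, 1715))

    def test_no_initial_bands_rejected(self):
        s, _ = make_spectrum([Band(1655.0, 15.0, 1.0)])
        with pytest.raises(SpectrumError):
            fit_bands(s, [])

    def test_auto_fit_helix_rich_preset(self):
        s, truth = gen_amide_spectrum(preset_spec("helix_rich", seed=11))
        bands, diag = fit_bands_auto(s)
        fractions = assign_fractions(bands)
        assert fractions.helix == pytest.approx(
            truth["class_fractions"]["helix"], abs=0.05
        )


class TestAssignFractions:
    def test_single_helix_band(self):
        fr = assign_fractions([Band(1655.0, 14.0, 1.0)])
        assert fr.helix == 1.0
        assert fr.sheet == fr.turn == fr.disordered == 0.0

    def test_sheet_low_plus_high_all_sheet(self):
        # [PAPER] 1630 major + 1691 minor are both beta-sheet
        fr = assign_fractions([Band(1630.0, 12.0, 1.0), Band(1691.0, 10.0, 0.2)])
        assert fr.sheet == 1.0

    def test_window_precedence_boundaries(self):
        w = AssignmentWindows()
        assert w.classify(1636.9) == "sheet"
        assert w.classify(1637.0) == "disordered"
        assert w.classify(1645.0) == "helix"
        assert w.classify(1662.0) == "helix"
        assert w.classify(1662.1) == "turn"
        assert w.classify(1682.0) == "turn"
        assert w.classify(1682.1) == "sheet"
        assert w.classify(1710.0) == "sheet"
        assert w.classify(1712.0) is None

    def test_unassigned_in_amide_i_counted_as_turn(self):
        fr = assign_fractions([Band(1605.0, 10.0, 1.0), Band(1655.0, 10.0, 1.0)])
        assert fr.turn > 0

    def test_outside_amide_i_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            fr = assign_fractions([Band(1750.0, 10.0, 1.0), Band(1655.0, 10.0, 1.0)])
        assert fr.helix == 1.0

    def test_scaling_invariance(self):
        bands = [Band(1630.0, 12.0, 0.5), Band(1655.0, 14.0, 1.0), Band(1670.0, 10.0, 0.2)]
        scaled = [Band(b.center, b.fwhm, 7.3 * b.amplitude, b.gauss_frac) for b in bands]
        a = assign_fractions(bands)
        b = assign_fractions(scaled)
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_fractions_sum_to_one(self):
        fr = assign_fractions(
            [Band(1630.0, 12.0, 0.3), Band(1655.0, 14.0, 0.9), Band(1695.0, 9.0, 0.1)]
        )
        assert sum(fr.as_dict().values()) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(SpectrumError):
            StructureFractions(0.5, 0.5, 0.5, 0.5)


class TestBetaPolymorph:
    def test_negligible_high_band_is_parallel_fibril(self):
        # [PAPER] 1630 major with negligible ~1695 absorption
        assert classify_beta_polymorph([Band(1630.0, 12.0, 1.0)]) == "parallel_fibril"

    def test_high_band_at_20pct_is_antiparallel_oligomer(self):
        # [PAPER] significant minor peak ~1/5 the intensity of the major one
        bands = [Band(1630.0, 12.0, 1.0), Band(1695.0, 10.0, 0.2)]
        assert classify_beta_polymorph(bands) == "antiparallel_oligomer"

    def test_helix_only_is_none(self):
        assert classify_beta_polymorph([Band(1655.0, 14.0, 1.0)]) == "none"

    def test_threshold_configurable(self):
        bands = [Band(1630.0, 12.0, 1.0), Band(1695.0, 10.0, 0.2)]
        assert classify_beta_polymorph(bands, ratio_threshold=0.30) == "parallel_fibril"


class TestHelixResidueCount:
    @pytest.mark.parametrize(
        "fraction,n,expected",
        [(0.672, 33, 22), (0.631, 34, 21), (0.446, 34, 15), (1.0, 33, 33)],
    )
    def test_paper_counts(self, fraction, n, expected):
        assert helix_residue_count(fraction, n) == expected

    def test_one_decimal_mode(self):
        assert helix_residue_count(0.446, 34, mode="one_decimal") == pytest.approx(15.2)

    def test_invalid_fraction(self):
        with pytest.raises(SpectrumError):
            helix_residue_count(1.2, 33)
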