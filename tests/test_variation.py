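"""Spectral shifts, opsin genotypes, and L-cone variant templates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conefund import (
    GenotypeSpec,
    builtin_template,
    combined_common_L,
    common_template_shifted,
    delta_theta,
    genotype_shift_nm,
    genotype_template,
    mix_templates,
    nm_shift_to_log10,
    parse_genotype,
    polymorphic_L,
    shift_template,
)


class TestDeltaTheta:
    def test_polymorphic_pair(self):
        # independent closed-form evaluation of the phase-shift formula
        expect = math.pi * math.log10(553.1 / 550.4) / math.log10(850.0 / 360.0)
        assert delta_theta(553.1, 550.4) == pytest.approx(expect, rel=1e-14)
        assert math.log10(553.1 / 550.4) == pytest.approx(0.002125, abs=5e-7)

    def test_zero_and_antisymmetry(self):
        assert delta_theta(500.0, 500.0) == 0.0
        assert delta_theta(556.0, 527.3) == pytest.approx(
            -delta_theta(527.3, 556.0), rel=1e-14)

    def test_domain(self):
        with pytest.raises(ValueError):
            delta_theta(360.0, 500.0)


class TestShiftedTemplates:
    @given(delta=st.floats(-0.02, 0.02))
    @settings(max_examples=25, deadline=None)
    def test_shape_invariance(self, delta):
        base = builtin_template("M")
        shifted = shift_template(base, delta)
        lam = np.linspace(420.0, 700.0, 29)
        assert np.allclose(shifted.log_absorbance(lam * 10.0 ** delta),
                           base.log_absorbance(lam), rtol=0, atol=1e-10)

    def test_composition_of_shifts(self):
        base = builtin_template("L")
        once = shift_template(shift_template(base, 0.004), -0.010)
        direct = shift_template(base, -0.006)
        lam = np.linspace(420.0, 700.0, 17)
        assert np.allclose(once.log_absorbance(lam), direct.log_absorbance(lam),
                           atol=1e-12)

    def test_zero_shift_identity(self):
        base = builtin_template("S")
        lam = np.linspace(380.0, 600.0, 17)
        assert np.array_equal(shift_template(base, 0.0).log_absorbance(lam),
                              base.log_absorbance(lam))

    def test_peak_moves_by_stated_log_shift(self):
        base = builtin_template("L")
        shifted = shift_template(base, 0.01)
        assert shifted.lambda_max() == pytest.approx(551.9 * 10 ** 0.01, abs=0.1)

    def test_out_of_support_raises(self):
        shifted = shift_template(builtin_template("L"), -0.01)
        with pytest.raises(ValueError):
            shifted.log_absorbance(849.0)  # maps above 850 in base coordinates


class TestPolymorphicL:
    def test_peaks(self):
        assert polymorphic_L("ser180").lambda_max() == 553.1
        assert polymorphic_L("ala180").lambda_max() == 550.4

    def test_ala_is_shifted_ser(self):
        ser, ala = polymorphic_L("ser180"), polymorphic_L("ala180")
        lam = np.linspace(420.0, 700.0, 17)
        assert np.allclose(ala.log_absorbance(lam * 10 ** -0.002125),
                           ser.log_absorbance(lam), atol=1e-10)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            polymorphic_L("thr180")


class TestCommonTemplate:
    @pytest.mark.parametrize("cone,peak", [("L", 557.5), ("L_ala180", 554.8),
                                           ("M", 527.3), ("S", 418.5)])
    def test_shifted_peaks(self, cone, peak):
        # within one 0.1-nm search step of the published peak
        assert common_template_shifted(cone).lambda_max() == pytest.approx(peak, abs=0.11)

    def test_combined_L_peak(self):
        assert combined_common_L().lambda_max() == 556.0

    def test_combined_L_unit_peak(self):
        mix = combined_common_L()
        lam = np.arange(mix.support[0], mix.support[1], 0.1)
        assert float(np.max(mix.linear_absorbance(lam))) == pytest.approx(1.0, abs=1e-9)


class TestMixtures:
    def test_degenerate_weight_is_component(self):
        ser = polymorphic_L("ser180")
        mix = mix_templates([ser, polymorphic_L("ala180")], [1.0, 0.0])
        lam = np.linspace(420.0, 700.0, 17)
        # identical up to the unit-peak rescale of the component itself
        ratio = mix.linear_absorbance(lam) / ser.linear_absorbance(lam)
        assert np.allclose(ratio, ratio[0], rtol=1e-10)

    def test_mixture_peak_between_components(self):
        ser, ala = polymorphic_L("ser180"), polymorphic_L("ala180")
        mix = mix_templates([ala, ser], [0.44, 0.56])
        assert ala.lambda_max() <= mix.lambda_max() <= ser.lambda_max()

    def test_population_mix_recovers_mean_L_peak(self):
        # 0.44 ala + 0.56 ser reproduces the mean L template's 551.9 nm peak
        mix = mix_templates([polymorphic_L("ala180"), polymorphic_L("ser180")],
                            [0.44, 0.56])
        assert mix.lambda_max() == pytest.approx(551.9, abs=0.1)

    def test_bad_weights(self):
        ser = polymorphic_L("ser180")
        with pytest.raises(ValueError):
            mix_templates([ser, ser], [0.7, 0.7])
        with pytest.raises(ValueError):
            mix_templates([ser, ser], [-0.1, 1.1])


class TestGenotypes:
    def test_single_substitution(self):
        assert genotype_shift_nm(parse_genotype("M[A285T]")) == 14.0
        assert genotype_shift_nm(parse_genotype("L[S180A]")) == -4.0

    def test_additive_combination(self):
        g = GenotypeSpec(base="L", states={277: "M_like", 285: "M_like"})
        assert genotype_shift_nm(g) == -21.0
        g_all = GenotypeSpec(base="M", states={c: "L_like" for c in
                                               (116, 180, 230, 233, 277, 285, 309)})
        assert genotype_shift_nm(g_all) == 27.0  # 0+3+3+0+7+14+0

    def test_native_states_shift_zero(self):
        assert genotype_shift_nm(GenotypeSpec(base="L")) == 0.0
        assert genotype_shift_nm(parse_genotype("M")) == 0.0

    def test_silent_codons(self):
        assert genotype_shift_nm(GenotypeSpec("L", {233: "M_like"})) == 0.0
        assert genotype_shift_nm(GenotypeSpec("M", {309: "L_like"})) == 0.0

    def test_parse_errors(self):
        with pytest.raises(ValueError):
            parse_genotype("K[A285T]")
        with pytest.raises(ValueError):
            parse_genotype("M[A200T]")  # not a spectral codon
        with pytest.raises(ValueError):
            parse_genotype("M[T285A]")  # wrong native residue

    def test_genotype_template_peak_moves_by_stated_nm(self):
        tpl = genotype_template(parse_genotype("M[A285T]"))
        assert tpl.lambda_max() == pytest.approx(529.8 + 14.0, abs=0.1)

    def test_nm_to_log_conversion_round_trip(self):
        delta = nm_shift_to_log10(-3.5, 551.9)
        shifted = shift_template(builtin_template("L"), delta)
        assert shifted.lambda_max() == pytest.approx(551.9 - 3.5, abs=0.1)
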