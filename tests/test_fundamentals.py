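"""Assembly of corneal cone fundamentals: self-screening, filtering, units."""

import numpy as np
import pytest

from conefund import (
    FilterScaling,
    ObserverParameters,
    SpectralFunction,
    absorptance,
    builtin_template,
    compute_fundamentals,
    corneal_quantal,
    find_lambda_max,
    standard_observer,
    tabulate,
    to_energy_normalized,
    total_prereceptoral_density,
)


def _fwhm(lam, vals):
    half = vals.max() / 2
    above = np.nonzero(vals >= half)[0]
    return lam[above[-1]] - lam[above[0]]


class TestAbsorptance:
    def test_closed_forms(self):
        sf = SpectralFunction(500.0, 1.0, [1.0, 0.0], "linear_absorbance")
        out = absorptance(sf, 0.5)
        assert out.values[0] == pytest.approx(1 - 10 ** -0.5, rel=1e-12)  # 0.68377
        assert out.values[1] == 0.0
        assert absorptance(sf, 0.4).values[0] == pytest.approx(0.60189, abs=5e-6)

    def test_od_must_be_positive(self):
        sf = SpectralFunction(500.0, 1.0, [1.0], "linear_absorbance")
        with pytest.raises(ValueError):
            absorptance(sf, 0.0)

    @pytest.mark.parametrize("cone", ["L", "M", "S"])
    def test_self_screening_broadens_without_moving_peak(self, cone):
        lin = tabulate(builtin_template(cone), 360.0, 850.0, 0.1, linear=True)
        widths, peaks = [], []
        for od in (0.2, 0.4, 0.6, 1.0):
            a = absorptance(lin, od)
            widths.append(_fwhm(a.wavelengths, a.values))
            peaks.append(find_lambda_max(a))
        assert all(w2 >= w1 for w1, w2 in zip(widths, widths[1:]))
        assert widths[-1] > widths[0]
        assert len(set(peaks)) == 1 and peaks[0] == find_lambda_max(lin)


class TestCornealFiltering:
    def test_equals_absorptance_where_filters_vanish(self):
        lin = tabulate(builtin_template("L"), 390.0, 830.0, 1.0, linear=True)
        a = absorptance(lin, 0.5)
        q = corneal_quantal(a, FilterScaling(1.0, 1.0))
        lam = a.wavelengths
        beyond = lam > 660.0
        assert np.array_equal(q.values[beyond], a.values[beyond])
        assert np.all(q.values[~beyond] <= a.values[~beyond])

    def test_zero_scalings_are_identity(self):
        lin = tabulate(builtin_template("M"), 390.0, 830.0, 1.0, linear=True)
        a = absorptance(lin, 0.5)
        q = corneal_quantal(a, FilterScaling(0.0, 0.0))
        assert np.array_equal(q.values, a.values)

    def test_definition_at_460(self):
        lin = tabulate(builtin_template("S"), 390.0, 830.0, 1.0, linear=True)
        a = absorptance(lin, 0.4)
        q = corneal_quantal(a, FilterScaling(1.0, 1.0))
        dens = total_prereceptoral_density(460.0, FilterScaling(1.0, 1.0))
        assert q.value_at(460.0) == pytest.approx(
            a.value_at(460.0) * 10 ** -dens, rel=1e-12)


class TestEnergyConversion:
    def test_peak_is_exactly_one(self, fund2):
        for ch in fund2.channels().values():
            assert float(ch.values.max()) == 1.0

    def test_constant_input_becomes_proportional_to_lambda(self):
        sf = SpectralFunction(400.0, 1.0, np.ones(101), "quantal_sensitivity")
        out, alpha = to_energy_normalized(sf)
        assert find_lambda_max(out) == out.lambda_end
        assert np.allclose(out.values, out.wavelengths / out.lambda_end, rtol=1e-12)

    def test_energy_peak_at_longer_wavelength(self, fund2, fund2_quantal):
        for ch in ("L", "M", "S"):
            lam_e = find_lambda_max(fund2.channels()[ch])
            lam_q = find_lambda_max(fund2_quantal.channels()[ch])
            assert lam_e >= lam_q

    def test_all_zero_rejected(self):
        sf = SpectralFunction(400.0, 1.0, np.zeros(5), "quantal_sensitivity")
        with pytest.raises(ValueError):
            to_energy_normalized(sf)

    def test_conversion_commutes_with_filtering_up_to_scale(self):
        # multiplying by lambda before vs after the corneal filter differs
        # only by the unit-peak renormalisation
        lin = tabulate(builtin_template("L"), 390.0, 830.0, 1.0, linear=True)
        a = absorptance(lin, 0.5)
        after, _ = to_energy_normalized(corneal_quantal(a))
        pre = a.with_values(a.values * a.wavelengths / a.wavelengths[-1])
        before = corneal_quantal(pre)
        before_n = before.values / before.values.max()
        assert np.allclose(after.values, before_n, rtol=0, atol=1e-12)


class TestStandardObservers:
    def test_parameter_sets(self):
        o2 = standard_observer("deg2")
        assert (o2.l_od, o2.m_od, o2.s_od) == (0.50, 0.50, 0.40)
        assert (o2.scaling.k_mac, o2.scaling.k_lens) == (1.0, 1.0)
        o10 = standard_observer("deg10")
        assert (o10.l_od, o10.m_od, o10.s_od) == (0.38, 0.38, 0.30)
        assert o10.scaling.k_mac == 0.271 and o10.scaling.k_lens == 1.0

    def test_od_validation(self):
        with pytest.raises(ValueError):
            ObserverParameters(l_od=0.0)
        with pytest.raises(ValueError):
            ObserverParameters(s_od=2.5)


class TestComputeFundamentals:
    def test_strictly_positive_over_tabulation_range(self, fund2, fund10):
        for fund in (fund2, fund10):
            for ch in fund.channels().values():
                assert np.all(ch.values > 0.0)

    def test_quantal_also_unit_peak_with_alpha_recorded(self, fund2_quantal):
        f = fund2_quantal
        assert f.units == "quantal"
        for ch in f.channels().values():
            assert float(ch.values.max()) == 1.0
        assert f.alpha_l > 0 and f.alpha_m > 0 and f.alpha_s > 0

    def test_increasing_lens_density_depresses_s_short_limb(self):
        obs_lo = ObserverParameters(scaling=FilterScaling(1.0, 0.5))
        obs_hi = ObserverParameters(scaling=FilterScaling(1.0, 1.5))
        s_lo = compute_fundamentals(obs_lo).S
        s_hi = compute_fundamentals(obs_hi).S
        lam = s_lo.wavelengths
        short = lam <= 440.0  # short-wave limb, below the S peak
        assert np.all(s_hi.values[short] < s_lo.values[short])

    def test_l_variant_changes_peak(self):
        ser = compute_fundamentals(ObserverParameters(l_variant="ser180"))
        ala = compute_fundamentals(ObserverParameters(l_variant="ala180"))
        assert find_lambda_max(ser.L) > find_lambda_max(ala.L)

    def test_shifted_observer_moves_fundamental_peak(self):
        from conefund import nm_shift_to_log10
        obs = ObserverParameters(shift_m=nm_shift_to_log10(10.0, 529.8))
        base = compute_fundamentals()
        shifted = compute_fundamentals(obs)
        assert find_lambda_max(shifted.M) > find_lambda_max(base.M)

    def test_ten_deg_s_peak_longer_than_two_deg(self, fund2, fund10):
        # macular pigment absorbs most near 460 nm, on the S cone's long-wave
        # limb; the sparser 10-deg macular screening lifts that limb and
        # moves the corneal S peak to longer wavelengths
        assert find_lambda_max(fund10.S) >= find_lambda_max(fund2.S)
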