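"""Weibull release, f2 similarity and virtual-formulation construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumenvbe import formulation as fm


GRID = fm.default_f2_grid()


def linear_profile(offset=0.0):
    return fm.DissolutionProfile(GRID, np.clip(np.linspace(5, 90, GRID.size) + offset, 0, 100))


class TestWeibull:
    def test_release_zero_at_lag_and_asymptote(self):
        p = fm.WeibullParams(80.0, 2.0, 1.2, t_lag=1.0)
        assert fm.evaluate_weibull(p, 1.0) == 0.0
        assert fm.evaluate_weibull(p, 0.5) == 0.0
        assert fm.evaluate_weibull(p, 1e6) == pytest.approx(80.0, rel=1e-12)

    def test_characteristic_time_gives_63_percent(self):
        # at t with t^beta = alpha the exponent is exactly -1
        p = fm.ENTOCORT_WEIBULL
        t = p.alpha ** (1.0 / p.beta)
        assert t == pytest.approx(3.355, abs=5e-3)
        assert fm.evaluate_weibull(p, t) == pytest.approx(100 * (1 - np.exp(-1)), rel=1e-9)

    def test_monotone_and_bounded(self):
        p = fm.WeibullParams(95.0, 3.0, 0.8)
        t = np.linspace(0, 48, 400)
        y = fm.evaluate_weibull(p, t)
        assert np.all(np.diff(y) >= 0)
        assert np.all(y <= 95.0)

    @pytest.mark.parametrize("bad", [
        dict(f_max=0.0, alpha=1, beta=1),
        dict(f_max=101.0, alpha=1, beta=1),
        dict(f_max=50, alpha=-1, beta=1),
        dict(f_max=50, alpha=1, beta=0),
        dict(f_max=50, alpha=1, beta=1, t_lag=-0.5),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            fm.WeibullParams(**bad)

    def test_roundtrip_recovers_parameters(self):
        truth = fm.WeibullParams(100.0, 3.12, 0.94, 0.0)
        t = np.array([0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12], float)
        prof = fm.DissolutionProfile(t, fm.evaluate_weibull(truth, t))
        fit, rss = fm.fit_weibull(prof, fix_fmax=100.0)
        assert fit.alpha == pytest.approx(truth.alpha, rel=1e-4)
        assert fit.beta == pytest.approx(truth.beta, rel=1e-4)
        assert rss < 1e-10

    def test_fit_with_noise_close_to_truth(self, rng):
        truth = fm.WeibullParams(100.0, 3.12, 0.94, 0.0)
        units = fm.generate_dissolution_replicates(truth, cv=2.0, n_units=1, seed=11)
        fit, _ = fm.fit_weibull(units[0], fix_fmax=100.0)
        assert fit.alpha == pytest.approx(truth.alpha, rel=0.10)
        assert fit.beta == pytest.approx(truth.beta, rel=0.10)

    def test_fit_rejects_flat_zero_profile(self):
        prof = fm.DissolutionProfile(GRID, np.zeros(GRID.size))
        with pytest.raises(ValueError, match="no release"):
            fm.fit_weibull(prof)


class TestProfileInvariants:
    def test_rejects_decreasing_release(self):
        with pytest.raises(ValueError):
            fm.DissolutionProfile([1, 2, 3, 4], [10, 20, 15, 30])

    def test_rejects_non_increasing_times(self):
        with pytest.raises(ValueError):
            fm.DissolutionProfile([1, 2, 2, 3], [1, 2, 3, 4])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fm.DissolutionProfile([1, 2, 3], [10, 50, 101])


class TestF2:
    def test_identical_profiles_give_100(self):
        a = linear_profile()
        assert fm.similarity_f2(a, a) == pytest.approx(100.0)

    def test_constant_10_point_offset_is_50(self):
        # the regulatory boundary: 10%-point shift at every time -> f2 ~ 50
        ref = fm.DissolutionProfile(GRID, np.linspace(2, 80, GRID.size))
        test = fm.DissolutionProfile(GRID, np.linspace(2, 80, GRID.size) + 10)
        f2 = fm.similarity_f2(ref, test)
        assert f2 == pytest.approx(50 * np.log10(100 / np.sqrt(101)), abs=1e-9)
        assert round(f2) == 50

    def test_constant_5_point_offset_closed_form(self):
        ref = linear_profile()
        test = fm.DissolutionProfile(GRID, ref.released + 5)
        assert fm.similarity_f2(ref, test) == pytest.approx(
            50 * np.log10(100 / np.sqrt(26)), abs=1e-9
        )
        assert fm.similarity_f2(ref, test) == pytest.approx(64.63, abs=0.005)

    def test_offset_independent_of_grid_size(self):
        for n in (3, 7, 20):
            t = np.linspace(0.5, 12, n)
            a = fm.DissolutionProfile(t, np.linspace(0, 85, n))
            b = fm.DissolutionProfile(t, np.linspace(0, 85, n) + 10)
            assert round(fm.similarity_f2(a, b)) == 50

    def test_mismatched_grids_error(self):
        a = linear_profile()
        b = fm.DissolutionProfile(GRID + 0.25, a.released)
        with pytest.raises(ValueError, match="time grid"):
            fm.similarity_f2(a, b)

    @given(offset=st.floats(1.0, 30.0))
    @settings(max_examples=30, deadline=None)
    def test_symmetry(self, offset):
        base = np.linspace(0, 70, GRID.size)
        a = fm.DissolutionProfile(GRID, base)
        b = fm.DissolutionProfile(GRID, base + offset)
        assert fm.similarity_f2(a, b) == pytest.approx(fm.similarity_f2(b, a), rel=1e-12)

    def test_strictly_decreasing_in_offset(self):
        base = np.linspace(0, 70, GRID.size)
        a = fm.DissolutionProfile(GRID, base)
        vals = [
            fm.similarity_f2(a, fm.DissolutionProfile(GRID, base + off))
            for off in range(1, 31)
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))
        assert all(v < 100 for v in vals)


class TestBootstrapF2:
    def test_identical_units_degenerate(self):
        units = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, cv=0.0, n_units=4)
        res = fm.bootstrap_f2(units, units, n_boot=200, seed=1)
        assert res["f2"] == pytest.approx(100.0)
        assert res["ci_high"] - res["ci_low"] == pytest.approx(0.0)

    def test_cv0_equals_plain_f2_of_means(self):
        ref = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 0.0, 3)
        shifted = fm.WeibullParams(100.0, 2.14, 0.89)
        tst = fm.generate_dissolution_replicates(shifted, 0.0, 3)
        res = fm.bootstrap_f2(ref, tst, n_boot=200, seed=1)
        assert res["f2"] == pytest.approx(fm.similarity_f2(ref[0], tst[0]), rel=1e-12)

    def test_ci_covers_true_f2_under_noise(self):
        truth_ref = fm.ENTOCORT_WEIBULL
        truth_tst = fm.WeibullParams(100.0, 2.56, 0.91)
        ref = fm.generate_dissolution_replicates(truth_ref, 3.0, 12, seed=5)
        tst = fm.generate_dissolution_replicates(truth_tst, 3.0, 12, seed=6)
        grid = fm.default_f2_grid()
        true_f2 = fm.similarity_f2(
            fm.DissolutionProfile(grid, fm.evaluate_weibull(truth_ref, grid)),
            fm.DissolutionProfile(grid, fm.evaluate_weibull(truth_tst, grid)),
        )
        res = fm.bootstrap_f2(ref, tst, n_boot=500, seed=7)
        assert res["ci_low"] <= true_f2 <= res["ci_high"]

    def test_small_n_boot_warns(self):
        units = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 1.0, 3, seed=2)
        with pytest.warns(UserWarning, match="n_boot"):
            fm.bootstrap_f2(units, units, n_boot=50, seed=3)

    def test_requires_two_units(self):
        units = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 0.0, 1)
        with pytest.raises(ValueError):
            fm.bootstrap_f2(units, units)


class TestReplicateGenerator:
    def test_cv0_identical_units(self):
        units = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 0.0, 5)
        for u in units[1:]:
            np.testing.assert_array_equal(u.released, units[0].released)

    def test_large_sample_mean_near_noiseless(self):
        # at assay-typical CV 2% the cumulative-max monotonisation bias near
        # the plateau stays inside the 1% law-of-large-numbers band
        units = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 2.0, 10_000, seed=3)
        mean = np.mean([u.released for u in units], axis=0)
        base = fm.evaluate_weibull(fm.ENTOCORT_WEIBULL, fm.default_f2_grid())
        np.testing.assert_allclose(mean, base, rtol=0.01)

    def test_single_unit_valid(self):
        (unit,) = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 2.0, 1, seed=4)
        assert np.all(np.diff(unit.released) >= 0)
        assert unit.released.max() <= 100.0


class TestVirtualFormulation:
    def test_delta_zero_is_identity(self):
        ref = fm.reference_profile()
        virt = fm.make_virtual_formulation(ref, delta=0.0)
        assert virt.f2_vs_reference == pytest.approx(100.0)

    def test_delta_shifts_midcurve_and_completes(self):
        ref = fm.reference_profile()
        mid = ref.released[5]
        virt = fm.make_virtual_formulation(ref, delta=10.0)
        regenerated = np.minimum(ref.released + 10, 100.0)
        assert regenerated[5] == pytest.approx(mid + 10)
        prof = virt.profile()
        assert prof.released[-1] > 95.0  # refit honours the 12 h completion

    def test_plus20_completes_at_7h(self):
        ref = fm.reference_profile()
        y = np.minimum(ref.released + 20, 100.0)
        t = ref.times
        # the construction forces 100% from 7 h onwards for the +20 variant
        virt = fm.make_virtual_formulation(ref, delta=20.0)
        assert fm.evaluate_weibull(virt.weibull, 7.0) > 93.0
        assert virt.weibull.alpha < fm.ENTOCORT_WEIBULL.alpha

    def test_trigger_mode_keeps_curve(self):
        ref = fm.reference_profile()
        virt = fm.make_virtual_formulation(ref, trigger_ph=6.0)
        base, _ = fm.fit_weibull(ref, fix_fmax=100.0)
        assert virt.trigger_ph == 6.0
        assert virt.weibull.alpha == pytest.approx(base.alpha, rel=1e-9)
        assert virt.weibull.beta == pytest.approx(base.beta, rel=1e-9)

    def test_requires_exactly_one_mode(self):
        ref = fm.reference_profile()
        with pytest.raises(ValueError):
            fm.make_virtual_formulation(ref)
        with pytest.raises(ValueError):
            fm.make_virtual_formulation(ref, delta=5.0, trigger_ph=6.0)

    def test_negative_release_rejected(self):
        ref = fm.reference_profile()
        with pytest.raises(ValueError, match="negative"):
            fm.make_virtual_formulation(ref, delta=-30.0)

    def test_small_delta_f2_matches_closed_form_on_uncapped_points(self):
        ref = fm.reference_profile()
        delta = 3.0
        uncapped = ref.released + delta < 100.0
        virt_prof_y = np.minimum(ref.released + delta, 100.0)
        virt_prof_y[ref.times >= 12.0] = 100.0
        n = int(uncapped.sum())
        f2_restricted = 50 * np.log10(100 / np.sqrt(1 + delta**2))
        sub_ref = fm.DissolutionProfile(ref.times[uncapped], ref.released[uncapped])
        sub_tst = fm.DissolutionProfile(ref.times[uncapped], virt_prof_y[uncapped])
        assert fm.similarity_f2(sub_ref, sub_tst) == pytest.approx(f2_restricted, abs=0.01)

    def test_library_has_eight_members(self, virtual_panel):
        assert len(virtual_panel) == 8
        assert {"+20%", "+10%", "+5%", "+3%", "-5%", "-10%"}.issubset(virtual_panel)

    def test_library_trigger_variants_carry_reference_weibull(self, virtual_panel):
        # a trigger-pH change does not alter the release curve itself
        for label, ph in [("pH threshold = 5", 5.0), ("pH threshold = 6", 6.0)]:
            assert virtual_panel[label].weibull == fm.ENTOCORT_WEIBULL
            assert virtual_panel[label].trigger_ph == ph


class TestIO:
    def test_profile_csv_roundtrip(self, tmp_path):
        units = fm.generate_dissolution_replicates(fm.ENTOCORT_WEIBULL, 2.0, 3, seed=9)
        path = tmp_path / "units.csv"
        fm.write_profile_csv(path, units)
        back = fm.read_profile_csv(path)
        assert len(back) == 3
        np.testing.assert_allclose(back[1].released, units[1].released)

    def test_library_json_roundtrip(self, tmp_path, virtual_panel):
        path = tmp_path / "lib.json"
        fm.write_library_json(path, list(virtual_panel.values()))
        back = fm.read_library_json(path)
        assert [f.label for f in back] == list(virtual_panel)
        assert back[0].weibull == list(virtual_panel.values())[0].weibull
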