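"""DEER kernel, processing chain, and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pdsfil as p
from pdsfil import deer
from pdsfil.errors import DegenerateInputError, ParameterError

from conftest import pure_form_factor


def brute_force_kernel(r_ang, t_us, n=100_000):
    """Independent oracle: quadrature over cos θ ∈ [0, 1]."""
    x = np.linspace(0.0, 1.0, n)
    w = 2 * np.pi * deer.DIPOLAR_CONSTANT_MHZ_NM3 / (r_ang / 10.0) ** 3
    return np.array([np.trapezoid(np.cos(w * t * (1 - 3 * x**2)), x)
                     for t in np.atleast_1d(t_us)])


class TestDipolarKernel:
    def test_unity_at_time_zero(self):
        assert deer.dipolar_kernel(np.array([15.0, 30.0, 80.0]), 0.0) \
            == pytest.approx([1.0, 1.0, 1.0])

    def test_bounded_and_decaying(self):
        t = np.linspace(0, 5, 400)
        k = deer.dipolar_kernel(25.0, t)
        assert np.all(np.abs(k) <= 1.0 + 1e-12)
        # damped toward the powder-average limit: late-time envelope small
        assert np.abs(k[t > 3]).max() < 0.2

    @pytest.mark.parametrize("r", [20.0, 30.0, 45.0, 70.0])
    def test_matches_quadrature_oracle(self, r):
        t = np.linspace(0.0, 3.0, 40)
        assert np.abs(deer.dipolar_kernel(r, t)
                      - brute_force_kernel(r, t)).max() < 1e-6

    def test_rejects_nonpositive_distance(self):
        with pytest.raises(ParameterError):
            deer.dipolar_kernel(0.0, 1.0)


class TestBackgroundRemoval:
    def test_pure_exponential_gives_constant(self):
        t = deer.DEFAULT_TIME_GRID
        tr = deer.DeerTrace(t, 2.0 * np.exp(-0.3 * t), "raw")
        u, fit = deer.remove_background(tr, order=1)
        assert np.abs(u.amplitude / u.amplitude[0] - 1.0).max() < 1e-10
        assert fit.coefficients[0] == pytest.approx(-0.3)

    def test_order_zero_on_flat_trace_is_identity(self):
        t = deer.DEFAULT_TIME_GRID
        tr = deer.DeerTrace(t, np.full_like(t, 0.8), "raw")
        u, _ = deer.remove_background(tr, order=0)
        assert u.amplitude == pytest.approx(np.ones_like(t))

    def test_recovers_form_factor_of_synthetic_trace(self):
        spec = p.SyntheticDeerSpec(
            distribution_components=[(30.0, 2.0, 1.0)], noise_sd=0.0)
        tr, truth = p.synthetic_deer(spec)
        u, _ = deer.remove_background(tr)
        ff = u.amplitude / u.amplitude[0]
        expected = 1.0 - 0.3 * (1.0 - deer.form_factor(truth, tr.time))
        assert np.abs(ff - expected).max() < 0.02

    def test_nonpositive_tail_raises(self):
        t = deer.DEFAULT_TIME_GRID
        amp = np.exp(-t)
        amp[-5:] = -1.0
        with pytest.raises(ParameterError, match="log"):
            deer.remove_background(deer.DeerTrace(t, amp, "raw"))


class TestNormalization:
    def test_constant_two_becomes_one(self):
        t = deer.DEFAULT_TIME_GRID
        tr = deer.DeerTrace(t, np.full_like(t, 2.0), "background_free")
        out = deer.normalize_form_factor(tr)
        assert out.amplitude == pytest.approx(np.ones_like(t))
        assert out.amplitude[0] == 1.0

    def test_scale_invariance(self):
        t = deer.DEFAULT_TIME_GRID
        amp = 1.0 - 0.3 * (1.0 - deer.dipolar_kernel(40.0, t))
        a = deer.normalize_form_factor(
            deer.DeerTrace(t, amp, "background_free"))
        b = deer.normalize_form_factor(
            deer.DeerTrace(t, 5.0 * amp, "background_free"))
        assert a.amplitude == pytest.approx(b.amplitude)

    def test_nonpositive_start_raises(self):
        t = deer.DEFAULT_TIME_GRID
        with pytest.raises(ParameterError):
            deer.normalize_form_factor(
                deer.DeerTrace(t, np.zeros_like(t), "background_free"))


class TestModulationDepth:
    def test_flat_unity_gives_zero(self):
        t = deer.DEFAULT_TIME_GRID
        assert deer.modulation_depth(
            deer.DeerTrace(t, np.ones_like(t), "form_factor")) == 0.0

    def test_tail_plateau(self):
        t = deer.DEFAULT_TIME_GRID
        amp = np.concatenate([np.linspace(1, 0.49, len(t) - 100),
                              np.full(100, 0.49)])
        tr = deer.DeerTrace(t, amp, "form_factor")
        assert deer.modulation_depth(tr) == pytest.approx(0.51)

    def test_three_spin_depth_closed_form(self):
        # fully-labeled 3-spin system at pump efficiency 0.3: 1-(1-λ)² = 0.51
        spec = p.SyntheticDeerSpec(
            distribution_components=[(30.0, 2.0, 1.0)], n_spins=3,
            noise_sd=0.0)
        tr, _ = p.synthetic_deer(spec)
        res = deer.full_reconstruction(tr, use_mem=False)
        assert res.depth == pytest.approx(0.51, abs=0.02)

    def test_short_record_warns(self):
        t = np.linspace(0, 0.05, 8)
        tr = deer.DeerTrace(t, np.linspace(1, 0.9, 8), "form_factor")
        with pytest.warns(UserWarning, match="best-effort"):
            deer.modulation_depth(tr)


class TestTikhonovInversion:
    def test_noiseless_gaussian_round_trip(self, r_grid):
        truth = p.synthetic_data.mixture_distribution([(45.0, 1.5, 1.0)])
        ff = pure_form_factor(truth, deer.DEFAULT_TIME_GRID)
        rec = deer.tikhonov_invert(ff, alpha=1e-4)
        assert abs(rec.mode - 45.0) <= r_grid[1] - r_grid[0]

    def test_bimodal_weights_recovered(self, r_grid):
        truth = p.synthetic_data.mixture_distribution(
            [(30.0, 1.5, 0.5), (45.0, 1.5, 0.5)])
        ff = pure_form_factor(truth, deer.DEFAULT_TIME_GRID)
        rec = deer.tikhonov_invert(ff, alpha=1e-3)
        modes = rec.modes()[:2]
        assert sorted(round(m) for m in modes) == pytest.approx([30, 45],
                                                                abs=1)
        cut = rec.r <= 37.5
        w_low = np.trapezoid(rec.density[cut], rec.r[cut])
        assert w_low == pytest.approx(0.5, abs=0.1)

    def test_density_nonnegative_for_rough_input(self):
        rng = np.random.default_rng(0)
        t = deer.DEFAULT_TIME_GRID
        amp = 1.0 - 0.3 * (1.0 - deer.dipolar_kernel(35.0, t))
        amp = amp + rng.normal(0, 0.02, amp.shape)
        amp[0] = 1.0
        rec = deer.tikhonov_invert(deer.DeerTrace(t, amp, "form_factor"),
                                   alpha=1e-2)
        assert np.all(rec.density >= 0)

    def test_flat_trace_is_degenerate(self):
        t = deer.DEFAULT_TIME_GRID
        tr = deer.DeerTrace(t, np.ones_like(t), "form_factor")
        with pytest.raises(DegenerateInputError):
            deer.tikhonov_invert(tr, alpha=1e-3)

    @settings(max_examples=8, deadline=None, derandomize=True)
    @given(mean=st.floats(15.0, 80.0), sd=st.floats(1.0, 5.0))
    def test_single_gaussian_mode_recovery_property(self, mean, sd):
        truth = p.synthetic_data.mixture_distribution([(mean, sd, 1.0)])
        # record long enough for ~2.5 dipolar periods at the target distance
        tmax = max(3.0, 2.5 * (mean / 10.0) ** 3
                   / deer.DIPOLAR_CONSTANT_MHZ_NM3)
        t = np.linspace(0.0, tmax, 400)
        rec = deer.tikhonov_invert(pure_form_factor(truth, t), alpha=1e-4)
        assert abs(rec.mode - truth.mode) <= 0.5 + 1e-9


class TestAlphaSelection:
    def _noisy_ff(self, components, noise, seed):
        spec = p.SyntheticDeerSpec(distribution_components=components,
                                   noise_sd=noise, seed=seed)
        tr, truth = p.synthetic_deer(spec)
        u, _ = deer.remove_background(tr)
        return deer.normalize_form_factor(u), truth

    def test_returns_member_of_candidates(self):
        ff, _ = self._noisy_ff([(40.0, 2.0, 1.0)], 0.01, 1)
        sel = deer.select_alpha(ff)
        assert sel.alpha in sel.alphas

    def test_residual_monotone_in_alpha(self):
        ff, _ = self._noisy_ff([(40.0, 2.0, 1.0)], 0.0, 1)
        sel = deer.select_alpha(ff)
        assert np.all(np.diff(sel.residual_norms) >= -1e-10)

    def test_corner_resolves_bimodal_while_oversmoothing_fails(self):
        ff, truth = self._noisy_ff([(30.0, 1.5, 0.5), (45.0, 1.5, 0.5)],
                                   0.01, 7)
        cands = np.logspace(-4, 4, 25)
        sel = deer.select_alpha(ff, cands)
        good = deer.tikhonov_invert(ff, alpha=sel.alpha)
        over = deer.tikhonov_invert(ff, alpha=cands[-1])
        top = sorted(good.modes()[:2])
        assert abs(top[0] - 30.0) <= 2.0 and abs(top[1] - 45.0) <= 2.0
        assert not (len(over.modes()) >= 2
                    and abs(sorted(over.modes()[:2])[0] - 30.0) <= 2.0
                    and abs(sorted(over.modes()[:2])[1] - 45.0) <= 2.0)

    def test_candidate_validation(self):
        ff, _ = self._noisy_ff([(40.0, 2.0, 1.0)], 0.01, 1)
        with pytest.raises(ParameterError):
            deer.select_alpha(ff, [1e-3, 1e-2])
        with pytest.raises(ParameterError):
            deer.select_alpha(ff, [1e-3, 2e-3, 4e-3])


class TestMemRefinement:
    def test_truth_is_fixed_point_on_noiseless_data(self):
        truth = p.synthetic_data.mixture_distribution([(45.0, 1.5, 1.0)])
        ff = pure_form_factor(truth, deer.DEFAULT_TIME_GRID)
        out = deer.mem_refine(truth, ff)
        assert truth.total_variation(out.distribution) < 1e-3

    def test_misfit_contract(self):
        spec = p.SyntheticDeerSpec(
            distribution_components=[(40.0, 2.0, 1.0)], noise_sd=0.01,
            seed=2)
        tr, _ = p.synthetic_deer(spec)
        u, _ = deer.remove_background(tr)
        ff = deer.normalize_form_factor(u)
        initial = deer.tikhonov_invert(ff)
        K = deer.kernel_matrix(ff.time, initial.r)
        m0 = deer._misfit(K, ff.amplitude, initial.density, initial.r)[0]
        out = deer.mem_refine(initial, ff)
        assert out.misfit <= m0 * 1.05 + 1e-12

    def test_side_lobes_not_amplified(self):
        spec = p.SyntheticDeerSpec(
            distribution_components=[(40.0, 2.0, 1.0)], noise_sd=0.01,
            seed=9)
        tr, truth = p.synthetic_deer(spec)
        u, _ = deer.remove_background(tr)
        ff = deer.normalize_form_factor(u)
        initial = deer.tikhonov_invert(ff)
        out = deer.mem_refine(initial, ff).distribution

        def side_peak_ratio(d):
            # height of the tallest spurious peak relative to the main one
            from scipy.signal import find_peaks

            idx, props = find_peaks(d.density, height=0)
            side = [h for i, h in zip(idx, props["peak_heights"])
                    if abs(d.r[i] - truth.mode) > 8.0]
            return max(side, default=0.0) / d.density.max()

        assert side_peak_ratio(initial) < 0.05
        assert side_peak_ratio(out) <= side_peak_ratio(initial) + 0.01


class TestFullReconstruction:
    @pytest.mark.parametrize("mean", [20.0, 45.0, 60.0])
    def test_noiseless_round_trip_within_one_grid_step(self, mean):
        # record covering >= 2.5 dipolar periods of the target distance,
        # so the tail background fit sees an oscillation-averaged signal
        tmax = max(3.0, 2.5 * (mean / 10.0) ** 3
                   / deer.DIPOLAR_CONSTANT_MHZ_NM3)
        spec = p.SyntheticDeerSpec(
            distribution_components=[(mean, 1.5, 1.0)],
            time_grid=np.linspace(0.0, tmax, 400), noise_sd=0.0)
        tr, truth = p.synthetic_deer(spec)
        res = deer.full_reconstruction(tr)
        assert abs(res.distribution.mode - truth.mode) <= 0.5 + 1e-9

    def test_deterministic_for_fixed_input(self):
        spec = p.SyntheticDeerSpec(
            distribution_components=[(35.0, 2.0, 1.0)], noise_sd=0.005,
            seed=11)
        tr, _ = p.synthetic_deer(spec)
        a = deer.full_reconstruction(tr)
        b = deer.full_reconstruction(tr)
        assert np.array_equal(a.distribution.density, b.distribution.density)
        assert a.depth == b.depth and a.alpha == b.alpha


class TestTraceIO:
    def test_tsv_round_trip(self, tmp_path):
        spec = p.SyntheticDeerSpec(
            distribution_components=[(40.0, 2.0, 1.0)], noise_sd=0.002,
            seed=3)
        tr, truth = p.synthetic_deer(spec)
        deer.write_trace(tr, tmp_path / "t.tsv")
        back = deer.read_trace(tmp_path / "t.tsv")
        assert np.allclose(back.amplitude, tr.amplitude)
        assert back.metadata["seed"] == 3
        deer.write_distribution(truth, tmp_path / "d.tsv")
        d = deer.read_distribution(tmp_path / "d.tsv")
        assert np.allclose(d.density, truth.density)
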