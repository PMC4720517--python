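"""Label clouds, filament mixtures, dilution inference."""

import math

import numpy as np
import pytest

import pdsfil as p
from pdsfil import spin_labels as sl, synthetic_data as sd
from pdsfil.errors import (
    BuriedSiteError,
    EmptyMixtureError,
    GridError,
    ParameterError,
)
from pdsfil.filament import Structure


class TestAttachLabel:
    def test_centroid_within_tether_bounds(self, helix45):
        cloud = p.attach_label(helix45, ("A", 20), seed=0)
        d = np.linalg.norm(cloud.centroid()
                           - helix45.coords[helix45.atom_index("A", 20)])
        assert 4.0 <= d <= 10.0

    def test_deterministic_for_fixed_seed(self, helix45):
        a = p.attach_label(helix45, ("A", 20), seed=5)
        b = p.attach_label(helix45, ("A", 20), seed=5)
        assert np.array_equal(a.points, b.points)

    def test_occluding_helix_reduces_acceptance(self, helix45):
        free = p.attach_label(helix45, ("A", 15), seed=0)
        ca = helix45.coords[helix45.atom_index("A", 15)]
        near = helix45.coords[
            np.sum((helix45.coords - ca) ** 2, axis=1) <= 144.0]
        outward = ca - near.mean(axis=0)
        outward /= np.linalg.norm(outward)
        other = p.ideal_helix(p.HelixSpec(30), chain="B")
        blocker = other.transformed(
            translation=ca + 6.0 * outward - other.coords[14])
        both = Structure.concatenate([helix45, blocker])
        occluded = p.attach_label(both, ("A", 15), seed=0)
        assert len(occluded.points) < len(free.points)

    def test_buried_site_raises_with_site_name(self, helix45):
        from pdsfil.filament import _sphere_points

        ca = helix45.coords[helix45.atom_index("A", 20)]
        cage = np.vstack([r * _sphere_points(400) for r in (4.0, 6.0, 8.0)])
        cage_s = Structure.from_arrays(ca + cage, chain_ids="C")
        buried = Structure.concatenate([helix45, cage_s])
        with pytest.raises(BuriedSiteError, match="A/20"):
            p.attach_label(buried, ("A", 20), seed=0)


class TestPairDistribution:
    def test_two_single_point_clouds_give_delta(self, r_grid):
        a = sl.LabelCloud(("A", 1), [[0.0, 0.0, 0.0]], [1.0])
        b = sl.LabelCloud(("A", 2), [[45.0, 0.0, 0.0]], [1.0])
        d = sl.pair_distribution(a, b, r_grid, smoothing_sd=0.0)
        assert d.mode == pytest.approx(45.0)
        assert np.sum(d.density > 0) == 1

    def test_symmetric_in_arguments(self, helix_label_pair):
        a, b = helix_label_pair
        assert np.allclose(sl.pair_distribution(a, b).density,
                           sl.pair_distribution(b, a).density)

    def test_helix_pair_fwhm_in_experimental_range(self, helix_label_pair):
        # MTSL pair-distribution widths are 0.4-1.2 nm FWHM
        a, b = helix_label_pair
        d = sl.pair_distribution(a, b)
        assert 4.0 <= d.fwhm() <= 12.0

    def test_grid_not_covering_support_raises(self):
        a = sl.LabelCloud(("A", 1), [[0.0, 0.0, 0.0]], [1.0])
        b = sl.LabelCloud(("A", 2), [[120.0, 0.0, 0.0]], [1.0])
        with pytest.raises(GridError):
            sl.pair_distribution(a, b)


class TestFilamentSiteDistribution:
    def test_infinite_dilution_reduces_to_intra_pair(self, filament7,
                                                     open_protomer):
        sites = [open_protomer.meta["sites"]["site_a"],
                 open_protomer.meta["sites"]["site_b"]]
        spec = sl.DilutionSpec(labeled_to_unlabeled=math.inf,
                               labeled_sites_per_protomer=2)
        sig = sl.filament_site_distribution(filament7, spec, sites, seed=0)
        assert list(sig.component_weights) == \
            [k for k in sig.component_weights if k.startswith("intra")]
        assert sig.expected_spins == pytest.approx(2.0)
        # matches the isolated-protomer pair distribution
        a = p.attach_label(filament7.protomer, sites[0], seed=0)
        b = p.attach_label(filament7.protomer, sites[1], seed=17)
        iso = sl.pair_distribution(a, b)
        assert abs(sig.distribution.mode - iso.mode) <= 2.0

    def test_undiluted_single_label_mode_at_repeat(self, filament7,
                                                   open_protomer):
        spec = sl.DilutionSpec(labeled_to_unlabeled=0.0,
                               labeled_sites_per_protomer=1)
        sig = sl.filament_site_distribution(
            filament7, spec, [open_protomer.meta["sites"]["site_a"]],
            seed=0)
        assert sig.distribution.mode == pytest.approx(30.0, abs=1.0)
        assert sig.expected_spins == pytest.approx(3.0)

    def test_depth_strictly_decreases_with_dilution(self, filament7,
                                                    open_protomer):
        site = [open_protomer.meta["sites"]["site_a"]]
        depths = []
        for k in (0.0, 1.0, 2.0, 8.0):
            spec = sl.DilutionSpec(labeled_to_unlabeled=k,
                                   labeled_sites_per_protomer=1)
            depths.append(sl.filament_site_distribution(
                filament7, spec, site, seed=0).expected_depth)
        assert np.all(np.diff(depths) < 0)

    def test_mixture_weights_sum_to_one(self, filament7, open_protomer):
        sites = [open_protomer.meta["sites"]["site_a"],
                 open_protomer.meta["sites"]["site_b"]]
        spec = sl.DilutionSpec(labeled_to_unlabeled=2.0,
                               labeled_sites_per_protomer=2)
        sig = sl.filament_site_distribution(filament7, spec, sites, seed=0)
        assert sum(sig.component_weights.values()) == pytest.approx(1.0)

    def test_fully_diluted_single_label_is_empty(self, filament7,
                                                 open_protomer):
        spec = sl.DilutionSpec(labeled_to_unlabeled=math.inf,
                               labeled_sites_per_protomer=1)
        with pytest.raises(EmptyMixtureError):
            sl.filament_site_distribution(
                filament7, spec, [open_protomer.meta["sites"]["site_a"]],
                seed=0)


class TestEffectiveSpinCount:
    def test_depth_equal_lambda_means_pair(self):
        assert sl.effective_spin_count(0.3, 0.3).n_nearest == 2

    def test_three_spin_example(self):
        # 1 - 0.7² = 0.51
        out = sl.effective_spin_count(0.51, 0.3)
        assert out.n_effective == pytest.approx(3.0)
        assert out.n_nearest == 3

    def test_zero_depth_is_single_spin(self):
        assert sl.effective_spin_count(0.0, 0.3).n_nearest == 1

    @pytest.mark.parametrize("lam", [0.1, 0.3, 0.5])
    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5])
    def test_inverts_forward_depth_model_exactly(self, lam, n):
        depth = 1.0 - (1.0 - lam) ** (n - 1)
        assert sl.effective_spin_count(depth, lam).n_nearest == n

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            sl.effective_spin_count(1.0, 0.3)
        with pytest.raises(ParameterError):
            sl.effective_spin_count(-0.1, 0.3)


class TestDilutionSeriesAnalysis:
    def _series(self, filament, protomer, ratios, time_grid):
        sites = [protomer.meta["sites"]["site_a"],
                 protomer.meta["sites"]["site_b"]]
        traces = []
        for k in ratios:
            spec = sl.DilutionSpec(labeled_to_unlabeled=k,
                                   labeled_sites_per_protomer=2)
            sig = sl.filament_site_distribution(filament, spec, sites,
                                                seed=0)
            traces.append((k, sd.trace_from_distribution(
                sig.distribution, sig.expected_depth, time_grid=time_grid)))
        return traces

    def test_identical_traces_converge(self, long_time_grid):
        truth = sd.mixture_distribution([(45.0, 2.0, 1.0)])
        tr = sd.trace_from_distribution(truth, 0.3,
                                        time_grid=long_time_grid)
        rep = sl.dilution_series_analysis([(0.0, tr), (8.0, tr)])
        assert rep.converged
        assert rep.convergence_tv == pytest.approx(0.0, abs=1e-12)

    def test_removing_most_diluted_point_is_local(self, filament7,
                                                  open_protomer,
                                                  long_time_grid):
        traces = self._series(filament7, open_protomer, [0.0, 2.0, 8.0],
                              long_time_grid)
        full = sl.dilution_series_analysis(traces)
        short = sl.dilution_series_analysis(traces[:2])
        for e_full, e_short in zip(full.entries[:2], short.entries):
            assert e_full.dominant_mode == e_short.dominant_mode
            assert e_full.depth == e_short.depth
        assert short.intra_mode != full.intra_mode

    def test_requires_two_ratios_and_common_grid(self, long_time_grid):
        truth = sd.mixture_distribution([(45.0, 2.0, 1.0)])
        tr = sd.trace_from_distribution(truth, 0.3,
                                        time_grid=long_time_grid)
        with pytest.raises(ParameterError):
            sl.dilution_series_analysis([(0.0, tr)])
        other = sd.trace_from_distribution(truth, 0.3)
        with pytest.raises(ParameterError, match="grid"):
            sl.dilution_series_analysis([(0.0, tr), (8.0, other)])
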