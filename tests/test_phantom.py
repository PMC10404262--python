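"""Phantom generator: geometry, domain series, rendering, defect injection."""

import numpy as np
import pytest
from scipy import ndimage

from arborseg.phantom import (
    DomainSpec,
    PhantomSizingError,
    contrast_index,
    default_base_spec,
    histogram_overlap,
    inject_topology_defects,
    make_domain_series,
    make_label_phantom,
    render_intensities,
)
from arborseg.types import BACKGROUND, CSF, GM, WM


@pytest.fixture(scope="module")
def phantom64():
    return make_label_phantom((64, 64, 64), branch_depth=3, gm_thickness=2, seed=7)


class TestLabelPhantom:
    def test_contains_all_tissue_codes(self, phantom64):
        assert set(np.unique(phantom64.voxels)) == {BACKGROUND, CSF, GM, WM}

    def test_wm_single_26_connected_component(self, phantom64):
        _, n = ndimage.label(phantom64.voxels == WM, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_deterministic_given_seed(self):
        a = make_label_phantom((48, 48, 48), 3, 2, seed=11)
        b = make_label_phantom((48, 48, 48), 3, 2, seed=11)
        assert np.array_equal(a.voxels, b.voxels)
        c = make_label_phantom((48, 48, 48), 3, 2, seed=12)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_gm_is_a_shell(self, phantom64):
        """Every GM voxel touches a non-GM voxel in its 26-neighborhood."""
        gm = phantom64.voxels == GM
        fully_surrounded = ndimage.minimum_filter(
            gm.astype(np.uint8), footprint=np.ones((3, 3, 3)), mode="constant", cval=0
        ).astype(bool)
        frac_touching = 1.0 - fully_surrounded[gm].mean()
        assert frac_touching == 1.0

    def test_too_small_shape_rejected(self):
        with pytest.raises(PhantomSizingError):
            make_label_phantom((16, 16, 16), 3, 2, seed=0)
        with pytest.raises(PhantomSizingError):
            make_label_phantom((32, 32, 32), branch_depth=12, gm_thickness=2, seed=0)


class TestDomainSeries:
    def test_gap_decays_geometrically(self):
        base = default_base_spec()
        series = make_domain_series(base, 6, contrast_decay=0.3, noise_growth=0.0)
        g0 = abs(base.means[0, GM] - base.means[0, WM])
        for k, spec in enumerate(series):
            gap = abs(spec.means[0, GM] - spec.means[0, WM])
            assert gap == pytest.approx(g0 * 0.7**k, rel=1e-9)

    def test_contrast_index_strictly_decreasing(self):
        series = make_domain_series(default_base_spec(), 6, 0.3, 0.1)
        idx = [contrast_index(s) for s in series]
        assert all(a > b for a, b in zip(idx, idx[1:]))

    def test_final_domain_inverts_gm_wm_ordering(self):
        series = make_domain_series(default_base_spec(), 6, 0.3, 0.1)
        first, last = series[0], series[-1]
        # T1w-like: WM brighter than GM at base, darker at the youngest domain
        assert first.means[0, WM] > first.means[0, GM]
        assert last.means[0, WM] < last.means[0, GM]
        # T2w-like flips the other way
        assert first.means[1, WM] < first.means[1, GM]
        assert last.means[1, WM] > last.means[1, GM]

    def test_two_domains_is_base_plus_one_shift(self):
        base = default_base_spec()
        series = make_domain_series(base, 2, 0.3, 0.1)
        assert len(series) == 2
        assert np.array_equal(series[0].means, base.means)

    def test_zero_noise_growth_keeps_noise_constant(self):
        series = make_domain_series(default_base_spec(), 4, 0.3, 0.0)
        assert len({s.noise_sigma for s in series}) == 1

    def test_invalid_decay_rejected(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                make_domain_series(default_base_spec(), 3, contrast_decay=bad)

    def test_histogram_overlap_grows_with_age_descent(self):
        """The youngest domain's GM/WM histograms overlap more than the base's."""
        series = make_domain_series(default_base_spec(), 6, 0.3, 0.1)
        lab = make_label_phantom((48, 48, 48), 3, 2, seed=5)
        first = render_intensities(lab, series[0], seed=8)
        last = render_intensities(lab, series[-1], seed=8)
        assert histogram_overlap(last, lab) > histogram_overlap(first, lab)


class TestRenderIntensities:
    def test_degenerate_distribution_renders_exact_means(self):
        lab = make_label_phantom((48, 48, 48), 3, 2, seed=5)
        spec = default_base_spec()
        spec = DomainSpec(
            domain_id="exact",
            means=spec.means,
            sds=np.full((2, 4), 1e-12),
            noise_sigma=0.0,
            blur_sigma=0.0,
        )
        vol = render_intensities(lab, spec, seed=1)
        wm_vals = vol.voxels[0][lab.voxels == WM]
        assert np.allclose(wm_vals, spec.means[0, WM], atol=1e-4)

    def test_within_tissue_means_statistically_correct(self):
        """Sample means land within 3 standard errors of the spec means."""
        lab = make_label_phantom((48, 48, 48), 3, 2, seed=5)
        base = default_base_spec()
        spec = DomainSpec(
            domain_id="stat", means=base.means, sds=base.sds,
            noise_sigma=3.0, blur_sigma=0.0,
        )
        vol = render_intensities(lab, spec, seed=42)
        for code in (CSF, GM, WM):
            vals = vol.voxels[0][lab.voxels == code]
            total_sd = np.hypot(spec.sds[0, code], spec.noise_sigma)
            se = total_sd / np.sqrt(vals.size)
            assert abs(vals.mean() - spec.means[0, code]) < 3 * se

    def test_t2_polarity_inverts_csf_wm_ordering(self):
        lab = make_label_phantom((48, 48, 48), 3, 2, seed=5)
        vol = render_intensities(lab, default_base_spec(), seed=3)
        csf_t1 = vol.voxels[0][lab.voxels == CSF].mean()
        wm_t1 = vol.voxels[0][lab.voxels == WM].mean()
        csf_t2 = vol.voxels[1][lab.voxels == CSF].mean()
        wm_t2 = vol.voxels[1][lab.voxels == WM].mean()
        assert csf_t1 < wm_t1
        assert csf_t2 > wm_t2

    def test_deterministic_and_shape_preserving(self):
        lab = make_label_phantom((48, 48, 48), 3, 2, seed=5)
        a = render_intensities(lab, default_base_spec(), seed=9)
        b = render_intensities(lab, default_base_spec(), seed=9)
        assert np.array_equal(a.voxels, b.voxels)
        assert a.shape == lab.shape
        assert a.spacing == lab.spacing


class TestDefectInjection:
    @pytest.fixture(scope="class")
    def phantom(self):
        return make_label_phantom((48, 48, 48), 3, 2, seed=13)

    def test_zero_defects_is_identity(self, phantom):
        labels, mask = inject_topology_defects(phantom, 0, seed=1)
        assert np.array_equal(labels.voxels, phantom.voxels)
        assert not mask.any()

    def test_holes_make_one_component_each_all_formerly_wm(self, phantom):
        res = inject_topology_defects(phantom, 3, kinds=("hole",), seed=2)
        placed = res.n_placed
        assert placed >= 1
        _, n_comp = ndimage.label(res.mask, structure=np.ones((3, 3, 3)))
        assert n_comp == placed
        assert (phantom.voxels[res.mask] == WM).all()
        assert (res.labels.voxels[res.mask] == GM).all()

    def test_voxels_outside_mask_unchanged(self, phantom):
        res = inject_topology_defects(phantom, 4, seed=3)
        assert np.array_equal(
            res.labels.voxels[~res.mask], phantom.voxels[~res.mask]
        )
        assert res.labels.spacing == phantom.spacing

    def test_excess_request_is_clipped_with_count(self, phantom):
        res = inject_topology_defects(phantom, 500, kinds=("hole",), seed=4)
        assert res.n_placed + res.n_clipped == 500
        assert res.n_clipped > 0

    def test_deterministic(self, phantom):
        a = inject_topology_defects(phantom, 3, seed=5)
        b = inject_topology_defects(phantom, 3, seed=5)
        assert np.array_equal(a.labels.voxels, b.labels.voxels)
        assert np.array_equal(a.mask, b.mask)
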