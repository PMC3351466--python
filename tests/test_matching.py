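"""Template matching: mismatch scoring, per-plane skeletonization, axis
scans, OR-combination and the global-threshold baseline."""

import numpy as np
import pytest

from fiberskel.datatypes import ImageStack, LineNetwork, Template
from fiberskel.matching import (
    MAX_MISMATCH,
    combine_scans,
    global_threshold_binarize,
    mismatch_plane,
    skeleton_plane,
    scan_axis,
)


def _random_template(rng, s=3):
    pat = rng.normal(size=(s, s))
    pat[s // 2, s // 2] = abs(pat[s // 2, s // 2]) + 1.0
    pat -= pat.mean()
    pat[s // 2, s // 2] = abs(pat[s // 2, s // 2])  # keep a positive core
    pat /= np.linalg.norm(pat)
    return Template(pattern=pat, scan_axis="x", global_mean=0.0)


def brute_force_mismatch(plane, template):
    """Independent per-pixel recomputation with explicit loops."""
    s = template.size
    half = s // 2
    out = np.full(plane.shape, MAX_MISMATCH)
    for i in range(half, plane.shape[0] - half):
        for j in range(half, plane.shape[1] - half):
            w = plane[i - half:i + half + 1, j - half:j + half + 1].astype(float)
            v = w - template.global_mean
            norm = np.sqrt((v**2).sum())
            if norm < 1e-12:
                continue
            v = v / norm
            out[i, j] = min(np.sqrt(((v - template.pattern) ** 2).sum()), 2.0)
    return out


def brute_force_skeleton(values, threshold):
    """Direct restatement of the local-minima rule with loops."""
    h, w = values.shape
    mask = values < threshold
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            keep = True
            for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                    continue
                if values[ni, nj] < values[i, j]:
                    keep = False
                elif values[ni, nj] == values[i, j] and (ni, nj) < (i, j):
                    keep = False
            out[i, j] = keep
    return out


class TestMismatchPlane:
    def test_perfect_match_scores_zero(self):
        rng = np.random.default_rng(0)
        t = _random_template(rng, 5)
        plane = np.zeros((11, 11))
        plane[3:8, 3:8] = 4.2 * t.pattern  # scaled copy, global mean 0
        d = mismatch_plane(plane, t).values
        assert d[5, 5] == pytest.approx(0.0, abs=1e-9)

    def test_negated_template_is_antipodal(self):
        rng = np.random.default_rng(1)
        t = _random_template(rng, 3)
        plane = np.zeros((9, 9))
        plane[3:6, 3:6] = -t.pattern
        d = mismatch_plane(plane, t).values
        assert d[4, 4] == pytest.approx(2.0, abs=1e-9)

    def test_constant_window_maximal_mismatch(self):
        t = _random_template(np.random.default_rng(2), 3)
        d = mismatch_plane(np.full((7, 7), 5.0),
                           Template(pattern=t.pattern, scan_axis="x",
                                    global_mean=5.0)).values
        assert np.all(d == 2.0)

    def test_margin_is_masked(self):
        t = _random_template(np.random.default_rng(3), 5)
        d = mismatch_plane(np.random.default_rng(4).random((12, 12)), t).values
        assert np.all(d[:2, :] == 2.0) and np.all(d[:, -2:] == 2.0)

    def test_plane_smaller_than_template_rejected(self):
        t = _random_template(np.random.default_rng(5), 5)
        with pytest.raises(ValueError):
            mismatch_plane(np.zeros((4, 9)), t)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_brute_force(self, case):
        rng = np.random.default_rng(10_000 + case)
        t = _random_template(rng, 3)
        t = Template(pattern=t.pattern, scan_axis="x",
                     global_mean=rng.uniform(0, 30))
        plane = rng.uniform(0, 255, size=(5, 5))
        got = mismatch_plane(plane, t).values
        want = brute_force_mismatch(plane, t)
        np.testing.assert_allclose(got, want, atol=1e-12)


class TestSkeletonPlane:
    def test_single_subthreshold_pixel_kept(self):
        field = np.full((6, 6), 1.5)
        field[2, 3] = 0.4
        out = skeleton_plane(field, 1.0)
        assert out.sum() == 1 and out[2, 3]

    def test_all_above_threshold_empty(self):
        assert skeleton_plane(np.full((5, 5), 1.2), 1.0).sum() == 0

    def test_two_basins_two_minima(self):
        yy, xx = np.mgrid[0:15, 0:15]
        bowl1 = 0.05 * ((yy - 3) ** 2 + (xx - 3) ** 2) + 0.2
        bowl2 = 0.05 * ((yy - 11) ** 2 + (xx - 11) ** 2) + 0.3
        field = np.minimum(bowl1, bowl2)
        out = skeleton_plane(field, 0.6)
        assert out.sum() == 2
        assert out[3, 3] and out[11, 11]

    def test_threshold_domain_enforced(self):
        with pytest.raises(ValueError):
            skeleton_plane(np.zeros((4, 4)), 0.0)
        with pytest.raises(ValueError):
            skeleton_plane(np.zeros((4, 4)), 2.0)

    @pytest.mark.parametrize("case", range(25))
    def test_matches_brute_force(self, case):
        rng = np.random.default_rng(20_000 + case)
        field = rng.choice(rng.uniform(0.1, 1.9, size=40), size=(10, 10))
        thr = rng.uniform(0.3, 1.8)
        np.testing.assert_array_equal(skeleton_plane(field, thr),
                                      brute_force_skeleton(field, thr))

    @pytest.mark.parametrize("case", range(10))
    def test_no_edge_adjacent_survivors(self, case):
        rng = np.random.default_rng(30_000 + case)
        out = skeleton_plane(rng.uniform(0, 2, size=(20, 20)), 1.5)
        assert not (out[1:, :] & out[:-1, :]).any()
        assert not (out[:, 1:] & out[:, :-1]).any()


class TestScanAxis:
    def test_background_stack_empty_output(self):
        t = _random_template(np.random.default_rng(6), 5)
        t = Template(pattern=t.pattern, scan_axis="x", global_mean=20.0)
        stack = ImageStack(voxels=np.full((16, 16, 16), 20.0))
        assert scan_axis(stack, t, 0.8).n_solid == 0

    def test_stack_thinner_than_template_rejected(self):
        t = _random_template(np.random.default_rng(7), 7)
        stack = ImageStack(voxels=np.zeros((16, 5, 16)))
        with pytest.raises(ValueError):
            scan_axis(stack, t, 0.8)

    def test_inplane_fiber_traced_within_one_voxel(self):
        """A single fiber along x is recovered by the x-scan as one voxel per
        plane, each within one voxel of the true medial axis."""
        from fiberskel.datatypes import ImagingParams
        from fiberskel.synthetic import render_stack, voxelize
        from fiberskel.templates import build_template

        seg = np.array([[[2.0, 20.5, 20.5], [38.0, 20.5, 20.5]]])
        net = LineNetwork(segments=seg, fiber_length=36.0,
                          volume_shape=(40, 40, 40))
        truth = voxelize(net)
        params = ImagingParams(psf_sigma=(0.8, 0.8, 2.0), noise_sigma=3.0)
        stack = render_stack(truth, net, params, mode="reflection", seed=1)
        template = build_template(stack, scan_axis="x", seed=2)
        out = scan_axis(stack, template, 0.9)
        xs, ys, zs = np.nonzero(out.voxels)
        assert len(xs) >= 25  # most interior planes fire
        assert np.all(np.abs(ys - 20) <= 1) and np.all(np.abs(zs - 20) <= 1)

    def test_affine_invariant_scan(self, small_surrogate):
        from fiberskel.templates import build_template

        _, _, stack = small_surrogate
        base = ImageStack(voxels=stack.voxels.astype(np.float64))
        mapped = ImageStack(voxels=0.6 * base.voxels + 40.0)
        ta = build_template(base, scan_axis="y", seed=8)
        tb = build_template(mapped, scan_axis="y", seed=8)
        np.testing.assert_array_equal(
            scan_axis(base, ta, 1.0).voxels,
            scan_axis(mapped, tb, 1.0).voxels,
        )


class TestCombineScans:
    def test_identity_and_idempotence(self):
        rng = np.random.default_rng(9)
        from fiberskel.datatypes import BinaryStack

        a = BinaryStack(voxels=rng.random((8, 8, 8)) < 0.1)
        empty = BinaryStack(voxels=np.zeros((8, 8, 8), bool))
        np.testing.assert_array_equal(combine_scans([a, empty]).voxels,
                                      a.voxels)
        np.testing.assert_array_equal(combine_scans([a, a]).voxels, a.voxels)

    def test_shape_mismatch_rejected(self):
        from fiberskel.datatypes import BinaryStack

        a = BinaryStack(voxels=np.zeros((8, 8, 8), bool))
        b = BinaryStack(voxels=np.zeros((8, 8, 9), bool))
        with pytest.raises(ValueError):
            combine_scans([a, b])

    def test_tilted_fiber_covered_by_or_of_scans(self):
        """A fiber at 45 degrees in the x-y plane distorts both single-scan
        cross-sections, but the OR of the x- and y-scans still covers the
        ground-truth trace within one voxel."""
        from fiberskel.datatypes import ImagingParams
        from fiberskel.synthetic import render_stack, voxelize
        from fiberskel.templates import build_template
        from scipy import ndimage

        seg = np.array([[[4.0, 4.0, 24.5], [44.0, 44.0, 24.5]]])
        net = LineNetwork(segments=seg, fiber_length=np.sqrt(2) * 40,
                          volume_shape=(48, 48, 48))
        truth = voxelize(net)
        params = ImagingParams(psf_sigma=(0.8, 0.8, 2.0), noise_sigma=3.0)
        stack = render_stack(truth, net, params, mode="reflection", seed=3)
        scans = [
            scan_axis(stack, build_template(stack, scan_axis=ax, seed=i), 1.0)
            for i, ax in enumerate(("x", "y"))
        ]
        comb = combine_scans(scans)
        near = ndimage.binary_dilation(comb.voxels, np.ones((3, 3, 3), bool))
        interior = truth.voxels.copy()
        interior[:6] = interior[-6:] = False  # border margin has no windows
        coverage = (near & interior).sum() / interior.sum()
        assert coverage >= 0.9


class TestGlobalThresholdBaseline:
    def test_extreme_thresholds(self, small_surrogate):
        _, _, stack = small_surrogate
        assert global_threshold_binarize(stack, 0).voxels.all()
        top = global_threshold_binarize(stack, 255).voxels
        np.testing.assert_array_equal(top, stack.voxels == 255)

    def test_out_of_range_rejected(self, small_surrogate):
        _, _, stack = small_surrogate
        with pytest.raises(ValueError):
            global_threshold_binarize(stack, 300)
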