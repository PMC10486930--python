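"""Unit and property tests for the 3D enclosure quantification."""

import numpy as np
import pytest

from gliaquant import synth
from gliaquant.mitoquant import (
    AstrocyteRecord,
    Component,
    VoxelStack,
    binarize_red,
    classify_astrocyte,
    label_components_3d,
    median_filter_slices,
    otsu_threshold,
    quantify_stack,
    summarize_cohort,
)
from gliaquant.mitoquant import test_enclosure as enclosure_record

from conftest import match_planted


# ---------------------------------------------------------------------------
# independent oracles


def otsu_oracle(image):
    """Exhaustive scan of all 256 thresholds maximizing between-class
    variance, written directly from the definition."""
    img = np.asarray(image).ravel()
    best_t, best_v = None, -1.0
    for t in range(256):
        lo = img[img <= t]
        hi = img[img > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / img.size, hi.size / img.size
        v = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def floodfill_oracle(mask, connectivity):
    """Iterative flood fill, independent of scipy labeling."""
    if connectivity == 6:
        offsets = [
            (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
        ]
    elif connectivity == 26:
        offsets = [
            (dz, dy, dx)
            for dz in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)
        ]
    else:
        raise ValueError(connectivity)
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            z, y, x = stack.pop()
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not labels[nz, ny, nx]
                ):
                    labels[nz, ny, nx] = current
                    stack.append((nz, ny, nx))
    return labels


def majority_filter_oracle(mask):
    """Per-slice 3x3 majority vote with replicate padding, written with
    explicit loops."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                votes = 0
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy = min(max(y + dy, 0), ny - 1)
                        xx = min(max(x + dx, 0), nx - 1)
                        votes += mask[z, yy, xx]
                out[z, y, x] = votes >= 5
    return out


def enclosure_oracle(coords, green, threshold):
    """Per-voxel exhaustive shell check from the definition."""
    coord_set = set(map(tuple, coords))
    shape = green.shape
    for z, y, x in coords:
        if z in (0, shape[0] - 1) or y in (0, shape[1] - 1) or x in (0, shape[2] - 1):
            return False
        for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)]:
            nb = (z + dz, y + dy, x + dx)
            if nb in coord_set:
                continue
            if green[nb] <= threshold:
                return False
    return True


def partition_of(labels):
    """Connected-component partition as a set of frozensets of voxels."""
    return {
        frozenset(map(tuple, np.argwhere(labels == lab)))
        for lab in np.unique(labels)
        if lab != 0
    }


# ---------------------------------------------------------------------------
# binarization


class TestBinarize:
    def test_fixed_threshold_strict(self):
        red = np.array([[[50, 120], [200, 99]]], dtype=np.uint8)
        expected = np.array([[[False, True], [True, False]]])
        np.testing.assert_array_equal(binarize_red(red, 100), expected)

    def test_threshold_value_itself_is_false(self):
        red = np.full((2, 2, 2), 100, dtype=np.uint8)
        assert not binarize_red(red, 100).any()

    def test_all_zero(self):
        assert not binarize_red(np.zeros((4, 4, 4), dtype=np.uint8), 100).any()

    def test_otsu_two_deltas(self):
        # equal mass at 10 and 200: everything at 200 must come out true
        red = np.zeros((2, 4, 4), dtype=np.uint8)
        red[0] = 10
        red[1] = 200
        mask = binarize_red(red, "otsu")
        assert mask[1].all() and not mask[0].any()

    def test_otsu_constant_warns_all_false(self):
        red = np.full((3, 3, 3), 7, dtype=np.uint8)
        with pytest.warns(UserWarning, match="Otsu"):
            mask = binarize_red(red, "otsu")
        assert not mask.any()

    @pytest.mark.parametrize("seed", range(20))
    def test_otsu_matches_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        img = r.choice([5, 30, 90, 180, 250], size=(6, 6, 6), p=[0.3, 0.2, 0.1, 0.2, 0.2])
        img = img.astype(np.uint8)
        t_oracle = otsu_oracle(img)
        mask = binarize_red(img, "otsu")
        np.testing.assert_array_equal(mask, img > t_oracle)


# ---------------------------------------------------------------------------
# median filter


class TestMedianFilter:
    def test_isolated_voxel_removed(self):
        m = np.zeros((1, 5, 5), dtype=bool)
        m[0, 2, 2] = True
        assert not median_filter_slices(m).any()

    def test_all_true_unchanged(self):
        m = np.ones((2, 4, 4), dtype=bool)
        np.testing.assert_array_equal(median_filter_slices(m), m)

    def test_plus_sign_tips_removed(self):
        # hand-evaluating each 3x3 neighborhood of the 5x5 plus sign:
        # the 4 arm tips have 3 true votes (removed), the centre 5 (kept),
        # and the diagonal neighbors of the centre gain 5 votes (filled) —
        # so the result is the central 3x3 block
        m = np.zeros((1, 5, 5), dtype=bool)
        m[0, 2, :] = True
        m[0, :, 2] = True
        out = median_filter_slices(m)
        expected = np.zeros_like(m)
        expected[0, 1:4, 1:4] = True
        np.testing.assert_array_equal(out, expected)
        assert out[0, 2, 2] and not out[0, 2, 0]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_majority_oracle(self, seed):
        r = np.random.default_rng(seed)
        m = r.random((3, 7, 7)) < 0.5
        np.testing.assert_array_equal(median_filter_slices(m), majority_filter_oracle(m))

    def test_slices_independent(self):
        r = np.random.default_rng(0)
        m = r.random((4, 8, 8)) < 0.4
        out = median_filter_slices(m)
        for z in range(4):
            np.testing.assert_array_equal(
                out[z], median_filter_slices(m[z][None])[0]
            )


# ---------------------------------------------------------------------------
# connected components


class TestLabeling:
    def test_empty_mask(self):
        cs = label_components_3d(np.zeros((4, 4, 4), dtype=bool))
        assert len(cs) == 0 and not cs.label_volume.any()

    def test_corner_touching_voxels(self):
        m = np.zeros((3, 3, 3), dtype=bool)
        m[0, 0, 0] = True
        m[1, 1, 1] = True
        assert len(label_components_3d(m, connectivity=26)) == 1
        assert len(label_components_3d(m, connectivity=6)) == 2

    def test_labels_contiguous_and_ordered(self):
        r = np.random.default_rng(5)
        m = r.random((6, 6, 6)) < 0.3
        cs = label_components_3d(m, connectivity=6)
        ids = [c.id for c in cs.components]
        assert ids == list(range(1, len(ids) + 1))
        firsts = [tuple(c.coords[0]) for c in cs.components]
        assert firsts == sorted(firsts)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_floodfill_oracle_100_masks(self, connectivity):
        r = np.random.default_rng(42)
        for _ in range(100):
            m = r.random((7, 7, 7)) < r.uniform(0.1, 0.6)
            cs = label_components_3d(m, connectivity=connectivity)
            oracle = floodfill_oracle(m, connectivity)
            assert partition_of(cs.label_volume) == partition_of(oracle)

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components_3d(np.zeros((3, 3, 3), dtype=bool), connectivity=4)


# ---------------------------------------------------------------------------
# enclosure


def _component_from(coords):
    coords = np.asarray(coords)
    return Component(id=1, coords=coords, voxel_count=len(coords))


class TestEnclosure:
    def test_interior_component_all_green(self):
        green = np.full((8, 8, 8), 255, dtype=np.uint8)
        rec = enclosure_record(_component_from([(4, 4, 4)]), green)
        assert rec.enclosed and rec.failure_reason == "none"
        assert rec.shell_min_green == 255

    def test_border_contact(self):
        green = np.full((8, 8, 8), 255, dtype=np.uint8)
        rec = enclosure_record(_component_from([(0, 4, 4)]), green)
        assert not rec.enclosed and rec.failure_reason == "border_contact"

    def test_shell_voxel_exactly_at_threshold_fails(self):
        green = np.full((8, 8, 8), 255, dtype=np.uint8)
        green[3, 4, 4] = 100  # shell neighbor exactly at threshold: strict >
        rec = enclosure_record(_component_from([(4, 4, 4)]), green, green_threshold=100)
        assert not rec.enclosed and rec.failure_reason == "shell_gap"
        assert rec.shell_min_green == 100

    def test_component_interior_green_not_required(self):
        # green may be displaced inside the component itself
        green = np.full((8, 8, 8), 255, dtype=np.uint8)
        green[4, 4, 4] = 0
        green[4, 4, 5] = 0
        rec = enclosure_record(_component_from([(4, 4, 4), (4, 4, 5)]), green)
        assert rec.enclosed

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        green = r.integers(0, 256, size=(9, 9, 9)).astype(np.uint8)
        mask = r.random((9, 9, 9)) < 0.15
        cs = label_components_3d(mask, connectivity=26)
        for comp in cs.components:
            rec = enclosure_record(comp, green, green_threshold=100)
            assert rec.enclosed == enclosure_oracle(comp.coords, green, 100)

    def test_monotone_in_threshold(self, rng):
        for _ in range(10):
            green = rng.integers(0, 256, size=(9, 9, 9)).astype(np.uint8)
            mask = rng.random((9, 9, 9)) < 0.1
            cs = label_components_3d(mask)
            for comp in cs.components:
                enclosed = [
                    enclosure_record(comp, green, green_threshold=t).enclosed
                    for t in (50, 100, 150, 200)
                ]
                # once lost, never regained as the threshold rises
                for lo, hi in zip(enclosed, enclosed[1:]):
                    assert lo or not hi

    def test_empty_component_rejected(self):
        green = np.zeros((4, 4, 4), dtype=np.uint8)
        with pytest.raises(ValueError):
            enclosure_record(_component_from(np.empty((0, 3), dtype=int)), green)


# ---------------------------------------------------------------------------
# per-stack quantification


class TestQuantifyStack:
    def _all_green_stack(self):
        green = np.full((64, 64, 64), 255, dtype=np.uint8)
        red = np.zeros((64, 64, 64), dtype=np.uint8)
        red[30:32, 30:32, 30:32] = 200  # 8-voxel cube, interior
        return VoxelStack(green=green, red=red)

    def test_interior_cube_fraction(self):
        quant, records, _ = quantify_stack(
            self._all_green_stack(), red_threshold=100, apply_median_filter=False
        )
        assert quant.astro_voxels == 64**3
        assert quant.enclosed_mito_voxels == 8
        assert quant.incorporation_fraction_pct == pytest.approx(100 * 8 / 64**3)
        assert [r.enclosed for r in records] == [True]

    def test_no_red_signal(self):
        green = np.full((16, 16, 16), 255, dtype=np.uint8)
        red = np.zeros((16, 16, 16), dtype=np.uint8)
        with pytest.warns(UserWarning):  # constant red -> no Otsu threshold
            quant, records, comps = quantify_stack(VoxelStack(green=green, red=red))
        assert quant.incorporation_fraction_pct == 0.0
        assert len(comps) == 0 and records == []

    def test_zero_astro_volume_fraction_undefined(self):
        green = np.zeros((16, 16, 16), dtype=np.uint8)
        red = np.zeros((16, 16, 16), dtype=np.uint8)
        red[8, 8, 8] = 200
        with pytest.warns(UserWarning, match="undefined"):
            quant, _, _ = quantify_stack(
                VoxelStack(green=green, red=red),
                red_threshold=100,
                apply_median_filter=False,
            )
        assert quant.incorporation_fraction_pct is None
        assert quant.astro_voxels == 0

    def test_synthetic_truth_recovered(self):
        stack, truth = synth.make_stack(
            n_astrocytes=1, n_enclosed=3, n_external=3, n_border=1, seed=7
        )
        detected, planted, n_comp, n_planted = match_planted(stack, truth)
        assert detected == planted
        assert n_comp == n_planted

    def test_conservation(self):
        stack, _ = synth.make_stack(seed=3)
        quant, _, _ = quantify_stack(stack, red_threshold=100)
        assert quant.enclosed_mito_voxels <= int((stack.red > 100).sum())

    def test_fraction_invariant_under_padding(self):
        stack, _ = synth.make_stack(seed=11, green_bg=20)
        quant, _, _ = quantify_stack(stack, red_threshold=100)
        pad = 4
        green = np.pad(stack.green, pad, constant_values=20)
        red = np.pad(stack.red, pad, constant_values=0)
        quant_p, _, _ = quantify_stack(
            VoxelStack(green=green, red=red), red_threshold=100
        )
        assert quant_p.incorporation_fraction_pct == pytest.approx(
            quant.incorporation_fraction_pct
        )

    def test_scale_covariance(self):
        stack, _ = synth.make_stack(seed=5)
        q1, _, _ = quantify_stack(stack, red_threshold=100)
        stack2 = VoxelStack(green=stack.green, red=stack.red, voxel_size_um=0.8)
        q2, _, _ = quantify_stack(stack2, red_threshold=100)
        assert q2.astro_volume_um3 == pytest.approx(q1.astro_volume_um3 * 8)
        assert q2.enclosed_mito_volume_um3 == pytest.approx(
            q1.enclosed_mito_volume_um3 * 8
        )
        assert q2.incorporation_fraction_pct == pytest.approx(
            q1.incorporation_fraction_pct
        )

    def test_min_component_size_filter(self):
        green = np.full((32, 32, 32), 255, dtype=np.uint8)
        red = np.zeros((32, 32, 32), dtype=np.uint8)
        red[10, 10, 10] = 200  # single voxel
        red[20:23, 20:23, 20:23] = 200  # 27 voxels
        quant, records, comps = quantify_stack(
            VoxelStack(green=green, red=red),
            red_threshold=100,
            min_component_voxels=5,
            apply_median_filter=False,
        )
        assert len(comps) == 1
        assert quant.enclosed_mito_voxels == 27


# ---------------------------------------------------------------------------
# classification and cohort summary


class TestClassify:
    @pytest.mark.parametrize(
        "count,expected",
        [(0, "none"), (1, "sporadic"), (3, "sporadic"), (5, "sporadic"),
         (6, "moderate"), (20, "moderate"), (21, "high"), (100, "high")],
    )
    def test_default_bins(self, count, expected):
        assert classify_astrocyte(count) == expected

    def test_custom_bins(self):
        assert classify_astrocyte(3, bins=(0, 2, 10)) == "moderate"

    def test_invalid(self):
        with pytest.raises(ValueError):
            classify_astrocyte(-1)
        with pytest.raises(ValueError):
            classify_astrocyte(1, bins=(0, 10, 5))


class TestSummarizeCohort:
    def test_worked_examples(self):
        control = [0] * 146 + [2] * 198
        high_iop = [0] * 92 + [3] * 247
        summary = summarize_cohort({"control": control, "high_iop": high_iop})
        assert summary.groups["control"].pct_zero == 42.4
        assert summary.groups["high_iop"].pct_zero == 27.1
        assert summary.groups["control"].n == 344
        assert summary.groups["high_iop"].n_zero == 92

    def test_no_zero(self):
        s = summarize_cohort({"g": [1] * 10})
        assert s.groups["g"].pct_zero == 0.0

    def test_accepts_records(self):
        recs = [AstrocyteRecord("a", 0), AstrocyteRecord("b", 25)]
        s = summarize_cohort({"g": recs})
        assert s.groups["g"].n_zero == 1
        assert s.groups["g"].category_counts["high"] == 1

    def test_empty_group_fails(self):
        with pytest.raises(ValueError):
            summarize_cohort({"g": []})
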