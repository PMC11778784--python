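"""Contour detection, parity classification and mask algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardiomorph import (
    build_contour_library,
    classify_contours,
    detect_slice_contours,
    fill_masks,
)
from cardiomorph.contours import DetectedContour
from cardiomorph.phantoms import OUTER, PhantomSpec, generate


def disc_image(r, centre=(32, 32), shape=(64, 64)):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (((yy - centre[0]) ** 2 + (xx - centre[1]) ** 2) <= r**2).astype(np.uint8) * 255


def annulus_image(r_out, r_in, centre=(32, 32), shape=(64, 64)):
    return disc_image(r_out, centre, shape) - disc_image(r_in, centre, shape)


class TestDetect:
    def test_disc_area(self):
        """One depth-0 contour whose enclosed area matches the pixel count."""
        img = disc_image(20)
        found = detect_slice_contours(img)
        assert len(found) == 1 and found[0].depth == 0
        rasterized = (img > 0).sum()  # pixel-count oracle for the same disc
        assert found[0].area == pytest.approx(rasterized, rel=0.03)
        assert found[0].area == pytest.approx(np.pi * 20**2, rel=0.03)

    def test_annulus_topology(self):
        found = detect_slice_contours(annulus_image(20, 10))
        assert sorted(c.depth for c in found) == [0, 1]

    def test_blank_image(self):
        assert detect_slice_contours(np.zeros((32, 32), dtype=np.uint8)) == []

    def test_min_area_filter(self):
        img = disc_image(20)
        img[2:4, 2:4] = 255  # 4-px speck
        found = detect_slice_contours(img, min_area=25)
        assert len(found) == 1

    def test_fixed_level(self):
        img = disc_image(15)
        assert len(detect_slice_contours(img, threshold_policy=128)) == 1
        with pytest.raises(ValueError):
            detect_slice_contours(img, threshold_policy=float("nan"))

    def test_border_touching_closed(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[:10, :10] = 255  # corner block touching two borders
        found = detect_slice_contours(img)
        assert len(found) == 1
        poly = found[0].polygon
        np.testing.assert_allclose(poly[0], poly[-1])


class TestClassify:
    def test_annulus_roles(self):
        sc = classify_contours(detect_slice_contours(annulus_image(20, 10)))
        by_depth = dict(zip(sc.depths, sc.roles))
        assert by_depth == {0: "external", 1: "internal"}

    def test_disjoint_discs_all_external(self):
        img = disc_image(10, centre=(16, 16)) | disc_image(10, centre=(48, 48))
        sc = classify_contours(detect_slice_contours(img))
        assert sc.roles == ["external", "external"]

    def test_triple_nested_parity(self):
        """Disc-in-hole-in-disc: the innermost island is external again."""
        img = annulus_image(25, 15) + disc_image(7)
        sc = classify_contours(detect_slice_contours(img))
        assert dict(zip(sc.depths, sc.roles)) == {0: "external", 1: "internal", 2: "external"}

    def test_inconsistent_depth_rejected(self):
        found = detect_slice_contours(annulus_image(20, 10))
        found[0] = DetectedContour(found[0].polygon, depth=found[0].depth + 1)
        with pytest.raises(ValueError, match="inconsistent"):
            classify_contours(found)


class TestFillMasks:
    def test_annulus_band_exact(self):
        sc = classify_contours(detect_slice_contours(annulus_image(20, 10)))
        m = fill_masks(sc, (64, 64))
        assert m.tissue.sum() == m.filled_external.sum() - m.filled_internal.sum()
        np.testing.assert_array_equal(m.tissue ^ m.filled_internal, m.filled_external)
        assert (m.filled_internal & ~m.filled_external).sum() == 0

    def test_no_internal_gives_tissue_equals_external(self):
        sc = classify_contours(detect_slice_contours(disc_image(15)))
        m = fill_masks(sc, (64, 64))
        np.testing.assert_array_equal(m.tissue, m.filled_external)

    def test_island_is_tissue_again(self):
        img = annulus_image(25, 15) + disc_image(7)
        sc = classify_contours(detect_slice_contours(img))
        m = fill_masks(sc, (64, 64))
        assert m.tissue[32, 32]  # island centre
        assert not m.tissue[32, 32 + 11]  # gap between island (r=7) and band (r=15)
        assert m.tissue[32, 32 + 20]  # outer band (15 < r < 25)

    def test_uncontained_internal_rejected(self):
        ring = classify_contours(detect_slice_contours(annulus_image(10, 6, centre=(16, 16))))
        bad = type(ring)(
            slice_index=0,
            polygons=[ring.polygons[1]],  # only the inner contour, forced internal
            roles=["internal"],
            depths=[1],
        )
        with pytest.raises(ValueError, match="not contained"):
            fill_masks(bad, (64, 64))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n_blobs=st.integers(1, 4),
    )
    def test_xor_identity_random_blobs(self, seed, n_blobs):
        """tissue XOR filled_internal == filled_external on arbitrary blob scenes."""
        rng = np.random.default_rng(seed)
        img = np.zeros((48, 48), dtype=np.uint8)
        yy, xx = np.mgrid[:48, :48]
        for _ in range(n_blobs):
            cy, cx, r = rng.integers(8, 40), rng.integers(8, 40), rng.integers(3, 12)
            blob = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2
            img[blob] = 255 - img[blob]  # xor-compose to create holes
        found = detect_slice_contours(img, min_area=4)
        sc = classify_contours(found)
        m = fill_masks(sc, img.shape)
        np.testing.assert_array_equal(m.tissue ^ m.filled_internal, m.filled_external)
        assert not (m.tissue & m.filled_internal).any()


class TestLibrary:
    def test_phantom_wall_volume(self, nested):
        res, lib = nested
        wall = lib.mask3d(OUTER, "tissue")
        vol = wall.sum() * np.prod(lib.spacing)
        assert vol == pytest.approx(res.truth["myo_wall_volume"], rel=0.03)

    def test_slice_count_matches_depth(self, nested):
        res, lib = nested
        for ch in lib.channel_names:
            assert len(lib.masks[ch]) == res.stack.shape[0]

    def test_blank_channel_empty_masks(self):
        from cardiomorph import IntensityStack

        stack = IntensityStack(
            channels={"empty": np.zeros((4, 16, 16), dtype=np.uint8)}, spacing=(1, 1, 1)
        )
        lib = build_contour_library(stack)
        assert not lib.mask3d("empty", "filled_external").any()

    def test_manual_override_substitutes_one_slice(self):
        from cardiomorph import IntensityStack

        img = np.stack([disc_image(15, shape=(48, 48), centre=(24, 24))] * 3)
        stack = IntensityStack(channels={"a": img}, spacing=(1, 1, 1))
        square = np.array([[10.0, 10.0], [10.0, 38.0], [38.0, 38.0], [38.0, 10.0], [10.0, 10.0]])
        lib = build_contour_library(stack, overrides={"a": {1: [square]}})
        assert lib.contours["a"][1].provenance == "manual"
        assert lib.contours["a"][0].provenance == "auto"
        # overridden slice fills the square, neighbours keep the disc
        assert lib.masks["a"][1].tissue.sum() == pytest.approx(29 * 29, rel=0.05)
        # disc area recovered within the rasterization bound (perimeter x pixel)
        assert abs(lib.masks["a"][0].tissue.sum() - np.pi * 15**2) <= 2 * np.pi * 15

    def test_override_bad_slice_rejected(self):
        from cardiomorph import IntensityStack

        stack = IntensityStack(channels={"a": np.zeros((2, 8, 8), np.uint8)}, spacing=(1, 1, 1))
        with pytest.raises(ValueError, match="nonexistent slice"):
            build_contour_library(stack, overrides={"a": {5: [np.zeros((4, 2))]}})

    def test_rerun_bit_identical(self, nested):
        res, lib = nested
        lib2 = build_contour_library(res.stack)
        np.testing.assert_array_equal(lib.mask3d(OUTER, "tissue"), lib2.mask3d(OUTER, "tissue"))
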