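import numpy as np
import pytest
from scipy import ndimage

from orgloc.sampling import (
    BC,
    OC,
    SamplePoint,
    SamplingConfig,
    background_points,
    build_dataset,
    extract_triplet,
    organ_points,
)
from orgloc.volume_io import BinaryMask, Volume


def brute_force_background(mask: np.ndarray, cfg: SamplingConfig) -> set:
    """Independent oracle: explicit Euclidean-disk dilation + strip removal
    + exhaustive grid membership."""
    h, w = mask.shape
    r = cfg.dilation_radius
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    disk = dy**2 + dx**2 <= r**2
    allowed = np.ones((h, w), dtype=bool)
    if mask.any():
        allowed &= ~ndimage.binary_dilation(mask, structure=disk)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        allowed[max(rows[0] - cfg.strip_pad, 0) : rows[-1] + cfg.strip_pad + 1, :] = False
        allowed[:, max(cols[0] - cfg.strip_pad, 0) : cols[-1] + cfg.strip_pad + 1] = False
    pts = set()
    for y in range(0, h, cfg.grid_spacing):
        for x in range(0, w, cfg.grid_spacing):
            if allowed[y, x]:
                pts.add((y, x))
    return pts


class TestOrganPoints:
    def test_rectangle_grid(self):
        mask = np.zeros((200, 100), dtype=bool)
        mask[0:120, 0:60] = True
        pts = organ_points(mask, SamplingConfig())
        coords = {(p.y, p.x) for p in pts}
        assert coords == {(y, x) for y in (0, 50, 100) for x in (0, 50)}
        assert len(pts) == 6
        assert all(p.label == OC for p in pts)

    def test_empty_mask(self):
        assert organ_points(np.zeros((64, 64), dtype=bool), SamplingConfig()) == []

    def test_single_pixel_anchoring(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[37, 83] = True
        pts = organ_points(mask, SamplingConfig())
        assert [(p.y, p.x) for p in pts] == [(37, 83)]

    def test_points_inside_mask(self, rng):
        mask = np.zeros((120, 120), dtype=bool)
        mask[30:90, 20:100] = True
        mask[50:70, 40:60] = False  # hole
        for p in organ_points(mask, SamplingConfig(grid_spacing=10)):
            assert mask[p.y, p.x]


class TestBackgroundPoints:
    def test_single_pixel_mask_100_points(self):
        mask = np.zeros((512, 512), dtype=bool)
        mask[200, 200] = True
        pts = background_points(mask, SamplingConfig())
        # 11x11 grid minus row 200 strip (11) minus col 200 strip (11) + overlap
        assert len(pts) == 100
        assert all(p.label == BC for p in pts)

    def test_empty_mask_full_grid(self):
        pts = background_points(np.zeros((512, 512), dtype=bool), SamplingConfig())
        assert len(pts) == 121

    def test_full_mask_empty(self):
        assert background_points(np.ones((100, 100), dtype=bool), SamplingConfig()) == []

    def test_rays_miss_mask(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[100:140, 80:130] = True
        for p in background_points(mask, SamplingConfig()):
            assert not mask[p.y, :].any() or not mask[:, p.x].any()
            # strip construction is stronger: both rays miss
            assert not mask[p.y, :].any()
            assert not mask[:, p.x].any()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((150, 150), dtype=bool)
        for _ in range(rng.integers(1, 4)):
            cy, cx = rng.integers(20, 130, size=2)
            rr = rng.integers(4, 12)
            yy, xx = np.mgrid[0:150, 0:150]
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rr**2
        cfg = SamplingConfig(grid_spacing=20, dilation_radius=15, strip_pad=5)
        got = {(p.y, p.x) for p in background_points(mask, cfg)}
        assert got == brute_force_background(mask, cfg)

    def test_bc_min_distance_to_mask(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[150:200, 150:210] = True
        cfg = SamplingConfig()
        dist = ndimage.distance_transform_edt(~mask)
        for p in background_points(mask, cfg):
            assert dist[p.y, p.x] > cfg.dilation_radius


class TestExtractTriplet:
    def test_shapes_on_fullsize(self, fullsize_phantom):
        vol, _ = fullsize_phantom
        trip = extract_triplet(vol, SamplePoint(x=100, y=250, z=20), side="left")
        assert trip.img_x.shape == (43, 512)
        assert trip.img_y.shape == (43, 256)
        assert trip.img_z.shape == (512, 512)

    def test_same_x_same_plane(self, small_phantom):
        vol, _ = small_phantom
        a = extract_triplet(vol, SamplePoint(x=40, y=10, z=2))
        b = extract_triplet(vol, SamplePoint(x=40, y=90, z=9))
        np.testing.assert_array_equal(a.img_x, b.img_x)

    def test_organ_visibility(self, clean_small_phantom, clean_small_spec):
        vol, masks = clean_small_phantom
        organ = clean_small_spec.organs[0]
        cz, cy, cx = (int(v) for v in organ.center)
        inside = extract_triplet(vol, SamplePoint(x=cx, y=cy, z=cz))
        assert inside.img_x.max() == pytest.approx(0.78)
        assert inside.img_y.max() == pytest.approx(0.78)
        outside = extract_triplet(vol, SamplePoint(x=5, y=5, z=0))
        assert outside.img_x.max() < 0.78
        assert outside.img_y.max() < 0.78

    def test_out_of_bounds(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(IndexError):
            extract_triplet(vol, SamplePoint(x=1000, y=0, z=0))

    def test_depth_resampled(self, small_phantom):
        vol, _ = small_phantom  # depth 20 -> resampled to 43 rows
        trip = extract_triplet(vol, SamplePoint(x=10, y=10, z=1))
        assert trip.img_x.shape[0] == 43
        assert trip.img_z.shape == vol.shape[1:]


class TestBuildDataset:
    @pytest.fixture()
    def tiny_cohort(self, rng):
        vol = Volume(data=rng.random((6, 120, 120)).astype(np.float32), normalized=True)
        mask = np.zeros((6, 120, 120), dtype=bool)
        mask[3, 30:60, 20:50] = True  # a single annotated slice
        return [(vol, {"kidney_right": BinaryMask(data=mask, label="kidney_right")})]

    def _cfg(self):
        return SamplingConfig(grid_spacing=25, dilation_radius=20, strip_pad=5)

    def test_counts_match_point_ops(self, tiny_cohort):
        cfg = self._cfg()
        (vol, masks) = tiny_cohort[0]
        mask2d = masks["kidney_right"].data[3]
        expected = len(organ_points(mask2d, cfg)) + len(background_points(mask2d, cfg))
        ds = build_dataset(tiny_cohort, "kidney_right", cfg, z_stride=1, dedupe=False)
        assert ds.images["X"].shape[0] == expected
        assert ds.images["Y"].shape[0] == expected
        assert ds.images["Z"].shape[0] == vol.n_slices

    def test_z_labels(self, tiny_cohort):
        ds = build_dataset(tiny_cohort, "kidney_right", self._cfg(), dedupe=False)
        np.testing.assert_array_equal(ds.labels["Z"], [0, 0, 0, 1, 0, 0])

    def test_deterministic(self, tiny_cohort):
        a = build_dataset(tiny_cohort, "kidney_right", self._cfg(), dedupe=False)
        b = build_dataset(tiny_cohort, "kidney_right", self._cfg(), dedupe=False)
        for axis in "XYZ":
            np.testing.assert_array_equal(a.images[axis], b.images[axis])
            np.testing.assert_array_equal(a.labels[axis], b.labels[axis])

    def test_oc_images_contain_organ(self, clean_small_spec):
        from orgloc.phantom import make_phantom

        vol, masks = make_phantom(clean_small_spec)
        cfg = SamplingConfig(grid_spacing=20, dilation_radius=20, strip_pad=5)
        cohort = [(vol, masks)]
        ds = build_dataset(cohort, "kidney_right", cfg, dedupe=False)
        organ_rows = ds.labels["Y"] == 1
        assert organ_rows.any()
        for img in ds.images["Y"][organ_rows]:
            assert img.max() == pytest.approx(0.78)

    def test_missing_organ_skipped(self, tiny_cohort, caplog):
        ds = build_dataset(tiny_cohort, "spleen", self._cfg(), dedupe=False)
        assert ds.images["X"].shape[0] == 0

    def test_dedupe_labels_3d_consistent(self, tiny_cohort):
        ds = build_dataset(tiny_cohort, "kidney_right", self._cfg(), dedupe=True)
        (vol, masks) = tiny_cohort[0]
        mask3d = masks["kidney_right"].data
        man = ds.manifest
        for _, row in man[man.axis == "X"].iterrows():
            assert row.label == int(mask3d[:, :, row.coord].any())
        for _, row in man[man.axis == "Y"].iterrows():
            assert row.label == int(mask3d[:, row.coord, :].any())
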