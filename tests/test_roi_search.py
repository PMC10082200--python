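import numpy as np
import pytest

from orgloc.roi_search import (
    DetectionError,
    RoiBox,
    SearchConfig,
    classify_axis_lines,
    find_roi,
    merge_points,
    positive_grid,
    refine_mask,
    side_box,
)
from orgloc.sampling import SamplePoint, extract_triplet
from orgloc.volume_io import Volume


class _RuleNet:
    """Duck-typed stand-in classifier: organ iff image mean > threshold."""

    def __init__(self, input_shape, threshold):
        from orgloc.models import NetConfig

        self.cfg = NetConfig.fast(input_shape=input_shape)
        self.threshold = threshold

    def predict(self, images):
        images = np.asarray(images)
        if images.size == 0:
            return np.zeros(0, dtype=int)
        return (images.reshape(images.shape[0], -1).mean(axis=1) > self.threshold).astype(int)


@pytest.fixture()
def toy_volume(rng):
    """50x64x64 volume with a bright box at z 10..29, y 16..39, x 8..23."""
    data = np.full((50, 64, 64), 0.2, np.float32)
    data += 0.01 * rng.standard_normal(data.shape).astype(np.float32)
    data[10:30, 16:40, 8:24] = 0.9
    return Volume(data=np.clip(data, 0, 1), normalized=True)


def toy_nets(vol, threshold=0.25):
    nz, ny, nx = vol.shape
    return {
        "X": _RuleNet((nz, ny), threshold),
        "Y": _RuleNet((nz, nx), threshold),
        "Z": _RuleNet((ny, nx), threshold),
    }


class TestConfigAndBox:
    def test_config_validation(self):
        with pytest.raises(ValueError):
            SearchConfig(scan_step=0)
        with pytest.raises(ValueError):
            SearchConfig(scan_step=10, merge_distance=5)
        with pytest.raises(ValueError):
            SearchConfig(side="top")

    def test_degenerate_box(self):
        with pytest.raises(ValueError):
            RoiBox(x0=5, x1=5, y0=0, y1=1, z0=0, z1=1)

    def test_clip_and_volume(self):
        box = RoiBox(x0=-5, x1=100, y0=0, y1=10, z0=0, z1=10).clip((8, 8, 8))
        assert (box.x0, box.x1, box.y0, box.y1, box.z0, box.z1) == (0, 8, 0, 8, 0, 8)
        assert box.volume() == 512

    def test_contains_fraction(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 1, 1] = mask[3, 3, 3] = True
        box = RoiBox(x0=0, x1=2, y0=0, y1=2, z0=0, z1=2)
        assert box.contains_fraction(mask) == 0.5

    def test_json_round_trip(self, tmp_path):
        box = RoiBox(x0=1, x1=9, y0=2, y1=8, z0=0, z1=4)
        box.to_json(tmp_path / "roi.json", extra={"organ": "spleen"})
        assert RoiBox.from_json(tmp_path / "roi.json") == box

    def test_side_box(self):
        assert side_box((10, 20, 30), "left") == RoiBox(x0=0, x1=15, y0=0, y1=20, z0=0, z1=10)
        assert side_box((10, 20, 30), "full").volume() == 6000


class TestClassifyAxisLines:
    def test_vector_length(self, toy_volume):
        cfg = SearchConfig(scan_step=7, merge_distance=7, side="full")
        nets = toy_nets(toy_volume)
        coords, flags = classify_axis_lines(toy_volume, "X", nets["X"], cfg)
        assert len(coords) == len(flags) == int(np.ceil(64 / 7))

    def test_all_background(self, rng):
        vol = Volume(data=np.full((20, 32, 32), 0.1, np.float32), normalized=True)
        cfg = SearchConfig(scan_step=8, merge_distance=8, side="full")
        _, flags = classify_axis_lines(vol, "Y", _RuleNet((20, 32), 0.5), cfg)
        assert not flags.any()

    def test_positives_form_interval(self, toy_volume):
        cfg = SearchConfig(scan_step=4, merge_distance=4, side="full")
        nets = toy_nets(toy_volume)
        coords, flags = classify_axis_lines(toy_volume, "X", nets["X"], cfg)
        on = np.flatnonzero(flags)
        assert len(on) > 0
        assert np.array_equal(on, np.arange(on[0], on[-1] + 1))


class TestPositiveGrid:
    def test_product_count(self):
        xc, xf = [0, 10, 20, 30], [True, True, True, False]
        yc, yf = [0, 10], [True, True]
        zc, zf = [0, 1, 2, 3], [True] * 4
        assert len(positive_grid(xc, xf, yc, yf, zc, zf)) == 3 * 2 * 4

    def test_empty_when_any_axis_empty(self):
        assert positive_grid([0], [False], [0], [True], [0], [True]) == set()

    def test_equals_bruteforce_triple_classification(self, toy_volume):
        cfg = SearchConfig(scan_step=10, merge_distance=10, side="full")
        nets = toy_nets(toy_volume)
        xc, xf = classify_axis_lines(toy_volume, "X", nets["X"], cfg)
        yc, yf = classify_axis_lines(toy_volume, "Y", nets["Y"], cfg)
        zc, zf = classify_axis_lines(toy_volume, "Z", nets["Z"], cfg)
        got = positive_grid(xc, xf, yc, yf, zc, zf)
        nz = toy_volume.n_slices
        brute = set()
        for x in xc:
            for y in yc:
                for z in zc:
                    trip = extract_triplet(
                        toy_volume, SamplePoint(x=int(x), y=int(y), z=int(z)),
                        side="full", target_depth=nz,
                    )
                    if (
                        nets["X"].predict(trip.img_x[None])[0]
                        and nets["Y"].predict(trip.img_y[None])[0]
                        and nets["Z"].predict(trip.img_z[None])[0]
                    ):
                        brute.add((int(x), int(y), int(z)))
        assert got == brute


class TestMergePoints:
    def _cfg(self):
        return SearchConfig(scan_step=10, merge_distance=10)

    def test_vertical_segment(self):
        mask = merge_points([(100, 100), (110, 100)], (200, 200), self._cfg())
        assert mask[100:111, 100].all()
        assert mask.sum() == 11

    def test_horizontal_segment(self):
        mask = merge_points([(100, 100), (100, 110)], (200, 200), self._cfg())
        assert mask[100, 100:111].all()
        assert mask.sum() == 11

    def test_isolated_point(self):
        mask = merge_points([(50, 50)], (100, 100), self._cfg())
        assert mask.sum() == 1 and mask[50, 50]

    def test_grid_block_connected_bbox(self):
        from skimage import measure

        pts = [(y, x) for y in range(40, 80, 10) for x in range(60, 100, 10)]
        mask = merge_points(pts, (150, 150), self._cfg())
        labels = measure.label(mask, connectivity=2)
        assert labels.max() == 1
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        assert (rows[0], rows[-1], cols[0], cols[-1]) == (40, 70, 60, 90)


class TestRefineMask:
    def _cfg(self, dilate=30):
        return SearchConfig(dilate_size=dilate)

    def test_largest_component_survives(self):
        mask = np.zeros((300, 300), dtype=bool)
        mask[10:15, 10:20] = True  # 50 px
        mask[200:201, 200:205] = True  # 5 px
        out = refine_mask(mask, self._cfg())
        assert out[12, 15]
        assert not out[200:230, 200:235].any() or not out[200, 200]
        assert not out[185:215, 185:220].any()

    def test_single_pixel_dilation_offsets(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[200, 200] = True
        out = refine_mask(mask, self._cfg())
        rows = np.flatnonzero(out.any(axis=1))
        cols = np.flatnonzero(out.any(axis=0))
        # even 30x30 SE centered as offsets [-15, +14]
        assert (rows[0], rows[-1]) == (185, 214)
        assert (cols[0], cols[-1]) == (185, 214)
        assert out.sum() == 900

    def test_superset_of_largest_component(self):
        mask = np.zeros((100, 100), dtype=bool)
        mask[40:60, 40:60] = True
        out = refine_mask(mask, self._cfg(dilate=10))
        assert (out & mask).sum() == mask.sum()

    def test_empty_mask(self):
        out = refine_mask(np.zeros((10, 10), dtype=bool), self._cfg())
        assert not out.any()


class TestFindRoi:
    def test_contains_toy_object(self, toy_volume):
        cfg = SearchConfig(scan_step=4, merge_distance=4, dilate_size=10, side="full")
        roi = find_roi(toy_volume, toy_nets(toy_volume), cfg)
        gt = np.zeros(toy_volume.shape, dtype=bool)
        gt[10:30, 16:40, 8:24] = True
        assert roi.contains_fraction(gt) == 1.0

    def test_volume_strictly_smaller_than_side_half(self, toy_volume):
        cfg = SearchConfig(scan_step=4, merge_distance=4, dilate_size=6, side="left")
        roi = find_roi(toy_volume, toy_nets(toy_volume), cfg)
        assert roi.volume() < side_box(toy_volume.shape, "left").volume()

    def test_dilate_monotonicity(self, toy_volume):
        nets = toy_nets(toy_volume)
        small = find_roi(
            toy_volume, nets, SearchConfig(scan_step=4, merge_distance=4, dilate_size=4, side="full")
        )
        big = find_roi(
            toy_volume, nets, SearchConfig(scan_step=4, merge_distance=4, dilate_size=12, side="full")
        )
        assert big.x0 <= small.x0 and big.x1 >= small.x1
        assert big.y0 <= small.y0 and big.y1 >= small.y1

    def test_deterministic(self, toy_volume):
        cfg = SearchConfig(scan_step=4, merge_distance=4, dilate_size=6, side="full")
        nets = toy_nets(toy_volume)
        assert find_roi(toy_volume, nets, cfg) == find_roi(toy_volume, nets, cfg)

    def test_detection_failure(self):
        vol = Volume(data=np.full((20, 32, 32), 0.1, np.float32), normalized=True)
        cfg = SearchConfig(scan_step=8, merge_distance=8, side="full")
        with pytest.raises(DetectionError, match="spleen"):
            find_roi(vol, toy_nets(vol, threshold=0.5), cfg, organ="spleen")
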