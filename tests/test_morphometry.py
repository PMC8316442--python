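"""Morphometry tests: perimeter estimator closed forms, jamming call,
segmentation recovery, colour coding."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from skimage.draw import disk as sk_disk
from skimage.draw import polygon
from skimage.segmentation import find_boundaries

from jamscope.image import LabelMask
from jamscope.morphometry import (
    JAMMING_THRESHOLD,
    EmptyMaskError,
    classify_jamming,
    colorize_aspect_ratio,
    crofton_perimeter,
    segment_membranes,
    shape_metrics,
)
from jamscope.render import RenderConfig, voronoi_masks
from jamscope.simulate import SimulationConfig, simulate_monolayer

SQUARE_Q = 4.0
HEXAGON_Q = 6.0 / np.sqrt(3.0 * np.sqrt(3.0) / 2.0)
DISK_Q = 2.0 * np.sqrt(np.pi)


def square_mask(side=300, pad=10):
    img = np.zeros((side + 2 * pad, side + 2 * pad), np.uint16)
    img[pad : pad + side, pad : pad + side] = 1
    return LabelMask(img, 1.0)


def hexagon_mask(circumradius=150):
    ang = np.pi / 2 + np.arange(6) * np.pi / 3
    c = circumradius + 10
    img = np.zeros((2 * c, 2 * c), np.uint16)
    rr, cc = polygon(c + circumradius * np.sin(ang), c + circumradius * np.cos(ang))
    img[rr, cc] = 1
    return LabelMask(img, 1.0)


def disk_mask(radius=150):
    c = radius + 10
    img = np.zeros((2 * c, 2 * c), np.uint16)
    rr, cc = sk_disk((c, c), radius)
    img[rr, cc] = 1
    return LabelMask(img, 1.0)


class TestShapeClosedForms:
    @pytest.mark.parametrize(
        "mask,expected",
        [
            (square_mask(), SQUARE_Q),
            (hexagon_mask(), HEXAGON_Q),
            (disk_mask(), DISK_Q),
        ],
        ids=["square", "hexagon", "disk"],
    )
    def test_reference_shapes_within_one_percent(self, mask, expected):
        table = shape_metrics(mask, exclude_border=False)
        assert table.q[0] == pytest.approx(expected, rel=0.01)

    def test_disk_aspect_ratio_is_one(self):
        table = shape_metrics(disk_mask(), exclude_border=False)
        assert table.aspect_ratio[0] == pytest.approx(1.0, abs=0.02)

    def test_q_is_scale_invariant_under_upsampling(self):
        mask = hexagon_mask(80)
        q1 = shape_metrics(mask, exclude_border=False).q[0]
        up = LabelMask(np.kron(mask.labels, np.ones((2, 2), np.uint16)), 0.5)
        q2 = shape_metrics(up, exclude_border=False).q[0]
        assert q2 == pytest.approx(q1, rel=0.005)

    def test_pixel_size_cancels_in_q_but_scales_area(self):
        mask = disk_mask(100)
        t1 = shape_metrics(mask, exclude_border=False)
        t2 = shape_metrics(LabelMask(mask.labels, 0.75488), exclude_border=False)
        assert t2.q[0] == pytest.approx(t1.q[0], rel=1e-9)
        assert t2.area_um2[0] == pytest.approx(t1.area_um2[0] * 0.75488**2)


class TestCroftonEstimator:
    def test_disk_perimeter_within_one_percent(self):
        mask = disk_mask(150)
        p = crofton_perimeter(mask.labels == 1)
        assert p == pytest.approx(2 * np.pi * 150, rel=0.01)

    def test_naive_pixel_edge_count_fails_where_crofton_passes(self):
        # exposed-pixel-edge counting measures the Manhattan boundary,
        # ~4/pi too long for a disk; the choice of estimator matters
        mask = disk_mask(150).labels == 1
        padded = np.pad(mask, 1)
        naive = (
            np.count_nonzero(padded[1:, :] != padded[:-1, :])
            + np.count_nonzero(padded[:, 1:] != padded[:, :-1])
        )
        assert abs(naive / (2 * np.pi * 150) - 1.0) > 0.2
        assert abs(crofton_perimeter(mask) / (2 * np.pi * 150) - 1.0) < 0.01

    def test_isoperimetric_bound_on_random_blobs(self):
        # cell-scale random blobs (the metrics are specified for objects
        # tens of pixels across, not slivers)
        rng = np.random.default_rng(9)
        field = ndimage.gaussian_filter(rng.standard_normal((768, 768)), 12.0)
        labels, _ = ndimage.label(field > 0.0)
        with pytest.warns(UserWarning, match="below"):
            table = shape_metrics(LabelMask(labels.astype(np.uint16), 1.0))
        table = table[table.area_um2 >= 300]
        assert len(table) >= 3
        assert np.all(table.q.to_numpy() >= DISK_Q - 0.02)


class TestClassifyJamming:
    def test_square_cells_are_unjammed(self):
        table = pd.DataFrame({"q": [SQUARE_Q] * 10})
        call = classify_jamming(table)
        assert call.state == "unjammed"
        assert call.threshold == JAMMING_THRESHOLD

    def test_hexagon_cells_are_jammed(self):
        table = pd.DataFrame({"q": [HEXAGON_Q] * 10})
        assert classify_jamming(table).state == "jammed"

    def test_tie_counts_as_unjammed(self):
        table = pd.DataFrame({"q": [3.813] * 5})
        assert classify_jamming(table).state == "unjammed"

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classify_jamming(pd.DataFrame({"q": []}))

    def test_mean_q_from_voronoi_sweep_is_monotone_in_motility(self):
        # faster monolayers disorder the tessellation: unjammed cells
        # elongate, so mean q must not decrease with v0 (after relaxation)
        rc = RenderConfig(pixel_size=0.5, image_shape=(720, 720))
        means = []
        for v0, dt in ((0.1, 0.5), (2.0, 0.5), (4.0, 0.25)):
            cfg = SimulationConfig(v0=v0, d_r=0.1, dt=dt, n_frames=11, rng_seed=2)
            traj = simulate_monolayer(cfg)
            mask = voronoi_masks(traj, cfg.n_frames - 1, rc)
            means.append(shape_metrics(mask).q.mean())
        assert means[0] <= means[1] <= means[2]


class TestShapeMetricsBookkeeping:
    def test_border_cells_flagged_and_excluded_by_default(self):
        img = np.zeros((64, 64), np.uint16)
        img[0:20, 0:20] = 1  # touches border
        img[30:50, 30:50] = 2  # interior
        mask = LabelMask(img, 1.0)
        kept = shape_metrics(mask)
        assert kept.cell_id.tolist() == [2]
        full = shape_metrics(mask, exclude_border=False)
        assert full.touches_border.tolist() == [True, False]

    def test_tiny_labels_excluded_with_warning(self):
        img = np.zeros((32, 32), np.uint16)
        img[2:4, 2:4] = 1  # 4 px, below the minimum
        img[10:25, 10:25] = 2
        with pytest.warns(UserWarning, match="below"):
            table = shape_metrics(LabelMask(img, 1.0), exclude_border=False)
        assert table.cell_id.tolist() == [2]


class TestSegmentMembranes:
    def test_voronoi_boundary_image_recovered_with_seeds(self):
        cfg = SimulationConfig(
            n_cells=16, box_size=240.0, v0=0.5, d_r=0.1, cell_radius=20.0,
            dt=0.5, n_frames=2, frame_interval=5.0, rng_seed=4,
        )
        traj = simulate_monolayer(cfg)
        rc = RenderConfig(pixel_size=1.0, image_shape=(240, 240))
        truth = voronoi_masks(traj, 0, rc)
        membrane = ndimage.gaussian_filter(
            find_boundaries(truth.labels, mode="thick").astype(float), 1.0
        )
        centers = np.mod(traj.positions[0], cfg.box_size)  # nuclei stand-ins
        seeds_px = centers  # pixel_size 1, origin at box corner (window = box)
        got = segment_membranes(membrane, seeds=seeds_px, pixel_size=1.0)
        # evaluate the central crop: cells wrapped across the periodic
        # window edge have no seed on their far-side fragment, which a
        # non-periodic watershed cannot recover by construction
        sl = np.s_[40:200, 40:200]
        got_c, truth_c = got.labels[sl], truth.labels[sl]
        # optimal matching: map each recovered label to its majority truth
        # label, then score pixel agreement
        agree = 0
        for lab in np.unique(got_c):
            sel = got_c == lab
            truth_lab = np.bincount(truth_c[sel]).argmax()
            agree += np.count_nonzero(truth_c[sel] == truth_lab)
        assert agree / truth_c.size >= 0.95

    def test_blank_image_raises_empty_mask_error(self):
        with pytest.raises(EmptyMaskError, match="blank"):
            segment_membranes(np.zeros((64, 64)))

    def test_bright_square_outline_gives_inside_and_outside(self):
        img = np.zeros((64, 64))
        img[16, 16:49] = img[48, 16:49] = 100.0
        img[16:49, 16] = img[16:49, 48] = 100.0
        mask = segment_membranes(img, smoothing_sigma=1.0)
        labels = np.unique(mask.labels)
        assert len(labels) == 2
        inside = mask.labels[32, 32]
        inside_area = np.count_nonzero(mask.labels == inside)
        assert inside_area == pytest.approx(33 * 33, rel=0.1)

    def test_unseeded_watershed_smoke(self):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.random((96, 96)), 6.0)
        mask = segment_membranes(img)
        assert mask.labels.max() >= 1


class TestColorize:
    @staticmethod
    def two_cell_mask():
        img = np.zeros((32, 64), np.uint16)
        img[4:28, 4:28] = 1
        img[4:28, 36:60] = 2
        return LabelMask(img, 1.0)

    def test_uniform_aspect_ratio_single_colour(self):
        mask = self.two_cell_mask()
        table = pd.DataFrame({"cell_id": [1, 2], "aspect_ratio": [1.0, 1.0]})
        rgb = colorize_aspect_ratio(mask, table)
        cells = rgb[mask.labels > 0]
        assert (cells == cells[0]).all()

    def test_range_endpoints_hit_colormap_ends(self):
        import matplotlib

        mask = self.two_cell_mask()
        table = pd.DataFrame({"cell_id": [1, 2], "aspect_ratio": [1.0, 4.0]})
        rgb = colorize_aspect_ratio(mask, table, ar_range=(1.0, 4.0), cmap="viridis")
        cmap = matplotlib.colormaps["viridis"]
        lo = (np.asarray(cmap(0.0)[:3]) * 255).astype(np.uint8)
        hi = (np.asarray(cmap(1.0)[:3]) * 255).astype(np.uint8)
        assert np.array_equal(rgb[16, 16], lo)
        assert np.array_equal(rgb[16, 48], hi)
        assert np.array_equal(rgb[0, 0], [0, 0, 0])  # background stays black

    def test_rendering_is_deterministic(self):
        mask = self.two_cell_mask()
        table = pd.DataFrame({"cell_id": [1, 2], "aspect_ratio": [1.3, 2.2]})
        a = colorize_aspect_ratio(mask, table)
        b = colorize_aspect_ratio(mask, table)
        assert np.array_equal(a, b)
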