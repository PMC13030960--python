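"""Preprocessing, colocalization, component volumetrics, and lamina metrics."""

import math

import numpy as np
import pytest

from wfkit.apposition import (
    Component,
    DendriteTrace,
    LabelVolume,
    assign_lamina,
    colocalize_and,
    dendrite_length_and_caliber,
    filter_by_volume,
    label_components,
    lamina_metrics,
    preprocess_binary,
    read_label_tiff,
    read_swc,
    write_label_tiff,
    write_swc,
)


def vol(grid, voxel=(0.06, 0.06, 0.3), channel=""):
    return LabelVolume(grid=np.asarray(grid, dtype=bool), voxel_size=voxel, channel=channel)


def flood_fill_components(grid: np.ndarray, connectivity: int) -> list[frozenset]:
    """Independent BFS component oracle."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    unseen = {tuple(p) for p in np.argwhere(grid)}
    comps = []
    while unseen:
        frontier = [unseen.pop()]
        comp = set(frontier)
        while frontier:
            z, y, x = frontier.pop()
            for dz, dy, dx in offsets:
                nb = (z + dz, y + dy, x + dx)
                if nb in unseen:
                    unseen.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return comps


class TestPreprocess:
    def test_fill_holes_closes_interior(self):
        g = np.zeros((1, 7, 7), bool)
        g[0, 1:6, 1:6] = True
        g[0, 3, 3] = False
        out = preprocess_binary(vol(g), ["fill_holes"])
        assert out.grid.sum() == 25

    def test_erode_3x3_square_to_center(self):
        g = np.zeros((1, 5, 5), bool)
        g[0, 1:4, 1:4] = True
        out = preprocess_binary(vol(g), ["erode"])
        assert out.grid.sum() == 1
        assert out.grid[0, 2, 2]

    def test_watershed_splits_touching_discs(self):
        g = np.zeros((1, 20, 26), bool)
        yy, xx = np.mgrid[0:20, 0:26]
        g[0] = ((yy - 10) ** 2 + (xx - 9) ** 2 <= 16) | ((yy - 10) ** 2 + (xx - 15) ** 2 <= 16)
        out = preprocess_binary(vol(g), ["watershed"])
        assert len(label_components(out, connectivity=26)) == 2

    def test_median_removes_speckle(self):
        g = np.zeros((1, 9, 9), bool)
        g[0, 4, 4] = True  # isolated voxel
        out = preprocess_binary(vol(g), ["median"])
        assert out.grid.sum() == 0

    def test_binarize_thresholds_intensity(self):
        g = np.zeros((1, 3, 3), np.uint8)
        g[0, 1, 1] = 255
        out = preprocess_binary(LabelVolume(grid=g), ["binarize"])
        assert out.grid.dtype == bool and out.grid.sum() == 1

    def test_unknown_step_rejected(self):
        with pytest.raises(ValueError, match="unknown preprocessing step"):
            preprocess_binary(vol(np.zeros((1, 3, 3), bool)), ["sharpen"])

    def test_steps_apply_in_given_order(self):
        # a 1-voxel-wide ring: fill-then-erode keeps a core, erode-then-fill
        # destroys the ring before the hole can be filled
        g = np.zeros((1, 7, 7), bool)
        g[0, 1:6, 1:6] = True
        g[0, 2:5, 2:5] = False
        a = preprocess_binary(vol(g), ["fill_holes", "erode"]).grid.sum()
        b = preprocess_binary(vol(g), ["erode", "fill_holes"]).grid.sum()
        assert a == 9 and b == 0


class TestColocalize:
    def test_self_and_identity_and_empty(self):
        g = np.zeros((2, 4, 4), bool)
        g[0, 1:3, 1:3] = True
        a = vol(g)
        assert np.array_equal(colocalize_and(a, a).grid, a.grid)
        empty = vol(np.zeros_like(g))
        assert colocalize_and(a, empty).grid.sum() == 0

    def test_shared_slab_voxel_count(self):
        a = np.zeros((3, 3, 5), bool)
        b = np.zeros((3, 3, 5), bool)
        a[:, :, 0:3] = True  # 3x3x3 cube
        b[:, :, 1:4] = True  # overlapping cube sharing a 2-wide slab
        out = colocalize_and(vol(a), vol(b))
        assert out.grid.sum() == 18

    def test_commutative_and_subset(self, rng):
        a = vol(rng.random((4, 6, 6)) > 0.5)
        b = vol(rng.random((4, 6, 6)) > 0.5)
        ab = colocalize_and(a, b).grid
        assert np.array_equal(ab, colocalize_and(b, a).grid)
        assert not (ab & ~a.grid.astype(bool)).any()
        assert not (ab & ~b.grid.astype(bool)).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            colocalize_and(vol(np.zeros((1, 2, 2), bool)), vol(np.zeros((1, 3, 3), bool)))


class TestLabelComponents:
    def test_single_voxel_volume(self):
        g = np.zeros((2, 2, 2), bool)
        g[0, 0, 0] = True
        comps = label_components(vol(g))
        assert len(comps) == 1
        assert comps[0].volume_um3 == pytest.approx(0.06 * 0.06 * 0.3)

    def test_empty_volume(self):
        assert label_components(vol(np.zeros((2, 2, 2), bool))) == []

    def test_diagonal_voxels_connectivity(self):
        g = np.zeros((2, 2, 2), bool)
        g[0, 0, 0] = g[1, 1, 1] = True
        assert len(label_components(vol(g), connectivity=26)) == 1
        assert len(label_components(vol(g), connectivity=6)) == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components(vol(np.zeros((1, 1, 1), bool)), connectivity=4)

    def test_volumes_sum_to_total(self, rng):
        g = rng.random((10, 10, 10)) > 0.7
        v = vol(g)
        comps = label_components(v)
        assert sum(c.voxel_count for c in comps) == int(g.sum())
        assert sum(c.volume_um3 for c in comps) == pytest.approx(g.sum() * v.voxel_volume_um3)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        g = rng.random((20, 20, 20)) > 0.8
        comps = label_components(vol(g), connectivity=connectivity)
        oracle = flood_fill_components(g, connectivity)
        assert len(comps) == len(oracle)
        assert sorted(c.voxel_count for c in comps) == sorted(len(o) for o in oracle)


class TestFilterByVolume:
    def test_default_cutoff_keeps_large(self):
        comps = [
            Component(1, 1, 0.00108, (0, 0, 0)),
            Component(2, 27, 0.02916, (1, 1, 1)),
        ]
        kept = filter_by_volume(comps)
        assert [c.label for c in kept] == [2]

    def test_zero_cutoff_is_identity(self):
        comps = [Component(1, 1, 0.001, (0, 0, 0))]
        assert filter_by_volume(comps, 0.0) == comps

    def test_boundary_volume_kept(self):
        comps = [Component(1, 1, 0.0218, (0, 0, 0))]
        assert filter_by_volume(comps, 0.0218) == comps

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            filter_by_volume([], -0.1)

    def test_kept_count_monotone_in_cutoff(self, rng):
        comps = [
            Component(i, 1, float(v), (0, 0, 0))
            for i, v in enumerate(rng.uniform(0.001, 0.5, size=50))
        ]
        counts = [len(filter_by_volume(comps, c)) for c in np.linspace(0, 0.6, 20)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 50


class TestDendriteTrace:
    def test_straight_path_single_lamina(self):
        path = np.array([[0, 50, 5, 0.5], [100, 50, 5, 0.5]], float)
        out = dendrite_length_and_caliber(
            DendriteTrace([path]), {"lSGS": (0.0, 100.0)}
        )
        assert out["lSGS"]["length_um"] == pytest.approx(100.0)
        assert out["lSGS"]["mean_caliber_um"] == pytest.approx(1.0)

    def test_boundary_crossing_splits_length(self):
        path = np.array([[0, 0, 0, 0.5], [0, 100, 0, 0.5]], float)
        out = dendrite_length_and_caliber(
            DendriteTrace([path]), {"upper": (0.0, 50.0), "lower": (50.0, 100.0)}
        )
        assert out["upper"]["length_um"] == pytest.approx(50.0)
        assert out["lower"]["length_um"] == pytest.approx(50.0)

    def test_degenerate_segment_contributes_zero(self):
        path = np.array([[5, 5, 5, 0.5], [5, 5, 5, 0.5], [5, 8, 5, 0.5]], float)
        out = dendrite_length_and_caliber(DendriteTrace([path]), {"a": (0.0, 10.0)})
        assert out["a"]["length_um"] == pytest.approx(3.0)

    def test_swc_round_trip(self, tmp_path):
        trace = DendriteTrace(
            [np.array([[0, 0, 0, 1.0], [10, 0, 0, 1.0], [20, 5, 0, 0.8]], float)]
        )
        path = tmp_path / "trace.swc"
        write_swc(trace, path)
        back = read_swc(path)
        assert back.total_length_um() == pytest.approx(trace.total_length_um())
        np.testing.assert_allclose(back.paths[0], trace.paths[0])


class TestLaminaMetrics:
    def comps(self, n):
        return [Component(i, 30, 0.03, (1, 1, 1)) for i in range(n)]

    def test_density_frequency_rdi_arithmetic(self):
        metrics = lamina_metrics(
            appositions={"lSGS": {"vglut1": self.comps(36), "vglut2": self.comps(36)}},
            boutons={"lSGS": {"vglut1": self.comps(70), "vglut2": self.comps(70)}},
            dendrite_lengths_um={"lSGS": 200.0},
            roi_volumes_um3={"lSGS": 1000.0},
        )["lSGS"]
        assert metrics.vglut1_density == pytest.approx(7.0)  # 70 per 1000 um^3
        assert metrics.vglut1_freq == pytest.approx(18.0)  # 36 per 200 um
        assert metrics.rdi_appositions == pytest.approx(50.0)
        assert metrics.rdi_overall == pytest.approx(50.0)

    def test_zero_denominator_names_lamina(self):
        with pytest.raises(ValueError, match="uSGSv"):
            lamina_metrics(
                appositions={"uSGSv": {"vglut1": []}},
                boutons={},
                dendrite_lengths_um={"uSGSv": 0.0},
                roi_volumes_um3={},
            )

    def test_assign_lamina_by_centroid_depth(self):
        comps = [
            Component(1, 1, 0.01, (5.0, 30.0, 2.0)),
            Component(2, 1, 0.01, (5.0, 80.0, 2.0)),
            Component(3, 1, 0.01, (5.0, 200.0, 2.0)),
        ]
        bounds = {"upper": (0.0, 50.0), "lower": (50.0, 100.0)}
        out = assign_lamina(comps, bounds, depth_axis="y")
        assert [c.lamina for c in out] == ["upper", "lower", None]


class TestTiffIO:
    def test_round_trip(self, tmp_path, rng):
        v = vol(rng.random((4, 8, 8)) > 0.5, channel="vglut2")
        path = tmp_path / "ch.tif"
        write_label_tiff(v, path)
        back = read_label_tiff(path, channel="vglut2")
        assert np.array_equal(back.grid, v.grid)
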