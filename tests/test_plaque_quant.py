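"""Plaque detection, region assignment, densities and reduction rates."""

import numpy as np
import pandas as pd
import pytest

from lymphomorph import plaque_quant as pq
from lymphomorph import synthetic_data as sd
from lymphomorph.imaging_io import BrainVolume, LabelVolume


def flood_fill_components(binary: np.ndarray, min_voxels: int = 1):
    """Brute-force 26-connected component oracle (explicit BFS)."""
    visited = np.zeros(binary.shape, dtype=bool)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
    sizes = []
    for start in zip(*np.nonzero(binary)):
        if visited[start]:
            continue
        stack, size = [start], 0
        visited[start] = True
        while stack:
            z, y, x = stack.pop()
            size += 1
            for dz, dy, dx in offsets:
                n = (z + dz, y + dy, x + dx)
                if (
                    0 <= n[0] < binary.shape[0]
                    and 0 <= n[1] < binary.shape[1]
                    and 0 <= n[2] < binary.shape[2]
                    and binary[n]
                    and not visited[n]
                ):
                    visited[n] = True
                    stack.append(n)
        if size >= min_voxels:
            sizes.append(size)
    return sorted(sizes)


def _volume_from_binary(binary, spacing=(1.0, 1.0, 1.0)):
    return BrainVolume(binary.astype(np.float64), spacing)


class TestDetectPlaques:
    def test_single_blob_detected_with_its_size(self):
        arr = np.zeros((8, 8, 8))
        arr[3, 3, 2:7] = 10.0  # 5-voxel bright line
        ps = pq.detect_plaques(
            _volume_from_binary(arr > 0), threshold_method="fixed",
            fixed_threshold=0.5, min_voxels=2,
        )
        assert len(ps) == 1
        assert ps.plaques[0].voxel_count == 5

    def test_min_voxels_filter_boundary(self):
        arr = np.zeros((8, 8, 8))
        arr[3, 3, 2:7] = 10.0
        ps = pq.detect_plaques(
            _volume_from_binary(arr > 0), threshold_method="fixed",
            fixed_threshold=0.5, min_voxels=6,
        )
        assert len(ps) == 0

    def test_constant_volume_otsu_errors(self):
        vol = BrainVolume(np.full((4, 4, 4), 7.0), (1, 1, 1))
        with pytest.raises(pq.PlaqueError):
            pq.detect_plaques(vol, threshold_method="otsu")

    @pytest.mark.parametrize("seed", range(5))
    def test_counts_and_sizes_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((24, 24, 24)) < 0.15
        ps = pq.detect_plaques(
            _volume_from_binary(binary), threshold_method="fixed",
            fixed_threshold=0.5, min_voxels=2,
        )
        expected = flood_fill_components(binary, min_voxels=2)
        assert sorted(p.voxel_count for p in ps.plaques) == expected

    def test_sphere_field_recovers_truth_centroids(self, single_region_labels):
        vol, truth = sd.gen_plaque_volume(
            single_region_labels, {1: 0.02}, snr=10.0, seed=9
        )
        ps = pq.detect_plaques(vol, threshold_method="otsu", min_voxels=5)
        true_centers = truth.params["regions"][1]["centers_zyx"]
        assert len(ps) == len(true_centers)
        found = np.asarray([p.centroid_zyx for p in ps.plaques])
        for c in true_centers:
            assert np.min(np.linalg.norm(found - np.asarray(c), axis=1)) <= 1.0

    def test_raising_threshold_never_increases_detections(self, rng):
        arr = rng.normal(100, 10, (20, 20, 20))
        arr[5:8, 5:8, 5:8] += 80
        vol = BrainVolume(arr, (1, 1, 1))
        prev_vol = np.inf
        for thr in (110.0, 130.0, 150.0, 170.0):
            ps = pq.detect_plaques(
                vol, threshold_method="fixed", fixed_threshold=thr, min_voxels=1
            )
            total = sum(p.voxel_count for p in ps.plaques)
            assert total <= prev_vol
            prev_vol = total


class TestAssignRegions:
    def _labels(self):
        grid = np.zeros((12, 12, 12), dtype=np.int32)
        grid[5, 10, 4] = 3
        return LabelVolume(grid, {3: "CA1"})

    def test_centroid_rounded_to_nearest_voxel(self):
        ps = pq.PlaqueSet(
            [pq.Plaque(1, (5.4, 10.1, 3.9), 4, 4.0, 1.0)],
            (12, 12, 12), (1, 1, 1), 0.5, 1,
        )
        pq.assign_regions(ps, self._labels())
        assert ps.plaques[0].region == 3

    def test_background_centroid_keeps_region_zero(self):
        ps = pq.PlaqueSet(
            [pq.Plaque(1, (1.0, 1.0, 1.0), 4, 4.0, 1.0)],
            (12, 12, 12), (1, 1, 1), 0.5, 1,
        )
        pq.assign_regions(ps, self._labels())
        assert ps.plaques[0].region == 0
        table = pq.region_density(ps, self._labels())
        assert table["plaque_count"].sum() == 0

    def test_shape_mismatch_errors(self):
        ps = pq.PlaqueSet([], (10, 10, 10), (1, 1, 1), 0.5, 1)
        with pytest.raises(pq.PlaqueError, match="shape"):
            pq.assign_regions(ps, self._labels())


class TestRegionDensity:
    def test_volume_fraction_arithmetic(self):
        # voxel volume 100 um^3; one 1-voxel plaque in a 10^4-voxel region
        spacing = (100.0 ** (1 / 3),) * 3
        grid = np.ones((10, 40, 25), dtype=np.int32)  # 10^4 voxels = 10^6 um^3
        labels = LabelVolume(grid, {1: "R"})
        arr = np.zeros((10, 40, 25))
        arr[5, 5, 5] = 10.0
        vol = BrainVolume(arr, spacing)
        ps = pq.detect_plaques(vol, threshold_method="fixed", fixed_threshold=1.0,
                               min_voxels=1)
        pq.assign_regions(ps, labels)
        table = pq.region_density(ps, labels, spacing)
        assert table["volume_fraction"].iloc[0] == pytest.approx(1e-4, rel=1e-9)

    def test_region_without_plaques_reports_zero(self, two_region_labels):
        ps = pq.PlaqueSet([], (24, 48, 48), (1, 1, 1), 0.5, 1)
        table = pq.region_density(ps, two_region_labels)
        assert (table["plaque_count"] == 0).all()
        assert (table["volume_fraction"] == 0).all()

    def test_generated_fraction_recovered(self, single_region_labels):
        vol, truth = sd.gen_plaque_volume(
            single_region_labels, {1: 0.02}, snr=10.0, seed=4
        )
        ps = pq.detect_plaques(vol, threshold_method="otsu", min_voxels=5)
        pq.assign_regions(ps, single_region_labels)
        table = pq.region_density(ps, single_region_labels, vol.spacing_um)
        realized = truth.params["regions"][1]["realized_fraction"]
        assert table["volume_fraction"].iloc[0] == pytest.approx(realized, rel=0.10)


class TestMergeRegions:
    def _table(self):
        return pd.DataFrame(
            [
                {"label": 1, "acronym": "A", "plaque_count": 2,
                 "total_plaque_volume_um3": 50.0, "region_volume_um3": 1e9,
                 "count_density_per_mm3": 2.0, "volume_fraction": 5e-8},
                {"label": 2, "acronym": "B", "plaque_count": 3,
                 "total_plaque_volume_um3": 70.0, "region_volume_um3": 1e9,
                 "count_density_per_mm3": 3.0, "volume_fraction": 7e-8},
            ]
        )

    def test_merge_pools_counts_and_recomputes_density(self):
        merged = pq.merge_region_groups(self._table(), {"AB": [1, 2]})
        row = merged.iloc[0]
        assert row["plaque_count"] == 5
        assert row["count_density_per_mm3"] == pytest.approx(2.5)

    def test_single_member_merge_is_identity(self):
        merged = pq.merge_region_groups(self._table(), {"A": [1]})
        row = merged.iloc[0]
        assert row["plaque_count"] == 2
        assert row["volume_fraction"] == pytest.approx(5e-8)

    def test_unknown_member_errors(self):
        with pytest.raises(pq.PlaqueError, match="unknown member"):
            pq.merge_region_groups(self._table(), {"X": [1, 9]})


class TestReductionRate:
    def test_group_mean_ratio_arithmetic(self):
        r = pq.reduction_rate([1.0], [0.61])
        assert r.reduction_rate_pct == pytest.approx(39.0)

    def test_identical_groups_give_zero(self):
        r = pq.reduction_rate([1.0, 1.2], [1.0, 1.2])
        assert r.reduction_rate_pct == pytest.approx(0.0)

    def test_fully_cleared_treatment_gives_100(self):
        r = pq.reduction_rate([1.0, 2.0], [0.0, 0.0])
        assert r.reduction_rate_pct == pytest.approx(100.0)

    def test_zero_control_mean_errors(self):
        with pytest.raises(pq.PlaqueError, match="undefined"):
            pq.reduction_rate([0.0, 0.0], [1.0])

    def test_welch_statistics_attached(self):
        r = pq.reduction_rate([1.0, 1.1, 0.9, 1.05, 0.95], [0.6, 0.65, 0.55, 0.62, 0.58])
        assert r.p < 0.001
        assert r.stars == "***"
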