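import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bullseye_wmh import (FAZEKAS, MANOLIO, SCHELTENS, LabeledVolume,
                          aggregate_scale_features, compute_regional_loads,
                          default_subscale_regions, plant_lesions,
                          total_burden)
from bullseye_wmh.loads import RegionalLoadTable, cohort_to_frame, frame_to_cohort
from bullseye_wmh.zones import RegionMap


def tiny_region_map():
    """Two regions: id 1 fills the left half, id 2 the right half."""
    labels = np.zeros((4, 10, 10), dtype=np.int16)
    labels[:2] = 1
    labels[2:] = 2
    return RegionMap(labels=labels, n_layers=4)


class TestRegionalLoads:
    def test_fraction_arithmetic(self):
        rm = tiny_region_map()
        lesion = np.zeros(rm.labels.shape, dtype=np.int16)
        lesion[0, :5, :] = 1  # 50 voxels in the 200-voxel region 1
        t = compute_regional_loads(LabeledVolume(lesion), rm)
        assert t.load[0] == 0.25
        assert t.load[1] == 0.0

    def test_full_region_saturates_at_one(self):
        rm = tiny_region_map()
        lesion = (rm.labels == 1).astype(np.int16)
        t = compute_regional_loads(LabeledVolume(lesion), rm)
        assert t.load[0] == 1.0

    def test_empty_lesion(self):
        rm = tiny_region_map()
        t = compute_regional_loads(
            LabeledVolume(np.zeros(rm.labels.shape, dtype=np.int16)), rm)
        assert np.all(t.load == 0)
        assert t.total_lesion_volume_ml == 0

    def test_lesion_outside_map_counted_separately(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[0] = 1
        rm = RegionMap(labels=labels, n_layers=4)
        lesion = np.zeros_like(labels)
        lesion[0, 0, 0] = 1
        lesion[3, 3, 3] = 1  # outside the region map
        t = compute_regional_loads(LabeledVolume(lesion), rm)
        assert t.unassigned_lesion_voxels == 1
        assert t.load[0] == pytest.approx(1 / 16)

    def test_conservation_identity(self, full_parcellation):
        rm = full_parcellation.regions
        rng = np.random.default_rng(3)
        lesion, _ = plant_lesions(rm, rng.uniform(0, 0.4, 36), seed=4)
        t = compute_regional_loads(lesion, rm)
        lesion_mm3 = (t.load * t.region_volume_mm3).sum()
        assert lesion_mm3 == pytest.approx(t.total_lesion_volume_ml * 1000.0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_monotonicity_adding_lesion_never_decreases_loads(self, seed):
        rm = tiny_region_map()
        rng = np.random.default_rng(seed)
        a = rng.random(rm.labels.shape) < 0.2
        b = a | (rng.random(rm.labels.shape) < 0.2)
        ta = compute_regional_loads(LabeledVolume(a.astype(np.int16)), rm)
        tb = compute_regional_loads(LabeledVolume(b.astype(np.int16)), rm)
        assert np.all(tb.load >= ta.load)


class TestTotalBurden:
    @pytest.mark.parametrize("n_voxels,voxel_size,expected_ml", [
        (1000, (1, 1, 1), 1.0), (0, (1, 1, 1), 0.0), (500, (1, 1, 2), 1.0)])
    def test_volume_in_ml(self, n_voxels, voxel_size, expected_ml):
        grid = np.zeros((20, 20, 20), dtype=np.int16)
        grid.ravel()[:n_voxels] = 1
        assert total_burden(LabeledVolume(grid, voxel_size)) == expected_ml


class TestScaleFeatures:
    def _loads(self, load, volumes=None):
        load = np.asarray(load, dtype=float)
        vols = np.ones_like(load) * 100 if volumes is None else np.asarray(volumes)
        return RegionalLoadTable(load=load, region_volume_mm3=vols,
                                 total_lesion_volume_ml=0.0,
                                 global_relative_burden=0.0)

    def test_equal_volume_mean(self):
        loads = self._loads(np.zeros(36))
        loads.load[[0, 4]] = 0.4  # frontal layer-1 L and R
        fs = aggregate_scale_features(loads, SCHELTENS)
        assert fs.features["FC"] == pytest.approx(0.4)

    def test_volume_weighting(self):
        loads = self._loads(np.zeros(36), volumes=np.ones(36))
        loads.load[0], loads.load[4] = 0.1, 0.4
        loads.region_volume_mm3[0], loads.region_volume_mm3[4] = 300.0, 100.0
        fs = aggregate_scale_features(loads, SCHELTENS)
        assert fs.features["FC"] == pytest.approx((0.1 * 300 + 0.4 * 100) / 400)

    def test_zero_loads_zero_features(self):
        fs = aggregate_scale_features(self._loads(np.zeros(36)), MANOLIO)
        assert all(v == 0 for v in fs.features.values())

    def test_single_region_mapping_is_identity(self):
        loads = self._loads(np.linspace(0, 0.35, 36))
        fs = aggregate_scale_features(loads, MANOLIO,
                                      mapping={"Manolio": (7,)})
        assert fs.features["Manolio"] == pytest.approx(loads.load[6])

    def test_unmapped_subscale_rejected(self):
        with pytest.raises(KeyError, match="PV"):
            aggregate_scale_features(self._loads(np.zeros(36)), FAZEKAS,
                                     mapping={"DWM": (1,)})

    def test_default_mapping_covers_every_subscale(self):
        for scale in (MANOLIO, FAZEKAS, SCHELTENS):
            mapping = default_subscale_regions(scale)
            assert set(mapping) >= set(scale.subscale_ids)
            for rids in mapping.values():
                assert all(1 <= r <= 36 for r in rids)

    def test_fazekas_pv_maps_to_layer1_only(self):
        mapping = default_subscale_regions(FAZEKAS)
        from bullseye_wmh import region_zone_layer
        assert all(region_zone_layer(r)[1] == 1 for r in mapping["PV"])
        assert all(region_zone_layer(r)[1] > 1 for r in mapping["DWM"])


class TestFrameRoundTrip:
    def test_cohort_frame_round_trip(self):
        rng = np.random.default_rng(5)
        cohort = {}
        for s in ("a", "b"):
            cohort[s] = RegionalLoadTable(
                load=rng.uniform(0, 1, 36),
                region_volume_mm3=rng.uniform(50, 150, 36),
                total_lesion_volume_ml=float(rng.uniform(0, 5)),
                global_relative_burden=float(rng.uniform(0, 0.2)))
        back = frame_to_cohort(cohort_to_frame(cohort))
        for s in cohort:
            assert np.allclose(back[s].load, cohort[s].load)
            assert back[s].total_lesion_volume_ml == pytest.approx(
                cohort[s].total_lesion_volume_ml)
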