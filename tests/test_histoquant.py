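"""Pixel classification, margin exclusion, watershed separation, object
filtering, crown classification and zonal summaries."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist

from wdnafld import histoquant, synth
from wdnafld.histoquant import (
    CLASS_CODES,
    LabelImage,
    classify_crowns,
    classify_pixels,
    exclude_margin,
    measure_and_filter,
    separate_droplets,
    zonal_quantification,
)
from wdnafld.synth.slides import SlideChannels


def _disc(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _channels(shape=(64, 64), um_per_px=1.0, **masks):
    zeros = np.zeros(shape, dtype=np.float32)
    return SlideChannels(
        lipid=masks.get("lipid", zeros).astype(np.float32),
        macrophage=masks.get("macrophage", zeros).astype(np.float32),
        zone_marker=masks.get("zone", zeros).astype(np.float32),
        tissue_mask=masks.get("tissue", np.zeros(shape, dtype=bool)),
        um_per_px=um_per_px,
    )


class TestClassifyPixels:
    def test_all_zero_is_background(self):
        pm = classify_pixels(_channels())
        assert (pm.classes == CLASS_CODES["background"]).all()

    def test_priority_order(self):
        ones = np.ones((4, 4), dtype=np.float32)
        pm = classify_pixels(_channels(shape=(4, 4), lipid=ones, macrophage=ones,
                                       zone=ones, tissue=np.ones((4, 4), bool)))
        assert (pm.classes == CLASS_CODES["lipid"]).all()
        assert pm.zone_mask.all()  # raw zone mask survives the priority stack

    def test_synthetic_slide_accuracy(self):
        spec = synth.SlideSpec(shape=(256, 256), um_per_px=1.0, n_droplets=8,
                               diameter_um=(8, 14), fraction_crowned=0.5)
        channels, _ = synth.simulate_histology_image(spec, seed=0)
        pm = classify_pixels(channels)
        acc = (pm.mask("lipid") == (channels.lipid >= 0.5)).mean()
        assert acc >= 0.99
        assert (pm.mask("macrophage") == ((channels.macrophage >= 0.5)
                                          & ~(channels.lipid >= 0.5))).all()

    def test_shape_mismatch_rejected(self):
        ch = _channels()
        ch.macrophage = np.zeros((8, 8), dtype=np.float32)
        with pytest.raises(ValueError):
            classify_pixels(ch)


class TestExcludeMargin:
    def test_zero_margin_is_identity(self):
        mask = _disc((32, 32), (16, 16), 5)
        tissue = np.ones((32, 32), bool)
        assert np.array_equal(exclude_margin(mask, tissue, 0.0, 1.0), mask)

    def test_object_near_boundary_removed(self):
        # tissue edge at column 0; object centered 10 um from it, margin 20 um
        tissue = np.zeros((64, 64), bool)
        tissue[:, 1:] = True
        mask = _disc((64, 64), (32, 11), 3)
        out = exclude_margin(mask, tissue, 20.0, 1.0)
        assert not out.any()

    def test_matches_exhaustive_distance_oracle(self):
        rng = np.random.default_rng(0)
        tissue = np.ones((64, 64), bool)
        tissue[:8, :] = False
        tissue[:, 50:] = False
        mask = rng.random((64, 64)) < 0.2
        margin = 6.0
        got = exclude_margin(mask, tissue, margin, 1.0)
        bg = np.argwhere(~tissue)
        want = np.zeros_like(mask)
        for r, c in np.argwhere(mask):
            if not tissue[r, c]:
                continue
            d = cdist([[r, c]], bg).min()
            want[r, c] = d >= margin
        assert np.array_equal(got, want)

    def test_empty_tissue_rejected(self):
        with pytest.raises(ValueError):
            exclude_margin(np.ones((4, 4), bool), np.zeros((4, 4), bool), 5.0, 1.0)


class TestSeparateDroplets:
    def test_single_disc_single_label(self):
        mask = _disc((64, 64), (32, 32), 10)
        lab = separate_droplets(mask, 1.0)
        assert lab.n_objects == 1

    def test_overlapping_pair_split_with_centers_apart(self):
        mask = _disc((64, 64), (32, 26), 10) | _disc((64, 64), (32, 38), 10)
        lab = separate_droplets(mask, 1.0)
        assert lab.n_objects == 2
        assert lab.labels[32, 26] != lab.labels[32, 38]
        assert lab.labels[32, 26] > 0 and lab.labels[32, 38] > 0

    def test_labels_partition_mask(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((128, 128), bool)
        for _ in range(6):
            r, c = rng.integers(15, 113, size=2)
            mask |= _disc((128, 128), (r, c), rng.integers(5, 12))
        lab = separate_droplets(mask, 1.0)
        assert np.array_equal(lab.labels > 0, mask)

    def test_empty_mask(self):
        lab = separate_droplets(np.zeros((8, 8), bool), 1.0)
        assert lab.n_objects == 0

    def test_deterministic(self):
        mask = _disc((64, 64), (30, 30), 9) | _disc((64, 64), (30, 42), 9)
        l1 = separate_droplets(mask, 1.0)
        l2 = separate_droplets(mask, 1.0)
        assert np.array_equal(l1.labels, l2.labels)


class TestMeasureAndFilter:
    def test_small_disc_removed(self):
        # 2.0 um diameter < 2.3 um threshold at 0.44 um/px
        mask = _disc((32, 32), (16, 16), 2.0 / 2 / 0.44)
        ds = measure_and_filter(separate_droplets(mask, 0.44))
        assert ds.objects == []

    def test_regular_disc_retained(self):
        mask = _disc((64, 64), (32, 32), 5.0 / 2 / 0.44)
        ds = measure_and_filter(separate_droplets(mask, 0.44))
        assert len(ds.objects) == 1
        obj = ds.objects[0]
        assert obj.equivalent_diameter_um == pytest.approx(5.0, rel=0.1)
        assert obj.roundness > 0.85

    def test_thin_line_removed_by_roundness(self):
        mask = np.zeros((40, 40), bool)
        mask[20, 5:35] = True  # 1 px x 30 px line, diameter ~6.2 um at 1 um/px
        lab = LabelImage(mask.astype(np.int32), 1.0)
        ds = measure_and_filter(lab, min_diameter_um=2.3, min_roundness=0.5)
        assert ds.objects == []

    def test_idempotent_and_contiguous(self):
        mask = _disc((64, 64), (20, 20), 8) | _disc((64, 64), (45, 45), 8)
        ds = measure_and_filter(separate_droplets(mask, 1.0))
        labels = sorted(o.label for o in ds.objects)
        assert labels == [1, 2]
        again = measure_and_filter(ds.labels)
        assert [o.area_um2 for o in again.objects] == [o.area_um2 for o in ds.objects]


class TestClassifyCrowns:
    @staticmethod
    def _ringed(diameter_um, um_per_px=0.5, shape=(96, 96)):
        r_px = diameter_um / 2 / um_per_px
        droplet = _disc(shape, (48, 48), r_px)
        ring = _disc(shape, (48, 48), r_px + 3.0 / um_per_px) & ~droplet
        ds = measure_and_filter(separate_droplets(droplet, um_per_px))
        return classify_crowns(ds, ring)

    def test_fully_ringed_large_droplet_crowned(self):
        ds = self._ringed(10.0)
        assert ds.objects[0].crowned
        assert ds.objects[0].crown_coverage == pytest.approx(1.0)

    def test_small_ringed_droplet_excluded(self):
        ds = self._ringed(4.0)  # below the 4.42 um lipogranuloma size rule
        assert ds.objects[0].crown_coverage == pytest.approx(1.0)
        assert not ds.objects[0].crowned

    def test_naked_droplet_not_crowned(self):
        droplet = _disc((64, 64), (32, 32), 10)
        ds = measure_and_filter(separate_droplets(droplet, 1.0))
        ds = classify_crowns(ds, np.zeros((64, 64), bool))
        assert not ds.objects[0].crowned and ds.objects[0].crown_coverage == 0.0

    def test_synthetic_slide_crowns_exactly_recovered(self):
        spec = synth.SlideSpec(shape=(512, 512), um_per_px=0.44, n_droplets=20,
                               diameter_um=(6, 12), fraction_crowned=0.5)
        channels, truth = synth.simulate_histology_image(spec, seed=3)
        pm = classify_pixels(channels)
        ds = measure_and_filter(separate_droplets(pm.mask("lipid"), 0.44))
        ds = classify_crowns(ds, pm.mask("macrophage"))
        got = {}
        for o in ds.objects:
            x, y = o.centroid_um
            nearest = min(truth, key=lambda t: (t.center_um[0] - x) ** 2
                          + (t.center_um[1] - y) ** 2)
            got[nearest.object_id] = o.crowned
        for t in truth:
            if t.kind == "droplet":
                assert got[t.object_id] == t.crowned


class TestZonalQuantification:
    @staticmethod
    def _scene():
        shape = (128, 128)
        tissue = np.ones(shape, bool)
        zone = np.zeros(shape, np.float32)
        zone[:, :64] = 1.0
        lipid = np.zeros(shape, np.float32)
        lipid[_disc(shape, (40, 30), 8)] = 1.0   # pericentral
        lipid[_disc(shape, (90, 30), 6)] = 1.0   # pericentral
        ch = _channels(shape=shape, lipid=lipid, zone=zone, tissue=tissue)
        pm = classify_pixels(ch)
        ds = measure_and_filter(separate_droplets(pm.mask("lipid"), 1.0))
        ds = classify_crowns(ds, np.zeros(shape, bool))
        return ds, pm, tissue

    def test_all_droplets_in_one_zone(self):
        ds, pm, tissue = self._scene()
        zs = zonal_quantification(ds, pm, tissue)
        assert zs.zones["periportal_midzonal"].lipid_area_fraction == 0.0
        assert zs.zones["periportal_midzonal"].droplet_count == 0
        assert zs.zones["pericentral"].droplet_count == 2

    def test_area_fraction_matches_analytic(self):
        ds, pm, tissue = self._scene()
        zs = zonal_quantification(ds, pm, tissue)
        analytic = (np.pi * 8**2 + np.pi * 6**2) / (64 * 128)
        assert zs.zones["pericentral"].lipid_area_fraction == pytest.approx(
            analytic, rel=0.05
        )

    def test_density_counts_only_crowns(self):
        ds, pm, tissue = self._scene()
        for o in ds.objects:
            o.crowned = True
        zs = zonal_quantification(ds, pm, tissue)
        area_mm2 = 64 * 128 / 1e6
        assert zs.zones["pericentral"].lipogranuloma_density_per_mm2 == pytest.approx(
            2 / area_mm2
        )


def test_full_pipeline_recovers_truth_within_tolerance():
    """End-to-end on a synthetic slide with overlapping droplets."""
    spec = synth.SlideSpec(shape=(600, 600), um_per_px=0.44, n_droplets=30,
                           diameter_um=(5, 12), fraction_crowned=0.3,
                           fraction_overlapping=0.3, n_kupffer=3)
    channels, truth = synth.simulate_histology_image(spec, seed=5)
    pm = classify_pixels(channels)
    lipid = exclude_margin(pm.mask("lipid"), channels.tissue_mask, 20.0, 0.44)
    ds = measure_and_filter(separate_droplets(lipid, 0.44))
    n_true = sum(1 for t in truth if t.kind == "droplet")
    assert abs(len(ds.objects) - n_true) <= max(1, round(0.05 * n_true))
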