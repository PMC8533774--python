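"""Lipid-droplet and lipogranuloma quantification on tissue images.

Pipeline: rule-based pixel classification of the stain channels; exclusion
of structures within a margin of the tissue boundary (default 20 um,
guarding against cutting/staining artifacts); separation of touching
droplets by marker-controlled watershed seeded at local maxima of the
Euclidean distance transform; size (> 2.3 um diameter) and roundness
(4*pi*A/P^2, default >= 0.5) filtering; crown classification of
lipogranulomas ("macrophage crowns") from the macrophage coverage of an
annulus around each droplet, with droplets below 4.42 um diameter
excluded; and per-lobular-zone summarization (pericentral vs
periportal/midzonal) of lipid area fractions and lipogranuloma density.

All geometry is reported in micrometers, so results are comparable across
pixel resolutions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.segmentation import watershed

CLASS_CODES = {"background": 0, "tissue": 1, "zone_marker": 2, "macrophage": 3, "lipid": 4}
DEFAULT_MARGIN_UM = 20.0
DEFAULT_MIN_DIAMETER_UM = 2.3
DEFAULT_MIN_ROUNDNESS = 0.5
DEFAULT_ANNULUS_UM = 3.0
DEFAULT_COVERAGE_THRESHOLD = 0.3
DEFAULT_MIN_CROWN_DIAMETER_UM = 4.42
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class PixelClassMap:
    classes: np.ndarray        # int codes per CLASS_CODES
    um_per_px: float
    zone_mask: np.ndarray      # raw zone-marker-positive mask (pre-priority)

    def mask(self, name: str) -> np.ndarray:
        return self.classes == CLASS_CODES[name]


@dataclass
class LabelImage:
    labels: np.ndarray
    um_per_px: float

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


@dataclass
class DropletObject:
    label: int
    area_um2: float
    equivalent_diameter_um: float
    perimeter_um: float
    roundness: float
    centroid_um: tuple[float, float]  # (x, y) = (col, row)
    zone: str | None = None
    crowned: bool = False
    crown_coverage: float = 0.0


@dataclass
class DropletSet:
    objects: list[DropletObject]
    labels: LabelImage


@dataclass
class ZoneStats:
    lipid_area_fraction: float
    droplet_count: int
    lipogranuloma_count: int
    lipogranuloma_density_per_mm2: float


@dataclass
class ZonalSummary:
    zones: dict[str, ZoneStats] = field(default_factory=dict)


def classify_pixels(channels, thresholds: dict | None = None) -> PixelClassMap:
    """Priority-ordered channel thresholding.

    ``channels`` provides ``lipid``, ``macrophage``, ``zone_marker`` arrays
    and a boolean ``tissue_mask`` sharing one shape (a
    :class:`~wdnafld.synth.slides.SlideChannels` works directly).  Priority:
    lipid > macrophage > zone_marker > tissue > background.
    """
    thr = {"lipid": 0.5, "macrophage": 0.5, "zone_marker": 0.5}
    if thresholds:
        thr.update(thresholds)
    lipid = np.asarray(channels.lipid)
    macro = np.asarray(channels.macrophage)
    zone = np.asarray(channels.zone_marker)
    tissue = np.asarray(channels.tissue_mask, dtype=bool)
    if not (lipid.shape == macro.shape == zone.shape == tissue.shape):
        raise ValueError("all channels must share one shape")
    classes = np.zeros(lipid.shape, dtype=np.uint8)
    zone_mask = zone >= thr["zone_marker"]
    classes[tissue] = CLASS_CODES["tissue"]
    classes[zone_mask] = CLASS_CODES["zone_marker"]
    classes[macro >= thr["macrophage"]] = CLASS_CODES["macrophage"]
    classes[lipid >= thr["lipid"]] = CLASS_CODES["lipid"]
    return PixelClassMap(classes, float(channels.um_per_px), zone_mask)


def exclude_margin(mask, tissue_mask, margin_um: float = DEFAULT_MARGIN_UM, um_per_px: float = 1.0):
    """Clear positive pixels closer than ``margin_um`` to the tissue boundary.

    Distance is the Euclidean distance (in um) from an in-tissue pixel to
    the nearest non-tissue pixel; pixels outside the tissue have distance 0.
    """
    mask = np.asarray(mask, dtype=bool)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not tissue.any():
        raise ValueError("tissue mask is empty")
    if margin_um < 0:
        raise ValueError("margin must be >= 0")
    if margin_um == 0:
        return mask.copy()
    dist = ndi.distance_transform_edt(tissue) * um_per_px
    return mask & (dist >= margin_um)


def separate_droplets(
    lipid_mask, um_per_px: float, min_seed_distance_um: float = DEFAULT_MIN_DIAMETER_UM
) -> LabelImage:
    """Split touching droplets by marker-controlled watershed.

    Seeds are local maxima of the Euclidean distance transform to the
    background with a minimum separation of ``min_seed_distance_um``;
    the watershed runs on the negated distance transform restricted to the
    mask.  Every connected component receives at least one label; ties are
    broken in scanline order, so the labeling is deterministic.
    """
    mask = np.asarray(lipid_mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return LabelImage(out, um_per_px)
    edt = ndi.distance_transform_edt(mask)
    cc, _ = ndi.label(mask, structure=_FOUR_CONN)
    min_dist_px = max(1, int(round(min_seed_distance_um / um_per_px)))
    coords = peak_local_max(edt, min_distance=min_dist_px, labels=cc, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    labels = watershed(-edt, markers, mask=mask, connectivity=1)
    # defensive: any component that lost its seed keeps a single label
    orphan = mask & (labels == 0)
    if orphan.any():
        oc, n = ndi.label(orphan, structure=_FOUR_CONN)
        labels = labels + np.where(oc > 0, oc + labels.max(), 0)
    # relabel contiguously in first-appearance (scanline) order
    ids = labels[labels > 0]
    _, inverse = np.unique(ids, return_inverse=True)
    first_seen = {}
    nxt = 1
    flat = labels.ravel()
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    for v in flat:
        if v and v not in first_seen:
            first_seen[v] = nxt
            remap[v] = nxt
            nxt += 1
    out = remap[labels]
    return LabelImage(out, um_per_px)


def _roundness(area_px: float, perimeter_px: float) -> float:
    if perimeter_px <= 0:
        return 1.0
    return float(min(1.0, 4.0 * np.pi * area_px / perimeter_px**2))


def measure_and_filter(
    labels: LabelImage,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    min_roundness: float = DEFAULT_MIN_ROUNDNESS,
) -> DropletSet:
    """Measure objects in um units and drop small or irregular ones.

    Retains objects with equivalent diameter strictly above
    ``min_diameter_um`` and roundness >= ``min_roundness``; survivors are
    relabeled contiguously.
    """
    mpp = labels.um_per_px
    objects: list[DropletObject] = []
    new_labels = np.zeros_like(labels.labels)
    nxt = 1
    for prop in regionprops(labels.labels):
        area_um2 = prop.area * mpp**2
        diameter = 2.0 * np.sqrt(area_um2 / np.pi)
        roundness = _roundness(prop.area, prop.perimeter)
        if diameter <= min_diameter_um or roundness < min_roundness:
            continue
        r0, c0 = prop.centroid
        objects.append(
            DropletObject(
                label=nxt,
                area_um2=float(area_um2),
                equivalent_diameter_um=float(diameter),
                perimeter_um=float(prop.perimeter * mpp),
                roundness=roundness,
                centroid_um=(float(c0 * mpp), float(r0 * mpp)),
            )
        )
        new_labels[labels.labels == prop.label] = nxt
        nxt += 1
    return DropletSet(objects, LabelImage(new_labels, mpp))


def classify_crowns(
    droplets: DropletSet,
    macrophage_mask,
    annulus_width_um: float = DEFAULT_ANNULUS_UM,
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    min_crown_diameter_um: float = DEFAULT_MIN_CROWN_DIAMETER_UM,
) -> DropletSet:
    """Flag lipogranulomas by macrophage coverage of a surrounding annulus.

    ``crown_coverage`` is the macrophage-positive fraction of the ring of
    width ``annulus_width_um`` just outside the droplet; a droplet is
    crowned when coverage >= threshold and its equivalent diameter is at
    least ``min_crown_diameter_um``.  Rings clipped by the image border are
    evaluated over their in-bounds part (with a warning).
    """
    macro = np.asarray(macrophage_mask, dtype=bool)
    lab = droplets.labels.labels
    mpp = droplets.labels.um_per_px
    if macro.shape != lab.shape:
        raise ValueError("macrophage mask shape does not match the label image")
    w_px = annulus_width_um / mpp
    pad = int(np.ceil(w_px)) + 1
    out = []
    slices = ndi.find_objects(lab)
    for obj in droplets.objects:
        sl = slices[obj.label - 1]
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, lab.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, lab.shape[1])
        if (sl[0].start - pad < 0 or sl[0].stop + pad > lab.shape[0]
                or sl[1].start - pad < 0 or sl[1].stop + pad > lab.shape[1]):
            warnings.warn(
                f"annulus of droplet {obj.label} clipped by the image border", stacklevel=2
            )
        crop = lab[r0:r1, c0:c1] == obj.label
        dist = ndi.distance_transform_edt(~crop)
        ring = (dist > 0) & (dist <= w_px)
        coverage = float(macro[r0:r1, c0:c1][ring].mean()) if ring.any() else 0.0
        crowned = (
            coverage >= coverage_threshold
            and obj.equivalent_diameter_um >= min_crown_diameter_um
        )
        out.append(replace(obj, crowned=crowned, crown_coverage=coverage))
    return DropletSet(out, droplets.labels)


def zonal_quantification(droplets: DropletSet, pixel_map: PixelClassMap, tissue_mask) -> ZonalSummary:
    """Per-zone lipid area fraction, droplet counts and lipogranuloma density.

    A droplet belongs to the pericentral zone when its centroid lies in
    the zone-marker-positive region; otherwise to periportal/midzonal.
    """
    tissue = np.asarray(tissue_mask, dtype=bool)
    mpp = pixel_map.um_per_px
    zone_masks = {
        "pericentral": tissue & pixel_map.zone_mask,
        "periportal_midzonal": tissue & ~pixel_map.zone_mask,
    }
    assigned: dict[str, list[DropletObject]] = {z: [] for z in zone_masks}
    for obj in droplets.objects:
        c_px = int(round(obj.centroid_um[0] / mpp))
        r_px = int(round(obj.centroid_um[1] / mpp))
        r_px = np.clip(r_px, 0, tissue.shape[0] - 1)
        c_px = np.clip(c_px, 0, tissue.shape[1] - 1)
        zone = "pericentral" if pixel_map.zone_mask[r_px, c_px] else "periportal_midzonal"
        obj.zone = zone
        assigned[zone].append(obj)

    summary = ZonalSummary()
    for zone, zmask in zone_masks.items():
        area_um2 = zmask.sum() * mpp**2
        objs = assigned[zone]
        if area_um2 == 0:
            warnings.warn(f"zone {zone!r} has no tissue area", stacklevel=2)
            summary.zones[zone] = ZoneStats(float("nan"), len(objs),
                                            sum(o.crowned for o in objs), float("nan"))
            continue
        lipid_area = sum(o.area_um2 for o in objs)
        crowns = sum(o.crowned for o in objs)
        summary.zones[zone] = ZoneStats(
            lipid_area_fraction=lipid_area / area_um2,
            droplet_count=len(objs),
            lipogranuloma_count=crowns,
            lipogranuloma_density_per_mm2=crowns / (area_um2 / 1e6),
        )
    return summary
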