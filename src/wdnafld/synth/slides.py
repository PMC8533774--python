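"""Synthetic tissue slides: elliptical lipid droplets, macrophage crowns,
Kupffer cells and a half-plane lobular zone split, with object-level truth.

The scene is a single-plane 2-D image.  Tissue fills the frame except for a
background border; the left half of the tissue is the pericentral zone
(zone-marker positive), the right half periportal/midzonal.  Crowned
droplets receive a macrophage-positive annulus constructed with the same
distance rule later used by the crown classifier, so coverage of a planted
crown is 1 by construction (up to image clipping).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

_SUPPORTED_RESOLUTIONS = (0.44, 3.54, 7.07)


@dataclass(frozen=True)
class ObjectTruth:
    object_id: int
    center_um: tuple[float, float]  # (x, y) = (col, row) in micrometers
    radii_um: tuple[float, float]   # (a, b) semi-axes
    kind: str                       # droplet | macrophage | kupffer
    crowned: bool
    zone: str                       # pericentral | periportal_midzonal

    def __post_init__(self) -> None:
        if min(self.radii_um) <= 0:
            raise ValueError("radii must be positive")
        if self.crowned and self.kind != "droplet":
            raise ValueError("only droplets can be crowned")


@dataclass
class SlideSpec:
    shape: tuple[int, int] = (512, 512)
    um_per_px: float = 0.44
    n_droplets: int = 40
    diameter_um: tuple[float, float] = (5.0, 14.0)
    min_axis_ratio: float = 0.85      # b/a lower bound (1 = circles)
    fraction_crowned: float = 0.0
    fraction_overlapping: float = 0.0  # fraction of droplets in planted overlapping pairs
    crown_annulus_um: float = 3.0
    tissue_border_um: float = 10.0
    placement_margin_um: float = 25.0  # droplet clearance from the tissue boundary
    n_kupffer: int = 0
    kupffer_diameter_um: float = 4.0
    max_tries: int = 200

    def __post_init__(self) -> None:
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.diameter_um[0] < self.um_per_px:
            raise ValueError(
                f"droplet diameter {self.diameter_um[0]} um is below one pixel "
                f"({self.um_per_px} um)"
            )
        if not (0 <= self.fraction_crowned <= 1 and 0 <= self.fraction_overlapping <= 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SlideChannels:
    lipid: np.ndarray
    macrophage: np.ndarray
    zone_marker: np.ndarray
    tissue_mask: np.ndarray
    um_per_px: float


def _ellipse_mask(shape, center_rc, radii_px) -> np.ndarray:
    r0, c0 = center_rc
    b, a = radii_px  # b along rows, a along cols
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - r0) / b) ** 2 + ((cc - c0) / a) ** 2 <= 1.0


def _annulus(droplet: np.ndarray, width_px: float) -> np.ndarray:
    dist = ndi.distance_transform_edt(~droplet)
    return (dist > 0) & (dist <= width_px)


def simulate_histology_image(
    spec: SlideSpec, seed: int
) -> tuple[SlideChannels, list[ObjectTruth]]:
    """Render a synthetic slide and return its channels plus object truth."""
    rng = np.random.default_rng(seed)
    H, W = spec.shape
    mpp = spec.um_per_px
    border_px = int(round(spec.tissue_border_um / mpp))
    tissue = np.zeros((H, W), dtype=bool)
    tissue[border_px: H - border_px, border_px: W - border_px] = True

    lipid = np.zeros((H, W), dtype=np.float32)
    macrophage = np.zeros((H, W), dtype=np.float32)
    zone = np.zeros((H, W), dtype=np.float32)
    zone[:, : W // 2] = 1.0
    zone[~tissue] = 0.0

    clearance_px = (spec.tissue_border_um + spec.placement_margin_um) / mpp
    n_pairs = int(round(spec.fraction_overlapping * spec.n_droplets)) // 2
    n_anchor = spec.n_droplets - n_pairs

    placed: list[tuple[float, float, float]] = []  # (row, col, max radius px)

    def sample_radii() -> tuple[float, float]:
        d = rng.uniform(*spec.diameter_um)
        a = d / 2.0
        b = a * rng.uniform(spec.min_axis_ratio, 1.0)
        return a, b

    def try_place(a_px, b_px, near=None):
        r_big = max(a_px, b_px)
        lo_r = clearance_px + r_big
        for _ in range(spec.max_tries):
            if near is None:
                r0 = rng.uniform(lo_r, H - lo_r)
                c0 = rng.uniform(lo_r, W - lo_r)
            else:
                ang = rng.uniform(0, 2 * np.pi)
                d = 0.8 * (near[2] + r_big)
                r0 = near[0] + d * np.sin(ang)
                c0 = near[1] + d * np.cos(ang)
                if not (lo_r <= r0 <= H - lo_r and lo_r <= c0 <= W - lo_r):
                    continue
            gap = 2.0 + spec.crown_annulus_um / mpp
            ok = all(
                np.hypot(r0 - pr, c0 - pc) >= r_big + prad + 2 * gap
                for pr, pc, prad in placed
                if near is None or (pr, pc) != (near[0], near[1])
            )
            if near is not None:
                # overlap partner must still overlap its anchor
                ok = ok and np.hypot(r0 - near[0], c0 - near[1]) < near[2] + min(a_px, b_px)
            if ok:
                return r0, c0
        raise RuntimeError("could not place all droplets; reduce n_droplets or sizes")

    droplets: list[dict] = []
    for i in range(n_anchor):
        a, b = sample_radii()
        a_px, b_px = a / mpp, b / mpp
        r0, c0 = try_place(a_px, b_px)
        placed.append((r0, c0, max(a_px, b_px)))
        droplets.append({"rc": (r0, c0), "ab_px": (a_px, b_px), "ab_um": (a, b)})
        if i < n_pairs:
            a2, b2 = sample_radii()
            r2, c2 = try_place(a2 / mpp, b2 / mpp, near=placed[-1])
            placed.append((r2, c2, max(a2, b2) / mpp))
            droplets.append({"rc": (r2, c2), "ab_px": (a2 / mpp, b2 / mpp), "ab_um": (a2, b2)})

    n = len(droplets)
    n_crowned = int(round(spec.fraction_crowned * n))
    crowned_ids = set(rng.choice(n, size=n_crowned, replace=False)) if n_crowned else set()

    truth: list[ObjectTruth] = []
    annulus_px = spec.crown_annulus_um / mpp
    for i, d in enumerate(droplets):
        mask = _ellipse_mask((H, W), d["rc"], (d["ab_px"][1], d["ab_px"][0]))
        lipid[mask] = 1.0
        r0, c0 = d["rc"]
        crowned = i in crowned_ids
        if crowned:
            macrophage[_annulus(mask, annulus_px)] = 1.0
        truth.append(
            ObjectTruth(
                object_id=i + 1,
                center_um=(c0 * mpp, r0 * mpp),
                radii_um=d["ab_um"],
                kind="droplet",
                crowned=crowned,
                zone="pericentral" if c0 < W / 2 else "periportal_midzonal",
            )
        )

    # resident Kupffer cells: small free macrophage blobs
    kr = spec.kupffer_diameter_um / 2.0 / mpp
    for j in range(spec.n_kupffer):
        r0, c0 = try_place(kr, kr)
        placed.append((r0, c0, kr))
        mask = _ellipse_mask((H, W), (r0, c0), (kr, kr))
        macrophage[mask] = 1.0
        truth.append(
            ObjectTruth(
                object_id=len(droplets) + j + 1,
                center_um=(c0 * mpp, r0 * mpp),
                radii_um=(kr * mpp, kr * mpp),
                kind="kupffer",
                crowned=False,
                zone="pericentral" if c0 < W / 2 else "periportal_midzonal",
            )
        )

    channels = SlideChannels(lipid, macrophage, zone, tissue, mpp)
    return channels, truth
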