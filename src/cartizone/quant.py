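"""Zone-wise cartilage thickness from 2D segmentation geometry.

The femoral cartilage cross-section, segmented on a transverse suprapatellar
ultrasound image, is represented by two ordered boundary polylines in mm
coordinates: the deep cartilage-bone interface and the superficial
synovial-cartilage boundary.  The section is partitioned about the manually
identified intercondylar-notch point into lateral / intercondylar / medial
zones by vertical slabs in the image x-axis, and each zone's thickness is
the clipped cross-sectional area divided by the arc length of the
cartilage-bone interface inside the slab.

Coordinate conventions: x runs lateral -> medial, y runs downward (raster
convention), so the bone interface lies at greater y than the synovial
boundary.  All coordinates are mm; mask pixels have their centres at
(i + 0.5) * pixel_spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box
from skimage.measure import label

ZONES = ("lateral", "intercondylar", "medial")

_CONSERVATION_RTOL = 1e-9


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent segmentation geometry."""


@dataclass
class CartilageSegmentation:
    """Cartilage cross-section: two boundary polylines plus the notch point.

    Parameters
    ----------
    bone : (n, 2) array
        Cartilage-bone interface, ordered lateral to medial, mm.
    synovial : (m, 2) array
        Synovial-cartilage boundary, ordered lateral to medial, mm.
    notch : (2,) array-like
        Manually identified centre of the intercondylar notch, mm.
    pixel_spacing : float, optional
        mm per pixel for mask-derived inputs (metadata only).
    image_id : str
        Label used in per-image outputs.
    """

    bone: np.ndarray
    synovial: np.ndarray
    notch: np.ndarray
    pixel_spacing: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.bone = np.asarray(self.bone, dtype=float)
        self.synovial = np.asarray(self.synovial, dtype=float)
        self.notch = np.asarray(self.notch, dtype=float)
        for name, arr in (("bone", self.bone), ("synovial", self.synovial)):
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise GeometryError(f"{name} polyline needs >= 2 (x, y) points")
        poly = self.polygon()
        if not poly.is_valid or poly.area <= 0:
            raise GeometryError(
                "bone and synovial polylines do not close into a simple "
                "polygon with positive area"
            )
        lo, hi = self.extent()
        if not lo <= self.notch[0] <= hi:
            raise GeometryError(
                f"notch x={self.notch[0]:.3f} outside lateral-medial extent "
                f"[{lo:.3f}, {hi:.3f}]"
            )

    def polygon(self) -> Polygon:
        """Closed cartilage polygon: bone chain then reversed synovial chain."""
        ring = np.vstack([self.bone, self.synovial[::-1]])
        return Polygon(ring)

    def extent(self) -> tuple[float, float]:
        """Lateral-medial x-extent over both boundaries (cartilage width)."""
        xs = np.concatenate([self.bone[:, 0], self.synovial[:, 0]])
        return float(xs.min()), float(xs.max())


@dataclass
class ZonePartition:
    """Two abscissae splitting the section into lateral|intercondylar|medial."""

    lateral_bound: float
    medial_bound: float
    convention: str = "absolute_mm"
    half_width: float = 4.8
    fraction: float = 0.25
    truncated: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.lateral_bound > self.medial_bound:
            raise GeometryError("lateral bound must not exceed medial bound")


@dataclass
class ZoneMeasurement:
    zone: str
    area: float  # mm^2
    interface_length: float  # mm
    thickness: float  # mm = area / interface_length
    empty: bool = False


@dataclass
class SiteReading:
    """Triplicate (or k-fold) per-site measurement set with zone means."""

    site: str
    per_image: list[list[ZoneMeasurement]]
    mean_thickness: dict[str, float]

    @property
    def n_images(self) -> int:
        return len(self.per_image)


def partition_zones(
    seg: CartilageSegmentation,
    fraction: float = 0.25,
    half_width: float = 4.8,
    convention: str = "absolute_mm",
) -> ZonePartition:
    """Place the intercondylar zone about the notch abscissa.

    ``absolute_mm`` uses a fixed half-width (default 4.8 mm each side of the
    notch); ``fraction_of_extent`` makes the zone a fixed fraction (default
    25%) of the imaged cartilage width.  If the notch sits closer than the
    half-span to an edge the zone is truncated at the extent and flagged.
    """
    if convention not in ("absolute_mm", "fraction_of_extent"):
        raise ValueError(f"unknown zone convention {convention!r}")
    lo, hi = seg.extent()
    width = hi - lo
    hw = half_width if convention == "absolute_mm" else fraction * width / 2.0
    if hw < 0:
        raise ValueError("intercondylar half-width must be >= 0")
    if 2.0 * hw > width * (1.0 + 1e-12):
        raise GeometryError(
            f"intercondylar span {2 * hw:.3f} mm exceeds cartilage width "
            f"{width:.3f} mm"
        )
    notch_x = float(seg.notch[0])
    a, b = notch_x - hw, notch_x + hw
    part = ZonePartition(
        lateral_bound=max(a, lo),
        medial_bound=min(b, hi),
        convention=convention,
        half_width=hw,
        fraction=fraction,
    )
    if a < lo - 1e-12 or b > hi + 1e-12:
        part.truncated = True
        part.warnings.append(
            f"notch at x={notch_x:.3f} is closer than {hw:.3f} mm to an "
            "edge; intercondylar zone truncated at the cartilage extent"
        )
    if part.lateral_bound - lo < 1e-12:
        part.warnings.append("lateral zone is empty")
    if hi - part.medial_bound < 1e-12:
        part.warnings.append("medial zone is empty")
    return part


def _polyline_length_in_slab(pts: np.ndarray, a: float, b: float) -> float:
    """Arc length of the polyline portion with x in [a, b].

    Segments crossing a bound are split at the exact bound abscissa so that
    slab lengths add up to the total length to floating tolerance.
    """
    total = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        if x0 == x1:
            if a <= x0 <= b:
                total += abs(y1 - y0)
            continue
        # clip the segment parameter t in [0,1] to the slab in x
        t0, t1 = 0.0, 1.0
        dx = x1 - x0
        ta, tb = (a - x0) / dx, (b - x0) / dx
        tlo, thi = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, tlo), min(t1, thi)
        if t1 <= t0:
            continue
        seg_len = float(np.hypot(dx, y1 - y0))
        total += (t1 - t0) * seg_len
    return total


def measure_zones(
    seg: CartilageSegmentation, part: ZonePartition
) -> list[ZoneMeasurement]:
    """Measure area, interface length and thickness for the three zones.

    Zone area is the cartilage polygon clipped to the vertical slab between
    the zone bounds; interface length is the bone polyline's arc length in
    the same slab; thickness is their ratio.  Zone areas and lengths are
    asserted to sum to the totals to 1e-9 relative tolerance on every call.
    """
    poly = seg.polygon()
    lo, hi = seg.extent()
    ymin = min(seg.bone[:, 1].min(), seg.synovial[:, 1].min()) - 1.0
    ymax = max(seg.bone[:, 1].max(), seg.synovial[:, 1].max()) + 1.0
    bounds = [(lo, part.lateral_bound), (part.lateral_bound, part.medial_bound),
              (part.medial_bound, hi)]
    out: list[ZoneMeasurement] = []
    for zone, (a, b) in zip(ZONES, bounds):
        if b - a <= 0:
            out.append(ZoneMeasurement(zone, 0.0, 0.0, float("nan"), empty=True))
            continue
        area = poly.intersection(box(a, ymin, b, ymax)).area
        length = _polyline_length_in_slab(seg.bone, a, b)
        if length <= 0:
            if area > 0:
                raise GeometryError(
                    f"zone {zone!r} has positive area but zero cartilage-bone "
                    "interface length"
                )
            out.append(ZoneMeasurement(zone, 0.0, 0.0, float("nan"), empty=True))
            continue
        out.append(ZoneMeasurement(zone, area, length, area / length))

    tot_area = sum(m.area for m in out)
    tot_len = sum(m.interface_length for m in out)
    full_area = poly.area
    full_len = _polyline_length_in_slab(seg.bone, lo, hi)
    if not np.isclose(tot_area, full_area, rtol=_CONSERVATION_RTOL, atol=1e-12):
        raise GeometryError(
            f"zone areas ({tot_area!r}) do not conserve total area ({full_area!r})"
        )
    if not np.isclose(tot_len, full_len, rtol=_CONSERVATION_RTOL, atol=1e-12):
        raise GeometryError(
            f"zone interface lengths ({tot_len!r}) do not conserve total "
            f"bone arc length ({full_len!r})"
        )
    return out


def measure(
    seg: CartilageSegmentation,
    fraction: float = 0.25,
    half_width: float = 4.8,
    convention: str = "absolute_mm",
) -> list[ZoneMeasurement]:
    """Partition and measure in one step (the per-image workhorse)."""
    return measure_zones(
        seg, partition_zones(seg, fraction, half_width, convention)
    )


def site_reading(
    images: list[CartilageSegmentation],
    site: str = "",
    fraction: float = 0.25,
    half_width: float = 4.8,
    convention: str = "absolute_mm",
) -> SiteReading:
    """Average per-zone thickness over repeated images of one site.

    Each still image is measured independently; the site value per zone is
    the arithmetic mean of the per-image thicknesses (three images in the
    standard protocol).  Per-image values are retained for reliability
    analysis.
    """
    if not images:
        raise ValueError("site_reading needs at least one image")
    per_image = [measure(seg, fraction, half_width, convention) for seg in images]
    means = {
        zone: float(np.mean([ms[i].thickness for ms in per_image]))
        for i, zone in enumerate(ZONES)
    }
    return SiteReading(site=site, per_image=per_image, mean_thickness=means)


def boundaries_from_mask(
    mask: np.ndarray,
    pixel_spacing: float,
    notch_hint: tuple[float, float],
    image_id: str = "",
) -> CartilageSegmentation:
    """Trace bone and synovial boundary polylines from a binary mask.

    The largest foreground component is kept (ties are an error), interior
    holes are filled, and each occupied pixel column contributes its outer
    pixel edges: the synovial boundary at the top edge of the topmost pixel,
    the bone interface at the bottom edge of the bottommost pixel.  The
    polylines span the full outer width of the occupied columns, so a solid
    w x h pixel block yields boundaries w*spacing long and h*spacing apart.
    """
    mask = np.asarray(mask).astype(bool)
    if pixel_spacing <= 0:
        raise ValueError("pixel_spacing must be > 0")
    if not mask.any():
        raise GeometryError("mask has no foreground pixels")
    lab, n = label(mask, return_num=True, connectivity=2)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        order = np.sort(sizes)[::-1]
        if order[0] == order[1]:
            raise GeometryError(
                f"mask has {int((sizes == order[0]).sum())} equally sized "
                "largest components; cannot pick one unambiguously"
            )
        mask = lab == (int(np.argmax(sizes)) + 1)
    mask = ndimage.binary_fill_holes(mask)

    cols = np.flatnonzero(mask.any(axis=0))
    s = float(pixel_spacing)
    xs, ys_top, ys_bot = [], [], []
    for c in cols:
        rows = np.flatnonzero(mask[:, c])
        xs.append((c + 0.5) * s)
        ys_top.append(rows[0] * s)          # top edge of topmost pixel
        ys_bot.append((rows[-1] + 1) * s)   # bottom edge of bottommost pixel
    # extend to the outer column edges so lengths match the pixel footprint
    xs = [cols[0] * s] + xs + [(cols[-1] + 1) * s]
    ys_top = [ys_top[0]] + ys_top + [ys_top[-1]]
    ys_bot = [ys_bot[0]] + ys_bot + [ys_bot[-1]]

    synovial = np.column_stack([xs, ys_top])
    bone = np.column_stack([xs, ys_bot])
    return CartilageSegmentation(
        bone=bone,
        synovial=synovial,
        notch=np.asarray(notch_hint, dtype=float),
        pixel_spacing=s,
        image_id=image_id,
    )


def suggest_notch(seg: CartilageSegmentation) -> np.ndarray:
    """Suggest a notch location: deepest synovial point toward the bone.

    With y pointing downward the intercondylar notch is where the synovial
    boundary dips deepest (largest y).  This is a convenience only -- the
    notch used for measurement is always supplied explicitly, mirroring the
    manual identification step of the acquisition protocol.
    """
    i = int(np.argmax(seg.synovial[:, 1]))
    return seg.synovial[i].copy()
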