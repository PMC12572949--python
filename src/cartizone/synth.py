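"""Synthetic inputs with known ground truth.

Two generators stand in for data that cannot be shipped with the package:

* **Analytic cartilage phantoms** -- a bone baseline curve (flat or circular
  arc) offset by a thickness profile t(x) gives a cartilage band whose
  per-zone area / interface-length ratio is computed by quadrature from the
  continuous geometry, independently of the polygon-based measurement code.
* **Synthetic cohorts** -- triplicate thickness readings per subject and
  site under a two-way additive model: reading r of subject i at site s is
  ``group_mean(s) + b_i + e_ir`` with b ~ N(0, between_sd^2) shared across
  sites and e ~ N(0, within_sd^2) per reading.  This is the homoscedastic
  normal model under which ICC(3,1) and SEM are defined; the planned ICC is
  between_var / (between_var + within_var).

An exact-moments mode affinely rescales each generated group sample so its
sample mean and SD (ddof=1) equal the requested values exactly, which lets
summary-statistics and raw-data inference engines be cross-checked
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import quad
from shapely import contains_xy

from .quant import (
    ZONES,
    CartilageSegmentation,
    GeometryError,
    partition_zones,
)

# --------------------------------------------------------------------------
# thickness profiles


def constant_profile(t: float) -> Callable[[np.ndarray], np.ndarray]:
    def f(x):
        return np.full_like(np.asarray(x, dtype=float), float(t))

    f.breakpoints = ()  # type: ignore[attr-defined]
    f.constant = float(t)  # type: ignore[attr-defined]
    return f


def piecewise_profile(
    breaks: list[float], values: list[float]
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-constant t(x): values[i] on [breaks[i], breaks[i+1])."""
    if len(values) != len(breaks) - 1:
        raise ValueError("need len(values) == len(breaks) - 1")
    br = np.asarray(breaks, dtype=float)
    vals = np.asarray(values, dtype=float)

    def f(x):
        idx = np.clip(np.searchsorted(br, np.asarray(x, float), "right") - 1,
                      0, len(vals) - 1)
        return vals[idx]

    f.breakpoints = tuple(br[1:-1])  # type: ignore[attr-defined]
    return f


def _as_profile(profile) -> Callable[[np.ndarray], np.ndarray]:
    if callable(profile):
        return profile
    return constant_profile(float(profile))


# --------------------------------------------------------------------------
# phantoms


@dataclass
class PhantomSpec:
    """Analytic cartilage phantom definition.

    ``bone_radius`` selects the baseline: None for a flat bone line,
    positive R for a circular arc convex toward the probe (cartilage on the
    outer side, so the full-band area/length ratio is t*(1 + t/(2R)) for
    constant t), negative R for a concave arc (cartilage offset toward the
    arc centre; requires t < |R| everywhere).
    """

    profile: float | Callable[[np.ndarray], np.ndarray] = 3.0  # mm
    band_width: float = 38.4  # lateral-medial extent of the bone, mm
    notch_x: float = 19.2  # mm
    bone_radius: float | None = None  # mm; None = flat
    bone_depth: float = 15.0  # y of the bone apex, mm (y points down)
    pixel_spacing: float = 0.05  # mm per pixel
    rasterize: bool = False
    n_points: int = 2001

    def __post_init__(self) -> None:
        if self.band_width <= 0 or self.pixel_spacing <= 0:
            raise ValueError("band_width and pixel_spacing must be > 0")
        if not 0 <= self.notch_x <= self.band_width:
            raise ValueError("notch_x must lie inside the band extent")
        if self.bone_radius is not None:
            if abs(self.bone_radius) <= self.band_width / 2:
                raise ValueError("|bone_radius| must exceed band_width / 2")
            if not hasattr(_as_profile(self.profile), "constant"):
                raise ValueError(
                    "arc-bone phantoms support constant thickness profiles only"
                )
        t = _as_profile(self.profile)(np.linspace(0, self.band_width, 4097))
        if np.any(t <= 0):
            raise ValueError("thickness profile must be strictly positive")


@dataclass
class PhantomResult:
    segmentation: CartilageSegmentation
    ground_truth: dict[str, dict[str, float]]  # zone -> area/length/thickness
    mask: np.ndarray | None = None
    sidecar: dict | None = None


def _arc_points(spec: PhantomSpec, n: int):
    """Bone and synovial arcs; returns (bone, synovial, geometry dict)."""
    R = spec.bone_radius
    t = _as_profile(spec.profile).constant  # type: ignore[attr-defined]
    cx = spec.band_width / 2.0
    half = spec.band_width / 2.0
    if R > 0:
        cy = spec.bone_depth + R
        phi_max = float(np.arcsin(half / R))
        phi = np.linspace(-phi_max, phi_max, n)
        bone = np.column_stack([cx + R * np.sin(phi), cy - R * np.cos(phi)])
        syn = np.column_stack(
            [cx + (R + t) * np.sin(phi), cy - (R + t) * np.cos(phi)]
        )
        geom = dict(kind="convex", cx=cx, cy=cy, r_in=R, r_out=R + t,
                    phi_max=phi_max)
    else:
        Ra = -R
        if t >= Ra:
            raise GeometryError(
                "offset self-intersects: thickness "
                f"{t:.3f} mm >= curvature radius {Ra:.3f} mm over "
                f"x in [0.000, {spec.band_width:.3f}]"
            )
        cy = spec.bone_depth - Ra
        phi_max = float(np.arcsin(half / Ra))
        phi = np.linspace(-phi_max, phi_max, n)
        bone = np.column_stack([cx + Ra * np.sin(phi), cy + Ra * np.cos(phi)])
        syn = np.column_stack(
            [cx + (Ra - t) * np.sin(phi), cy + (Ra - t) * np.cos(phi)]
        )
        geom = dict(kind="concave", cx=cx, cy=cy, r_in=Ra - t, r_out=Ra,
                    phi_max=phi_max)
    return bone, syn, geom


def _flat_zone_truth(spec: PhantomSpec, a: float, b: float):
    prof = _as_profile(spec.profile)
    pts = [p for p in getattr(prof, "breakpoints", ()) if a < p < b]
    area, _ = quad(lambda x: float(prof(x)), a, b, points=pts or None, limit=200)
    return area, b - a


def _arc_zone_truth(geom: dict, a: float, b: float):
    """Quadrature area and bone arc length of an annular band in an x-slab.

    The band is {r in [r_in, r_out], phi in [-phi_max, phi_max]} in polar
    coordinates about the arc centre (phi measured from the apex direction),
    clipped to a <= x <= b where x = cx + r*sin(phi).  The bone interface is
    the circle of the bone radius.
    """
    cx = geom["cx"]
    r_in, r_out = geom["r_in"], geom["r_out"]
    phi_max = geom["phi_max"]
    r_bone = geom["r_out"] if geom["kind"] == "concave" else geom["r_in"]
    lo, hi = a - cx, b - cx

    def r_interval(phi):
        s = np.sin(phi)
        if abs(s) < 1e-15:
            return (r_in, r_out) if lo <= 0.0 <= hi else None
        r1, r2 = sorted((lo / s, hi / s))
        lo_r, hi_r = max(r_in, r1), min(r_out, r2)
        return (lo_r, hi_r) if hi_r > lo_r else None

    def integrand(phi):
        iv = r_interval(phi)
        if iv is None:
            return 0.0
        return 0.5 * (iv[1] ** 2 - iv[0] ** 2)

    area, _ = quad(integrand, -phi_max, phi_max, limit=400)

    def phi_of_x(xc):
        return float(np.arcsin(np.clip(xc / r_bone, -1.0, 1.0)))

    p_lo = np.clip(phi_of_x(lo), -phi_max, phi_max)
    p_hi = np.clip(phi_of_x(hi), -phi_max, phi_max)
    length = r_bone * max(p_hi - p_lo, 0.0)
    return area, length


def make_phantom(
    spec: PhantomSpec,
    fraction: float = 0.25,
    half_width: float = 4.8,
    convention: str = "absolute_mm",
) -> PhantomResult:
    """Build a phantom segmentation with quadrature ground-truth thickness.

    Ground truth per zone is the continuous-geometry area divided by the
    continuous bone arc length inside the same vertical slab used by the
    measurement code, so phantom tests compare like with like.
    """
    prof = _as_profile(spec.profile)
    n = spec.n_points
    if spec.bone_radius is None:
        breaks = [b for b in getattr(prof, "breakpoints", ())
                  if 0.0 < b < spec.band_width]
        x = np.unique(np.concatenate(
            [np.linspace(0.0, spec.band_width, n), np.asarray(breaks)]))
        bone = np.column_stack([x, np.full(len(x), spec.bone_depth)])
        # represent profile jumps exactly: a duplicate abscissa carrying the
        # left-limit value makes the synovial step a vertical segment
        sx, sy = list(x), list(spec.bone_depth - prof(x))
        for b in sorted(breaks, reverse=True):
            left_val = spec.bone_depth - float(prof(b - 1e-9))
            i = int(np.searchsorted(x, b))
            if abs(left_val - sy[i]) > 0:
                sx.insert(i, b)
                sy.insert(i, left_val)
        syn = np.column_stack([sx, sy])
        notch = (spec.notch_x, spec.bone_depth)
        geom = None
    else:
        bone, syn, geom = _arc_points(spec, n)
        # notch y on the bone circle at notch_x
        r_bone = geom["r_out"] if geom["kind"] == "concave" else geom["r_in"]
        dx = spec.notch_x - geom["cx"]
        dy = float(np.sqrt(r_bone**2 - dx**2))
        ny = geom["cy"] - dy if geom["kind"] == "convex" else geom["cy"] + dy
        notch = (spec.notch_x, ny)

    seg = CartilageSegmentation(
        bone=bone, synovial=syn, notch=np.asarray(notch),
        pixel_spacing=spec.pixel_spacing if spec.rasterize else None,
        image_id="phantom",
    )

    part = partition_zones(seg, fraction, half_width, convention)
    lo, hi = seg.extent()
    slabs = [(lo, part.lateral_bound),
             (part.lateral_bound, part.medial_bound),
             (part.medial_bound, hi)]
    truth: dict[str, dict[str, float]] = {}
    for zone, (a, b) in zip(ZONES, slabs):
        if b - a <= 0:
            truth[zone] = dict(area=0.0, interface_length=0.0,
                               thickness=float("nan"))
            continue
        if spec.bone_radius is None:
            area, length = _flat_zone_truth(spec, a, b)
        else:
            area, length = _arc_zone_truth(geom, a, b)
        truth[zone] = dict(
            area=area, interface_length=length,
            thickness=area / length if length > 0 else float("nan"),
        )

    mask = sidecar = None
    if spec.rasterize:
        mask = _rasterize(seg, spec.pixel_spacing)
        sidecar = {
            "pixel_spacing_mm": spec.pixel_spacing,
            "notch_xy_mm": [float(notch[0]), float(notch[1])],
            "ground_truth": truth,
        }
    return PhantomResult(segmentation=seg, ground_truth=truth,
                         mask=mask, sidecar=sidecar)


def _rasterize(seg: CartilageSegmentation, spacing: float) -> np.ndarray:
    """Binary mask with pixel (r, c) on iff its centre is inside the band."""
    poly = seg.polygon()
    xmax = max(seg.bone[:, 0].max(), seg.synovial[:, 0].max())
    ymax = max(seg.bone[:, 1].max(), seg.synovial[:, 1].max())
    w = int(np.ceil(xmax / spacing)) + 2
    h = int(np.ceil(ymax / spacing)) + 2
    cols = (np.arange(w) + 0.5) * spacing
    rows = (np.arange(h) + 0.5) * spacing
    X, Y = np.meshgrid(cols, rows)
    return contains_xy(poly, X, Y).astype(np.uint8)


# --------------------------------------------------------------------------
# cohorts

SITE_KEYS = (
    "right_lateral", "right_middle", "right_medial",
    "left_lateral", "left_middle", "left_medial",
)


@dataclass
class CohortSpec:
    """Synthetic cohort: subjects in (sex, age_group) cells, k readings/site.

    group_means maps (sex, age_group) to a per-site mean thickness in mm
    (site keys like "right_lateral"); n_per_group maps the same cells to
    subject counts.  between_subject_sd is the SD of the per-subject offset
    shared across sites; within_subject_sd is the per-reading error SD.
    """

    group_means: Mapping[tuple[str, str], Mapping[str, float]]
    n_per_group: Mapping[tuple[str, str], int]
    between_subject_sd: float = 0.30
    within_subject_sd: float = 0.055
    n_readings: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.n_readings < 2:
            raise ValueError("need at least 2 readings per site")
        if set(self.n_per_group) != set(self.group_means):
            raise ValueError("group_means and n_per_group keys must match")

    @property
    def planned_icc(self) -> float:
        b2 = self.between_subject_sd**2
        w2 = self.within_subject_sd**2
        return 1.0 if b2 + w2 == 0 else b2 / (b2 + w2)


def within_sd_from_sem_pct(sem_pct: float, grand_mean: float) -> float:
    """Reading-error SD implied by a target SEM% at a given grand mean."""
    return sem_pct / 100.0 * grand_mean


def make_cohort(spec: CohortSpec):
    """Generate the long-format cohort table (one row per reading).

    Columns: subject_id, sex, age_group, side, site, reading_index,
    thickness_mm.  Deterministic for a fixed spec and seed.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    rows = []
    sid = 0
    for (sex, age_group) in sorted(spec.group_means):
        means = spec.group_means[(sex, age_group)]
        n = spec.n_per_group[(sex, age_group)]
        for _ in range(n):
            sid += 1
            b_i = rng.normal(0.0, spec.between_subject_sd)
            for site_key in sorted(means):
                side, site = site_key.split("_", 1)
                e = rng.normal(0.0, spec.within_subject_sd, spec.n_readings)
                for r in range(spec.n_readings):
                    rows.append((
                        f"S{sid:04d}", sex, age_group, side, site, r + 1,
                        means[site_key] + b_i + e[r],
                    ))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "sex", "age_group", "side", "site",
                 "reading_index", "thickness_mm"],
    )


def readings_matrix(cohort, side: str, site: str) -> np.ndarray:
    """Subjects x readings matrix for one side/site (complete cases only)."""
    sub = cohort[(cohort["side"] == side) & (cohort["site"] == site)]
    wide = sub.pivot_table(index="subject_id", columns="reading_index",
                           values="thickness_mm")
    return wide.dropna().to_numpy()


def reliability_matrix(
    n: int,
    k: int,
    mean: float,
    between_sd: float,
    within_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Subjects x readings matrix under the two-way additive model.

    Same generative model as make_cohort, for a single site, without the
    long-table plumbing; the workhorse for reliability calibration studies.
    """
    b = rng.normal(0.0, between_sd, (n, 1))
    e = rng.normal(0.0, within_sd, (n, k))
    return mean + b + e


def exact_moment_sample(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Normal draw affinely rescaled to the exact sample mean and SD (ddof=1)."""
    if n < 2:
        raise ValueError("need n >= 2 for a defined sample SD")
    x = rng.normal(size=n)
    x = x - x.mean()
    s = x.std(ddof=1)
    if s == 0:  # pragma: no cover - measure-zero draw
        x = np.linspace(-1, 1, n)
        x -= x.mean()
        s = x.std(ddof=1)
    return mean + sd * x / s


def make_group_samples(
    summary: Mapping[str, tuple[int, float, float]],
    seed: int = 0,
    exact_moments: bool = True,
) -> dict[str, np.ndarray]:
    """Per-group samples from (n, mean, sd) summaries.

    With exact_moments=True every group's sample moments equal the request
    exactly, so statistics computed from the raw samples agree bit-for-bit
    with the summary-statistics engines.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for label in summary:
        n, mean, sd = summary[label]
        if exact_moments:
            out[label] = exact_moment_sample(mean, sd, n, rng)
        else:
            out[label] = rng.normal(mean, sd, n)
    return out
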