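"""Radiographic morphometry: profile-AUC optical density and keel geometry.

Implements the six per-image measurements used in longitudinal keel
studies:

* tibiotarsal radiographic optical density — area under the pixel
  intensity profile of a wide line drawn across the tibiotarsal
  mid-shaft (line length = bone width, profile width 100 px);
* keel radiographic optical density — same AUC proxy over a 25 px wide,
  10 mm long line dragged across the pila carinae;
* keel length — arc length of a cubic spline through the operator's
  points from pila carinae to keel tip;
* keel mid-depth and cranial depth — Euclidean lengths of the
  corresponding annotation lines;
* xlm — keel length divided by mid-depth, a geometry index whose
  expected value for an undamaged keel is around 5.

The wide-line profile follows ImageJ "plot profile" semantics: at each
1 px step along the drawn axis, intensities are sampled (bilinear) along
the perpendicular across the full width and averaged.  AUC is the
trapezoidal integral of that profile; positions are in mm when the
image carries pixel spacing, otherwise in px, and the unit is recorded
on the output record.

Note the tibiotarsal density deliberately scales with bone width — the
drawn line spans the bone, so wider bones integrate over a longer
profile.  A width-normalised variant (AUC / line length) is available
via ``width_normalized=True`` but is not the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

from .radiograph_io import KeypointAnnotation, Radiograph

log = logging.getLogger("keelmorph")

TIBIO_PROFILE_WIDTH_PX = 100.0
KEEL_PROFILE_WIDTH_PX = 25.0
KEEL_DENSITY_LENGTH_MM = 10.0
MIDPOINT_WARN_TOL_PX = 10.0


@dataclass
class IntensityProfile:
    """Width-averaged intensity sampled along a line region axis."""

    positions: np.ndarray  # strictly increasing, constant step
    values: np.ndarray
    step: float
    unit: str = "px"  # "px" or "mm"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size < 2 or self.positions.size != self.values.size:
            raise ValueError("profile needs >= 2 matched samples")
        d = np.diff(self.positions)
        if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-9, atol=1e-12)):
            raise ValueError("positions must increase with constant step")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")
        if not self.step > 0:
            raise ValueError("step must be positive")


@dataclass
class MorphometricRecord:
    """One bird x one timepoint's six radiographic measurements."""

    bird_id: str
    timepoint: str | None
    tibiotarsal_density: float | None = None
    keel_density: float | None = None
    keel_length_px: float | None = None
    keel_mid_depth_px: float | None = None
    keel_cranial_depth_px: float | None = None
    xlm: float | None = None
    background_level: float | None = None
    unit: str = "px"
    ossified_only: bool = False  # wk16 keels are not fully ossified


# ---------------------------------------------------------------------------
# Profiles

def _check_rect_bounds(img: Radiograph, corners: np.ndarray) -> None:
    nrow, ncol = img.shape
    sides = []
    if corners[:, 0].min() < 0:
        sides.append("left")
    if corners[:, 0].max() > ncol - 1:
        sides.append("right")
    if corners[:, 1].min() < 0:
        sides.append("top")
    if corners[:, 1].max() > nrow - 1:
        sides.append("bottom")
    if sides:
        raise ValueError(
            f"profile region exits image bounds on the {'/'.join(sides)} side"
        )


def profile_curve(
    image: Radiograph,
    start,
    end,
    width_px: float,
    step_px: float = 1.0,
    perp_step_px: float = 0.1,
) -> IntensityProfile:
    """Wide-line intensity profile along the segment start -> end.

    At each 1 px position on the axis, the value is the mean of
    bilinear samples taken along the perpendicular across ``width_px``
    (dense 0.1 px sample spacing, so the mean converges to the exact
    width average).  Positions are reported in mm when the image has
    pixel spacing, else in px.
    """
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    axis = p1 - p0
    length = float(np.hypot(*axis))
    if length == 0:
        raise ValueError("profile start and end coincide")
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    u = axis / length  # unit axis direction
    v = np.array([-u[1], u[0]])  # unit perpendicular

    n_pos = max(2, int(round(length / step_px)) + 1)
    t = np.linspace(0.0, length, n_pos)
    half_span = (width_px - 1) / 2.0
    offsets = np.arange(-half_span, half_span + perp_step_px / 2.0,
                        perp_step_px)
    n_off = offsets.size

    # sample grid: (n_pos, n_off, 2) in (x, y)
    pts = (p0[None, None, :]
           + t[:, None, None] * u[None, None, :]
           + offsets[None, :, None] * v[None, None, :])
    corners = np.array([
        p0 + offsets[0] * v, p0 + offsets[-1] * v,
        p1 + offsets[0] * v, p1 + offsets[-1] * v,
    ])
    _check_rect_bounds(image, corners)

    # map_coordinates wants (row, col) = (y, x)
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    sampled = map_coordinates(image.pixels, coords, order=1, mode="nearest")
    values = sampled.reshape(n_pos, n_off).mean(axis=1)

    step = t[1] - t[0]
    if image.mm_per_px is not None:
        return IntensityProfile(t * image.mm_per_px, values,
                                step * image.mm_per_px, unit="mm")
    return IntensityProfile(t, values, step, unit="px")


def profile_auc(profile: IntensityProfile) -> float:
    """Trapezoidal area under the intensity profile."""
    return float(np.trapezoid(profile.values, profile.positions))


def background_correct(
    raw_auc: float,
    image: Radiograph,
    ann: KeypointAnnotation,
    region_length: float,
) -> tuple[float, float | None]:
    """Subtract the background pedestal from a profile AUC.

    Uses the median intensity of the annotated off-bone rectangle times
    the profile's axis length, clamped at zero.  Returns
    ``(corrected_auc, background_median)``; with no background region the
    raw AUC passes through unchanged (logged).
    """
    if ann.background_region is None:
        log.warning("%s: no background region; density left uncorrected",
                    ann.image_id)
        return raw_auc, None
    x0, y0, x1, y1 = ann.background_region
    c0, c1 = sorted((int(round(x0)), int(round(x1))))
    r0, r1 = sorted((int(round(y0)), int(round(y1))))
    patch = image.pixels[r0:r1 + 1, c0:c1 + 1]
    if patch.size == 0:
        raise ValueError(f"{ann.image_id}: empty background region")
    level = float(np.median(patch))
    return max(0.0, raw_auc - level * region_length), level


# ---------------------------------------------------------------------------
# Densities

def tibiotarsal_density(
    image: Radiograph,
    ann: KeypointAnnotation,
    correct_background: bool = True,
    width_normalized: bool = False,
) -> tuple[float, float | None]:
    """AUC density across the tibiotarsal mid-shaft.

    The drawn line spans the bone width and the profile region is 100 px
    wide along the bone axis.  Returns ``(density, background_level)``.
    """
    if ann.tibiotarsal_line is None:
        raise ValueError(f"{ann.image_id}: tibiotarsal_line missing")
    p0, p1 = ann.tibiotarsal_line
    prof = profile_curve(image, p0, p1, width_px=TIBIO_PROFILE_WIDTH_PX)
    auc = profile_auc(prof)
    level = None
    span = prof.positions[-1] - prof.positions[0]
    if correct_background:
        auc, level = background_correct(auc, image, ann, span)
    if width_normalized:
        auc /= span
    return auc, level


def keel_density(
    image: Radiograph,
    ann: KeypointAnnotation,
    correct_background: bool = True,
    fallback_mm_per_px: float | None = None,
) -> tuple[float, float | None]:
    """AUC density over a 25 px x 10 mm region across the pila carinae."""
    if ann.keeldensity_anchor is None:
        raise ValueError(f"{ann.image_id}: keeldensity_anchor missing")
    spacing = image.mm_per_px if image.mm_per_px is not None else fallback_mm_per_px
    if spacing is None:
        raise ValueError(
            f"{ann.image_id}: cannot realize 10 mm keel-density line "
            "without pixel spacing"
        )
    if image.mm_per_px is None:
        image = Radiograph(image.pixels, mm_per_px=spacing,
                           bird_id=image.bird_id, timepoint=image.timepoint,
                           photometric_normalized=image.photometric_normalized)
    point = np.asarray(ann.keeldensity_anchor["point"], dtype=float)
    direction = np.asarray(ann.keeldensity_anchor["direction"], dtype=float)
    length_px = KEEL_DENSITY_LENGTH_MM / spacing
    end = point + direction * length_px
    prof = profile_curve(image, point, end, width_px=KEEL_PROFILE_WIDTH_PX)
    auc = profile_auc(prof)
    level = None
    if correct_background:
        auc, level = background_correct(
            auc, image, ann, prof.positions[-1] - prof.positions[0])
    return auc, level


# ---------------------------------------------------------------------------
# Geometry

def keel_spline_length(polyline) -> tuple[float, tuple[float, float]]:
    """Arc length and half-length midpoint of a natural cubic spline.

    The spline interpolates the clicked points, parameterised by
    cumulative chord length; arc length uses 1000-segment quadrature.
    """
    pts = np.asarray(polyline, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be >= 2 (x, y) points")
    if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
        raise ValueError("polyline has consecutive duplicate points")
    chord = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    if pts.shape[0] == 2:
        mid = (pts[0] + pts[1]) / 2.0
        return float(chord[-1]), (float(mid[0]), float(mid[1]))
    cs = CubicSpline(chord, pts, bc_type="natural")
    t = np.linspace(0.0, chord[-1], 1001)
    dense = cs(t)
    seg = np.hypot(*np.diff(dense, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(cum[-1])
    mid_t = float(np.interp(length / 2.0, cum, t))
    mid = tuple(cs(mid_t))
    return length, (float(mid[0]), float(mid[1]))


def _point_segment_distance(p, a, b) -> float:
    p, a, b = (np.asarray(v, dtype=float) for v in (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
    return float(np.hypot(*(a + t * ab - p)))


def keel_geometry(
    image: Radiograph,
    ann: KeypointAnnotation,
    midpoint_tol_px: float = MIDPOINT_WARN_TOL_PX,
) -> tuple[float, float, float, float]:
    """Keel length, mid-depth, cranial depth and their ratio xlm.

    Lengths are in px.  Warns when the annotated mid-depth line misses
    the computed spline midpoint by more than ``midpoint_tol_px``.
    """
    for name in ("keel_polyline", "middepth_line", "cranialdepth_line"):
        if getattr(ann, name) is None:
            raise ValueError(f"{ann.image_id}: {name} missing")
    length, midpoint = keel_spline_length(ann.keel_polyline)
    m0, m1 = ann.middepth_line
    mid_depth = float(np.hypot(m1[0] - m0[0], m1[1] - m0[1]))
    c0, c1 = ann.cranialdepth_line
    cranial_depth = float(np.hypot(c1[0] - c0[0], c1[1] - c0[1]))
    if mid_depth == 0:
        raise ValueError(f"{ann.image_id}: zero mid-depth line")
    miss = _point_segment_distance(midpoint, m0, m1)
    if miss > midpoint_tol_px:
        log.warning(
            "%s: mid-depth line is %.1f px from the spline midpoint "
            "(tolerance %.1f px)", ann.image_id, miss, midpoint_tol_px)
    return length, mid_depth, cranial_depth, length / mid_depth


# ---------------------------------------------------------------------------
# Full per-image measurement

def measure_image(
    image: Radiograph,
    ann: KeypointAnnotation,
    correct_background: bool = True,
    fallback_mm_per_px: float | None = None,
    width_normalized_tibio: bool = False,
) -> MorphometricRecord:
    """Compute all available measurements for one annotated radiograph."""
    rec = MorphometricRecord(
        bird_id=image.bird_id, timepoint=image.timepoint,
        unit="mm" if (image.mm_per_px or fallback_mm_per_px) else "px",
        ossified_only=image.timepoint == "wk16",
    )
    levels = []
    if ann.tibiotarsal_line is not None:
        rec.tibiotarsal_density, lvl = tibiotarsal_density(
            image, ann, correct_background, width_normalized_tibio)
        levels.append(lvl)
    if ann.keeldensity_anchor is not None:
        rec.keel_density, lvl = keel_density(
            image, ann, correct_background, fallback_mm_per_px)
        levels.append(lvl)
    if (ann.keel_polyline is not None and ann.middepth_line is not None
            and ann.cranialdepth_line is not None):
        (rec.keel_length_px, rec.keel_mid_depth_px,
         rec.keel_cranial_depth_px, rec.xlm) = keel_geometry(image, ann)
    lvls = [l for l in levels if l is not None]
    rec.background_level = float(np.mean(lvls)) if lvls else None
    return rec
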