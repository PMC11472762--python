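"""Reading radiographs and keypoint annotations.

Radiographs arrive as DICOM (the acquisition format) or PNG/TIFF (test
phantoms).  On load every image is canonicalised to a single photometric
convention — *denser tissue is brighter* — so that all downstream
density measurements share one polarity regardless of how the detector
encoded the image (MONOCHROME1 sources are inverted).

Coordinates are 0-based with ``x`` = column and ``y`` = row; continuous
positions refer to pixel centres.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger("keelmorph")

#: Recognised longitudinal timepoints: five live imaging ages (weeks),
#: whole-body post-mortem (PM) and dissected-bone post-mortem (PMD).
TIMEPOINTS = ("wk16", "wk29", "wk42", "wk55", "wk68", "PM", "PMD")

MIN_IMAGE_SIDE = 64


class AnnotationError(ValueError):
    """An annotation failed schema or bounds validation."""


@dataclass
class Radiograph:
    """A calibrated radiographic image.

    Attributes
    ----------
    pixels
        2-D float array, rows x columns, arbitrary intensity units.
    mm_per_px
        Physical pixel spacing, mm per pixel, or ``None`` when the source
        carried no calibration (the record is then usable in pixel units
        only).
    bird_id, timepoint
        Identity of the record; ``timepoint`` is one of :data:`TIMEPOINTS`
        or ``None`` for anonymous fixtures.
    photometric_normalized
        True once the image obeys the canonical "denser = brighter"
        polarity.  :func:`normalize_photometric` is idempotent, so the
        flag is safe to trust.
    """

    pixels: np.ndarray
    mm_per_px: float | None = None
    bird_id: str = ""
    timepoint: str | None = None
    photometric_normalized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D matrix")
        if min(self.pixels.shape) < MIN_IMAGE_SIDE:
            raise ValueError(
                f"image must be at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE}, "
                f"got {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be strictly positive")
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def contains_point(self, p: Sequence[float]) -> bool:
        x, y = float(p[0]), float(p[1])
        nrow, ncol = self.pixels.shape
        return 0.0 <= x <= ncol - 1 and 0.0 <= y <= nrow - 1


def normalize_photometric(img: Radiograph, invert: bool = False) -> Radiograph:
    """Canonicalise polarity so that higher value means greater attenuation.

    ``invert=True`` flips the intensity scale (``max - pixels``), used for
    MONOCHROME2-style sources where air is bright and bone dark.  Calling
    this twice with the same arguments equals calling it once: the flag on
    the record guards re-entry.
    """
    if img.photometric_normalized:
        return img
    px = img.pixels
    if invert:
        px = px.max() - px
    return Radiograph(
        pixels=px,
        mm_per_px=img.mm_per_px,
        bird_id=img.bird_id,
        timepoint=img.timepoint,
        photometric_normalized=True,
    )


@dataclass
class KeypointAnnotation:
    """Named keypoints standing in for the operator's on-screen drawings.

    All points are ``(x, y)`` pairs in image coordinates.  ``keel_polyline``
    runs from the pila carinae to the keel tip; ``keeldensity_anchor`` is a
    point on the keel edge plus a unit direction dragged across the pila
    carinae.
    """

    image_id: str
    tibiotarsal_line: tuple | None = None
    keel_polyline: tuple | None = None
    middepth_line: tuple | None = None
    cranialdepth_line: tuple | None = None
    keeldensity_anchor: dict | None = None
    background_region: tuple | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.keel_polyline is not None:
            pts = [tuple(map(float, p)) for p in self.keel_polyline]
            if len(pts) < 2:
                raise AnnotationError(
                    f"{self.image_id}: keel_polyline needs >= 2 points"
                )
            for a, b in zip(pts, pts[1:]):
                if a == b:
                    raise AnnotationError(
                        f"{self.image_id}: keel_polyline has consecutive "
                        f"duplicate point {a}"
                    )
            self.keel_polyline = tuple(pts)
        for name in ("tibiotarsal_line", "middepth_line", "cranialdepth_line"):
            seg = getattr(self, name)
            if seg is not None:
                seg = tuple(tuple(map(float, p)) for p in seg)
                if len(seg) != 2:
                    raise AnnotationError(
                        f"{self.image_id}: {name} must be a pair of points"
                    )
                setattr(self, name, seg)
        if self.keeldensity_anchor is not None:
            a = self.keeldensity_anchor
            if "point" not in a or "direction" not in a:
                raise AnnotationError(
                    f"{self.image_id}: keeldensity_anchor needs point and direction"
                )
            d = np.asarray(a["direction"], dtype=float)
            n = np.hypot(*d)
            if n == 0:
                raise AnnotationError(
                    f"{self.image_id}: keeldensity_anchor direction is zero"
                )
            self.keeldensity_anchor = {
                "point": tuple(map(float, a["point"])),
                "direction": (d[0] / n, d[1] / n),
            }

    def validate_bounds(self, img: Radiograph) -> None:
        """Raise :class:`AnnotationError` naming any out-of-bounds field."""
        def _check(name: str, pts) -> None:
            for p in pts:
                if not img.contains_point(p):
                    raise AnnotationError(
                        f"{self.image_id}: {name} point {tuple(p)} outside "
                        f"image of shape {img.shape}"
                    )

        for name in ("tibiotarsal_line", "keel_polyline", "middepth_line",
                     "cranialdepth_line"):
            val = getattr(self, name)
            if val is not None:
                _check(name, val)
        if self.keeldensity_anchor is not None:
            _check("keeldensity_anchor", [self.keeldensity_anchor["point"]])
        if self.background_region is not None:
            x0, y0, x1, y1 = map(float, self.background_region)
            _check("background_region", [(x0, y0), (x1, y1)])

    def to_dict(self) -> dict:
        d: dict = {"image_id": self.image_id}
        for name in ("tibiotarsal_line", "keel_polyline", "middepth_line",
                     "cranialdepth_line"):
            val = getattr(self, name)
            if val is not None:
                d[name] = [list(p) for p in val]
        if self.keeldensity_anchor is not None:
            d["keeldensity_anchor"] = {
                "point": list(self.keeldensity_anchor["point"]),
                "direction": list(self.keeldensity_anchor["direction"]),
            }
        if self.background_region is not None:
            d["background_region"] = list(self.background_region)
        return d


# ---------------------------------------------------------------------------
# Loading

def _load_dicom(path: Path) -> tuple[np.ndarray, float | None, bool]:
    import pydicom

    ds = pydicom.dcmread(path)
    px = ds.pixel_array.astype(float)
    spacing = None
    if getattr(ds, "PixelSpacing", None):
        spacing = float(ds.PixelSpacing[0])
    elif getattr(ds, "ImagerPixelSpacing", None):
        spacing = float(ds.ImagerPixelSpacing[0])
    # MONOCHROME1: smallest value displayed white => bone (attenuating)
    # is already bright after the standard display inversion, i.e. raw
    # values have air bright; invert to the canonical polarity.
    invert = getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1"
    return px, spacing, invert


def _load_plain_image(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:  # collapse RGB fixtures
        arr = arr.mean(axis=2)
    return arr


def load_radiograph(
    path: str | Path,
    fallback_mm_per_px: float | None = None,
    bird_id: str = "",
    timepoint: str | None = None,
) -> Radiograph:
    """Read a DICOM / PNG / TIFF radiograph into canonical form.

    Pixel spacing comes from DICOM metadata when present, else from
    ``fallback_mm_per_px``; with neither, the record is flagged
    px-units-only (``mm_per_px is None``) rather than an error.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such radiograph: {path}")
    suffix = path.suffix.lower()
    invert = False
    if suffix in (".dcm", ".dicom", ""):
        px, spacing, invert = _load_dicom(path)
    else:
        px, spacing = _load_plain_image(path), None
    if spacing is None:
        spacing = fallback_mm_per_px
        if spacing is None:
            log.warning("%s: no pixel spacing available; px-units-only", path.name)
    img = Radiograph(pixels=px, mm_per_px=spacing, bird_id=bird_id,
                     timepoint=timepoint)
    return normalize_photometric(img, invert=invert)


_SEGMENT_FIELDS = ("tibiotarsal_line", "middepth_line", "cranialdepth_line")


def load_annotations(
    path: str | Path,
    images: dict[str, Radiograph] | None = None,
) -> list[KeypointAnnotation]:
    """Read the sidecar annotation JSON (a list of per-image objects).

    When ``images`` is given, annotations are bounds-checked against their
    image and annotations referencing unknown images are skipped with a
    warning.
    """
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise AnnotationError(f"{path}: annotation file must be a JSON array")
    out: list[KeypointAnnotation] = []
    for obj in raw:
        if "image_id" not in obj:
            raise AnnotationError(f"{path}: annotation without image_id")
        ann = KeypointAnnotation(
            image_id=obj["image_id"],
            tibiotarsal_line=obj.get("tibiotarsal_line"),
            keel_polyline=obj.get("keel_polyline"),
            middepth_line=obj.get("middepth_line"),
            cranialdepth_line=obj.get("cranialdepth_line"),
            keeldensity_anchor=obj.get("keeldensity_anchor"),
            background_region=obj.get("background_region"),
        )
        if images is not None:
            if ann.image_id not in images:
                warnings.warn(
                    f"annotation for unknown image {ann.image_id!r} skipped"
                )
                log.warning("annotation for unknown image %r skipped", ann.image_id)
                continue
            ann.validate_bounds(images[ann.image_id])
        out.append(ann)
    return out


def save_annotations(anns: Sequence[KeypointAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([a.to_dict() for a in anns], fh, indent=1)
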