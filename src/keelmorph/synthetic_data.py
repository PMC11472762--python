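"""Synthetic inputs with known ground truth.

Two generators make every downstream stage testable without the study's
raw data:

* :func:`make_phantom` renders a radiograph phantom containing a
  tibiotarsal-like uniform band, a curved keel-like bone (a circular
  arc band, so its centreline arc length is known in closed form) and a
  uniform cranial block for the keel-density line, plus optional
  additive haze and Gaussian noise.  It returns the image, an exact
  keypoint annotation, and the analytic truth for every measurement.
  Attenuation is additive (no Beer–Lambert exponentiation) because the
  profile-AUC measurements are linear in intensity.

* :func:`simulate_flock` draws bird-level records from a latent
  multivariate-normal model: ordinal keel scores arise by thresholding
  damage liabilities, fracture counts from a log-linear Poisson
  right-censored at 4 (">= four"), longitudinal radiographic
  measurements from a persistent-plus-AR(1) process over the seven
  timepoints, and pelvic dimensions correlated ~0.65 with body weight.
  Default marginal frequencies follow the dissection scoring
  distribution observed in aviary-housed brown layers (deviation sizes
  0.25/0.29/0.46, fracture counts ~ Poisson(2) censored at 4, callus
  sizes 0.17/0.41/0.42); the deviation-fracture latent correlation is
  calibrated so their damage co-occurrence is 67%.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .keel_scoring import FRACTURE_CENSOR_POINT, KeelScore
from .radiograph_io import TIMEPOINTS, KeypointAnnotation, Radiograph

log = logging.getLogger("keelmorph")


# ===========================================================================
# Phantom radiographs

@dataclass
class ArcBone:
    """Curved bone: a band of constant half-width around a circular arc."""

    center: tuple[float, float]
    radius: float
    theta_deg: tuple[float, float]  # start, end angles (math convention)
    half_width: float
    level: float

    def arc_length(self) -> float:
        t0, t1 = np.deg2rad(self.theta_deg)
        return self.radius * abs(t1 - t0)

    def point_at(self, theta_deg: float) -> np.ndarray:
        t = np.deg2rad(theta_deg)
        return np.array([self.center[0] + self.radius * np.cos(t),
                         self.center[1] + self.radius * np.sin(t)])

    def radial_at(self, theta_deg: float) -> np.ndarray:
        t = np.deg2rad(theta_deg)
        return np.array([np.cos(t), np.sin(t)])


@dataclass
class PhantomSpec:
    """Geometry and attenuation of the default phantom.

    All coordinates in px; attenuation in arbitrary additive units.
    The default layout keeps every measurement region strictly inside a
    uniform attenuation area, so the analytic truths below are exact.
    """

    size: tuple[int, int] = (400, 400)  # rows, cols
    mm_per_px: float = 0.2
    tibio_x: tuple[float, float] = (300.0, 360.0)  # vertical band bounds
    tibio_level: float = 120.0
    keel_arc: ArcBone = field(default_factory=lambda: ArcBone(
        center=(140.0, 340.0), radius=220.0, theta_deg=(245.0, 290.0),
        half_width=12.0, level=80.0))
    cranial_block: tuple[float, float, float, float] = (40.0, 200.0, 100.0, 280.0)
    cranial_level: float = 60.0
    mid_depth_px: float | None = None  # default: arc length / 5
    cranial_depth_px: float = 30.0
    n_spline_points: int = 9
    haze: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tibio_level < 0 or self.cranial_level < 0 or self.keel_arc.level < 0:
            raise ValueError("attenuation levels must be >= 0")
        if self.mid_depth_px is None:
            self.mid_depth_px = self.keel_arc.arc_length() / 5.0


def _render(spec: PhantomSpec) -> np.ndarray:
    nrow, ncol = spec.size
    yy, xx = np.mgrid[0:nrow, 0:ncol].astype(float)
    img = np.zeros((nrow, ncol))

    x0, x1 = spec.tibio_x
    img += spec.tibio_level * ((xx >= x0) & (xx <= x1))

    bx0, by0, bx1, by1 = spec.cranial_block
    img += spec.cranial_level * ((xx >= bx0) & (xx <= bx1)
                                 & (yy >= by0) & (yy <= by1))

    arc = spec.keel_arc
    cx, cy = arc.center
    r = np.hypot(xx - cx, yy - cy)
    theta = np.rad2deg(np.arctan2(yy - cy, xx - cx)) % 360.0
    t0, t1 = (t % 360.0 for t in arc.theta_deg)
    in_angle = (theta >= min(t0, t1)) & (theta <= max(t0, t1))
    img += arc.level * (in_angle & (np.abs(r - arc.radius) <= arc.half_width))
    return img


def make_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[Radiograph, KeypointAnnotation, dict]:
    """Render a phantom and its exact annotation + analytic truth.

    Truth densities are in a.u. * mm (profile positions in mm); lengths
    in px.  Haze is a uniform pedestal that background correction must
    remove; Gaussian noise has zero mean.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    img = _render(spec)
    img = img + spec.haze
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    nrow, ncol = spec.size
    arc = spec.keel_arc
    t0, t1 = arc.theta_deg

    # tibiotarsal line: horizontal, fully inside the uniform band
    margin = 5.0
    tx0, tx1 = spec.tibio_x[0] + margin, spec.tibio_x[1] - margin
    tibio_line = ((tx0, 150.0), (tx1, 150.0))
    tibio_len_px = tx1 - tx0

    # keel-density line: 10 mm downwards inside the cranial block
    bx0, by0, bx1, by1 = spec.cranial_block
    anchor = ((bx0 + bx1) / 2.0, by0 + 10.0)
    density_len_px = 10.0 / spec.mm_per_px

    # keel spline points on the true arc
    thetas = np.linspace(t0, t1, spec.n_spline_points)
    polyline = tuple(tuple(arc.point_at(t)) for t in thetas)

    tm = (t0 + t1) / 2.0
    mid = arc.point_at(tm)
    rad = arc.radial_at(tm)
    d = spec.mid_depth_px
    middepth_line = (tuple(mid - rad * d / 2.0), tuple(mid + rad * d / 2.0))
    tc = t0 + 3.0 * np.sign(t1 - t0)
    cpt = arc.point_at(tc)
    crad = arc.radial_at(tc)
    dc = spec.cranial_depth_px
    cranial_line = (tuple(cpt - crad * dc / 2.0), tuple(cpt + crad * dc / 2.0))

    ann = KeypointAnnotation(
        image_id=f"phantom-{spec.seed}",
        tibiotarsal_line=tibio_line,
        keel_polyline=polyline,
        middepth_line=middepth_line,
        cranialdepth_line=cranial_line,
        keeldensity_anchor={"point": anchor, "direction": (0.0, 1.0)},
        background_region=(5.0, 5.0, 35.0, 35.0),
    )
    img_r = Radiograph(pixels=img, mm_per_px=spec.mm_per_px,
                       bird_id=f"phantom-{spec.seed}",
                       photometric_normalized=True)
    ann.validate_bounds(img_r)

    arc_len = arc.arc_length()
    truth = {
        "tibio_auc": spec.tibio_level * tibio_len_px * spec.mm_per_px,
        "keel_auc": spec.cranial_level * 10.0,  # 10 mm line
        "keel_length_px": arc_len,
        "mid_depth_px": float(d),
        "cranial_depth_px": float(dc),
        "xlm": arc_len / d,
        "haze": spec.haze,
        "tibio_line_px": tibio_len_px,
        "density_line_px": density_len_px,
    }
    return img_r, ann, truth


def write_phantom_dicom(
    image: Radiograph,
    path,
    invert_polarity: bool = False,
) -> None:
    """Write a phantom as a minimal 16-bit DICOM (Secondary Capture).

    Pixel values are rounded to uint16.  With ``invert_polarity`` the
    stored array is max - pixels and the photometric interpretation is
    MONOCHROME1, exercising the loader's polarity canonicalisation.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    px = np.round(image.pixels).astype(np.int64)
    if px.max() > 65535:
        raise ValueError("pixel values exceed uint16 range")
    # negative noise excursions clamp at the detector floor
    arr = np.clip(px, 0, 65535).astype(np.uint16)
    photometric = "MONOCHROME2"
    if invert_polarity:
        arr = (arr.max() - arr).astype(np.uint16)
        photometric = "MONOCHROME1"

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = image.bird_id or "phantom"
    ds.Rows, ds.Columns = arr.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = photometric
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if image.mm_per_px is not None:
        ds.PixelSpacing = [image.mm_per_px, image.mm_per_px]
    ds.PixelData = arr.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# ===========================================================================
# Flock simulation

#: order of the latent variables in the correlation matrix
LATENT_VARS = ("keel_density", "tibio_density", "xlm", "body_weight",
               "pelvic_width", "pelvic_depth", "dev_liab", "frac_liab",
               "callus_liab", "keel_len")

#: cumulative category probabilities (Table-2-like marginals)
DEV_SIZE_CUM = (0.25, 0.54)            # sizes 0/1/2 -> 0.25/0.29/0.46
DEV_EXTENT_CUM = (0.25, 0.55, 0.82)    # extents 0..3
CALLUS_SIZE_CUM = (0.17, 0.58)         # sizes 0/1/2 -> 0.17/0.41/0.42
#: conditional extent distribution given damage present
FRAC_EXTENT_GIVEN = (0.837, 0.105, 0.058)
CALLUS_EXTENT_GIVEN = (0.847, 0.118, 0.035)
#: localization codes per extent (uniform choice within)
_CODES_BY_EXTENT = {1: (1, 2, 3), 2: (4, 5, 6), 3: (7,)}

#: per-timepoint means for the longitudinal measurements
MEASUREMENT_MEANS = {
    "tibio_density": (800.0, 900.0, 950.0, 1000.0, 1010.0, 950.0, 900.0),
    "keel_density": (400.0, 450.0, 500.0, 500.0, 490.0, 480.0, 470.0),
    "xlm": (4.0, 5.0, 5.1, 5.15, 5.2, 5.2, 5.1),
}
MEASUREMENT_SCALES = {"tibio_density": 80.0, "keel_density": 40.0, "xlm": 0.5}
BODYWEIGHT_MEANS = (1400.0, 1750.0, 1850.0, 1900.0, 1950.0, 1950.0, 1950.0)
BODYWEIGHT_SD = 150.0


def default_latent_correlation() -> pd.DataFrame:
    """Default latent correlation matrix (symmetric positive definite).

    Pelvic dimensions correlate 0.65 with body weight; keel geometry
    (xlm) correlates ~0.3 with the damage liabilities; optical densities
    correlate weakly negatively with damage; callus tracks fracture
    liability closely.  The deviation-fracture entry is calibrated at
    simulation time (see :func:`calibrate_dev_frac_corr`).
    """
    C = pd.DataFrame(np.eye(len(LATENT_VARS)), index=LATENT_VARS,
                     columns=LATENT_VARS)

    def s(a, b, v):
        C.loc[a, b] = C.loc[b, a] = v

    s("keel_density", "tibio_density", 0.30)
    s("keel_density", "body_weight", 0.10)
    s("keel_density", "dev_liab", -0.15)
    s("keel_density", "frac_liab", -0.20)
    s("keel_density", "callus_liab", -0.15)
    s("tibio_density", "body_weight", 0.20)
    s("tibio_density", "dev_liab", -0.20)
    s("tibio_density", "frac_liab", -0.20)
    s("tibio_density", "callus_liab", -0.15)
    s("xlm", "dev_liab", 0.30)
    s("xlm", "frac_liab", 0.30)
    s("xlm", "callus_liab", 0.20)
    s("xlm", "keel_len", 0.50)
    s("body_weight", "pelvic_width", 0.65)
    s("body_weight", "pelvic_depth", 0.65)
    s("pelvic_width", "pelvic_depth", 0.45)
    s("pelvic_width", "dev_liab", 0.15)
    s("pelvic_depth", "dev_liab", 0.10)
    s("dev_liab", "frac_liab", 0.40)  # placeholder; calibrated below
    s("dev_liab", "callus_liab", 0.55)
    s("frac_liab", "callus_liab", 0.85)
    s("keel_len", "dev_liab", 0.20)
    s("keel_len", "frac_liab", 0.10)
    return C


def calibrate_frac_log_rate(b: float, target_zero: float) -> float:
    """Intercept a of log lambda = a + b*Z_frac matching P(count = 0).

    With liability mixing (b > 0) the zero-count probability is
    E[exp(-exp(a + b Z))]; a is solved so it equals the target marginal
    (0.135 under a plain Poisson with mean 2).
    """
    def p0(a):
        val, _ = integrate.quad(
            lambda z: stats.norm.pdf(z) * np.exp(-np.exp(a + b * z)),
            -8, 8, limit=200)
        return val

    return float(optimize.brentq(lambda a: p0(a) - target_zero, -3.0, 3.0,
                                 xtol=1e-8))


def calibrate_dev_frac_corr(
    a: float, b: float, tau_dev: float, target_cofreq: float,
) -> float:
    """Latent corr(dev, frac) giving the target damage co-occurrence.

    Fracture counts are Poisson with log lambda = a + b*Z_frac; the
    probability that a bird has both a deviation (Z_dev > tau_dev) and
    at least one fracture is a 1-D integral over Z_frac, solved for the
    correlation by bisection.
    """
    def cofreq(r):
        def f(z):
            lam = np.exp(a + b * z)
            p_frac = 1.0 - np.exp(-lam)
            p_dev = stats.norm.sf((tau_dev - r * z) / np.sqrt(1 - r * r))
            return stats.norm.pdf(z) * p_frac * p_dev
        val, _ = integrate.quad(f, -8, 8, limit=200)
        return val

    lo, hi = cofreq(0.0), cofreq(0.95)
    if not lo <= target_cofreq <= hi:
        raise ValueError(
            f"target co-frequency {target_cofreq} outside attainable "
            f"range [{lo:.3f}, {hi:.3f}]")
    return float(optimize.brentq(lambda r: cofreq(r) - target_cofreq,
                                 0.0, 0.95, xtol=1e-6))


@dataclass
class FlockSimParams:
    """Study-design parameters of the simulated flock.

    Defaults emulate the study conditions: 155 analysed birds, two
    scoring operators, fracture rate lambda = 2 right-censored at
    ">= four", pelvic means 40.43 mm (width) and 71.92 mm (depth) with
    the observed SDs, and a persistent-plus-AR(1) longitudinal process
    (adjacent-age correlation = persistent_weight +
    (1 - persistent_weight) * ar_persistence, about 0.8 by default).
    """

    n_birds: int = 155
    seed: int = 0
    latent_corr: pd.DataFrame = field(default_factory=default_latent_correlation)
    frac_log_rate: float | None = None  # None: calibrated to target_frac_zero
    frac_liab_coef: float = 0.35
    censor_point: int = FRACTURE_CENSOR_POINT
    target_frac_zero: float = 0.135  # P(no fractures), Poisson(2) value
    target_dev_frac_cofreq: float | None = 0.67
    persistent_weight: float = 0.6
    ar_persistence: float = 0.5
    pelvic_width_mean: float = 40.43
    pelvic_width_sd: float = 5.30
    pelvic_depth_mean: float = 71.92
    pelvic_depth_sd: float = 10.38
    keel_len_cm_mean: float = 10.0
    keel_len_cm_sd: float = 0.8
    xlm_dissect_log_sd: float = 0.12
    operator_p: float = 0.5
    laying_p: float = 0.95

    def __post_init__(self) -> None:
        C = self.latent_corr
        if list(C.index) != list(LATENT_VARS):
            raise ValueError(f"latent_corr must be over {LATENT_VARS}")
        if not np.allclose(C.values, C.values.T):
            raise ValueError("latent correlation matrix must be symmetric")
        if not 0.0 <= self.ar_persistence < 1.0:
            raise ValueError("ar_persistence must be in [0, 1)")
        if not 0.0 <= self.persistent_weight <= 1.0:
            raise ValueError("persistent_weight must be in [0, 1]")
        if self.frac_log_rate is None:
            self.frac_log_rate = calibrate_frac_log_rate(
                self.frac_liab_coef, self.target_frac_zero)
        if self.target_dev_frac_cofreq is not None:
            tau_dev = stats.norm.ppf(DEV_SIZE_CUM[0])
            r = calibrate_dev_frac_corr(
                self.frac_log_rate, self.frac_liab_coef, tau_dev,
                self.target_dev_frac_cofreq)
            C = C.copy()
            C.loc["dev_liab", "frac_liab"] = C.loc["frac_liab", "dev_liab"] = r
            self.latent_corr = C
        eig = np.linalg.eigvalsh(self.latent_corr.values)
        if eig.min() <= 1e-10:
            raise ValueError(
                f"latent correlation matrix not positive definite "
                f"(min eigenvalue {eig.min():.2e})")


def _ordinal_from_latent(z: np.ndarray, cum_probs) -> np.ndarray:
    """Threshold standard-normal draws into ordinal categories."""
    thresholds = stats.norm.ppf(np.asarray(cum_probs))
    return np.digitize(z, thresholds)


def _loc_codes(extent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform localization code among those matching each extent."""
    out = np.zeros(extent.size, dtype=int)
    for e, codes in _CODES_BY_EXTENT.items():
        mask = extent == e
        if mask.any():
            out[mask] = rng.choice(codes, size=int(mask.sum()))
    return out


def simulate_flock(params: FlockSimParams | None = None) -> pd.DataFrame:
    """Draw one simulated flock as a wide, SM1-like DataFrame.

    One row per bird.  Columns: identity (``bird_id``, ``operator``,
    ``laying_status``), longitudinal measurements
    ``{tibio_density,keel_density,xlm,bodyweight}_{wk16..PMD}``,
    post-mortem pelvic dimensions, and the dissected keel score
    variables (sizes, counts with censor flag, localizations, derived
    extents, keel length/mid-depth in cm).
    """
    p = params or FlockSimParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_birds
    C = p.latent_corr.values
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n, len(LATENT_VARS))) @ L.T
    lat = {v: Z[:, i] for i, v in enumerate(LATENT_VARS)}

    df = pd.DataFrame({
        "bird_id": [f"B{i:04d}" for i in range(n)],
        "operator": np.where(rng.random(n) < p.operator_p, "op1", "op2"),
        "laying_status": rng.random(n) < p.laying_p,
    })

    # --- longitudinal measurements: persistent bird effect + AR(1) noise
    w = p.persistent_weight
    rho = p.ar_persistence
    for var, means in MEASUREMENT_MEANS.items():
        scale = MEASUREMENT_SCALES[var]
        persistent = lat[var]
        a = rng.standard_normal(n)  # AR(1) transient, stationary
        for t_idx, tp in enumerate(TIMEPOINTS):
            if t_idx > 0:
                a = rho * a + np.sqrt(1 - rho * rho) * rng.standard_normal(n)
            m = np.sqrt(w) * persistent + np.sqrt(1 - w) * a
            df[f"{var}_{tp}"] = means[t_idx] + scale * m
    for t_idx, tp in enumerate(TIMEPOINTS):
        df[f"bodyweight_{tp}"] = (BODYWEIGHT_MEANS[t_idx]
                                  + BODYWEIGHT_SD * lat["body_weight"])

    # --- pelvic dimensions (post-mortem, one per bird)
    df["pelvic_width"] = p.pelvic_width_mean + p.pelvic_width_sd * lat["pelvic_width"]
    df["pelvic_depth"] = p.pelvic_depth_mean + p.pelvic_depth_sd * lat["pelvic_depth"]
    df["pelvic_capacity"] = df["pelvic_width"] * df["pelvic_depth"]

    # --- dissected keel scores
    dev_size = _ordinal_from_latent(lat["dev_liab"], DEV_SIZE_CUM)
    dev_extent = _ordinal_from_latent(lat["dev_liab"], DEV_EXTENT_CUM)
    # shared first threshold guarantees extent>0 iff size>0
    df["deviation_size"] = dev_size
    df["deviation_extent"] = dev_extent
    df["deviation_loc"] = _loc_codes(dev_extent, rng)

    lam = np.exp(p.frac_log_rate + p.frac_liab_coef * lat["frac_liab"])
    counts = rng.poisson(lam)
    censored = counts >= p.censor_point
    counts = np.minimum(counts, p.censor_point)
    df["fracture_count"] = counts
    df["fracture_censored"] = censored
    frac_present = counts > 0
    frac_extent = np.zeros(n, dtype=int)
    frac_extent[frac_present] = rng.choice(
        [1, 2, 3], size=int(frac_present.sum()),
        p=np.asarray(FRAC_EXTENT_GIVEN) / np.sum(FRAC_EXTENT_GIVEN))
    df["fracture_extent"] = frac_extent
    df["fracture_loc"] = _loc_codes(frac_extent, rng)

    # Callus is healed fracture tissue: it occurs only on fractured keels
    # (the printed fracture-callus co-occurrence equals callus prevalence).
    # Conditional size categories are cut at empirical quantiles of the
    # callus liability among fractured birds, chosen so the marginal
    # matches CALLUS_SIZE_CUM.
    cal_size = np.zeros(n, dtype=int)
    if frac_present.any():
        p_frac0 = 1.0 - frac_present.mean()
        p_pos = frac_present.mean()
        q = np.clip((np.asarray(CALLUS_SIZE_CUM) - p_frac0) / p_pos, 0.0, 1.0)
        liab = lat["callus_liab"][frac_present]
        cuts = np.quantile(liab, q)
        cal_size[frac_present] = np.digitize(liab, cuts, right=True)
    cal_extent = np.zeros(n, dtype=int)
    cal_present = cal_size > 0
    cal_extent[cal_present] = rng.choice(
        [1, 2, 3], size=int(cal_present.sum()),
        p=np.asarray(CALLUS_EXTENT_GIVEN) / np.sum(CALLUS_EXTENT_GIVEN))
    df["callus_size"] = cal_size
    df["callus_extent"] = cal_extent
    df["callus_loc"] = _loc_codes(cal_extent, rng)

    # --- dissected keel geometry (cm); mid-depth = length / geometric index
    length_cm = p.keel_len_cm_mean + p.keel_len_cm_sd * lat["keel_len"]
    xlm_d = 5.0 * np.exp(p.xlm_dissect_log_sd * lat["xlm"])
    df["keel_length_cm"] = length_cm
    df["keel_mid_depth_cm"] = length_cm / xlm_d
    return df


def flock_to_scores(df: pd.DataFrame) -> list[KeelScore]:
    """Convert simulated (or ingested) rows to validated KeelScore objects."""
    out = []
    for _, r in df.iterrows():
        out.append(KeelScore(
            bird_id=str(r["bird_id"]),
            operator=str(r["operator"]),
            deviation_size=int(r["deviation_size"]),
            deviation_loc=int(r["deviation_loc"]),
            fracture_count=int(r["fracture_count"]),
            fracture_censored=bool(r.get("fracture_censored", False)),
            fracture_loc=int(r["fracture_loc"]),
            callus_size=int(r["callus_size"]),
            callus_loc=int(r["callus_loc"]),
            keel_length_cm=float(r["keel_length_cm"]),
            keel_mid_depth_cm=float(r["keel_mid_depth_cm"]),
            laying_status=bool(r["laying_status"]),
        ))
    return out


# ===========================================================================
# SM1-like sheet I/O

def write_sm1_like(
    records: pd.DataFrame,
    path,
    inject_missing: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Write the combined data sheet (XLSX or CSV by extension).

    With ``inject_missing`` > 0, that fraction of rows is deliberately
    broken (blanked bird ID or a missing measurement) to exercise the
    cleaning stage; the returned frame is what was written.
    """
    df = records.copy()
    if inject_missing > 0:
        rng = np.random.default_rng(seed)
        n_bad = int(round(inject_missing * len(df)))
        bad = rng.choice(len(df), size=n_bad, replace=False)
        for i in bad:
            if rng.random() < 0.5:
                df.iloc[i, df.columns.get_loc("bird_id")] = None
            else:
                numeric = [c for c in df.columns
                           if pd.api.types.is_float_dtype(df[c])]
                col = numeric[rng.integers(len(numeric))]
                df.iloc[i, df.columns.get_loc(col)] = np.nan
    path = str(path)
    if path.endswith(".csv"):
        df.to_csv(path, index=False)
    else:
        df.to_excel(path, index=False)
    return df


def read_sm1_like(path) -> pd.DataFrame:
    path = str(path)
    if path.endswith(".csv"):
        return pd.read_csv(path)
    return pd.read_excel(path)
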