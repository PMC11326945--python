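"""Circle fitting to membrane-channel rings.

Each peroxisome is seeded with an approximate center (from a clicked-centers
table or the synthetic-scene ground truth, jittered).  The fitter shoots
``n_rays`` radial rays from the seed, locates the membrane peak on each ray
with sub-pixel parabolic refinement, drops rays without signal above the local
background, excludes radial outliers (peaks deviating more than
``outlier_fraction`` from the mean distance to the center, 10% by default),
and fits an algebraic least-squares (Kåsa) circle to the surviving peak
points.  Very small organelles whose image shows no central intensity dip are
handled by a segmentation fallback: threshold, take the connected component at
the seed, and read center and radius off its centroid and major axis.

Coordinates are 0-based (row, col); pixel centers sit at integer coordinates
and sub-pixel positions are continuous.  A point at angle ``theta`` on a ring
is ``center + r * (cos(theta), sin(theta))`` in (row, col) order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from .errors import (
    BoundsError,
    DegenerateGeometryError,
    NoSignalError,
    ValidationError,
)

__all__ = [
    "ImagePlane",
    "FitConfig",
    "PolarPeakSet",
    "RingFitResult",
    "detect_peak_points",
    "exclude_outlier_peaks",
    "fit_circle_lsq",
    "segment_fallback",
    "fit_ring",
    "refine_ring_fits",
]


@dataclass(frozen=True)
class ImagePlane:
    """A single 2D grayscale channel with its physical pixel size.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities.
    pixel_size_nm
        Physical edge length of one pixel, in nanometres.
    channel_name
        Free-text channel label (e.g. ``"Pex3"``, ``"Atg30"``).
    resolution_class
        ``"sted"`` for the high-resolution membrane channel, ``"confocal"``
        for the companion channel.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel_name: str = ""
    resolution_class: str = "sted"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValidationError(f"pixels must be 2D, got shape {px.shape}")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel_size_nm must be positive")
        if self.resolution_class not in ("sted", "confocal"):
            raise ValidationError(
                f"resolution_class must be 'sted' or 'confocal', got {self.resolution_class!r}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class FitConfig:
    """Parameters of the ring fit.

    ``outlier_fraction`` is the relative radial deviation beyond which a peak
    is excluded (default 0.10, i.e. >10% deviation from the mean distance to
    the center).  ``dip_ratio`` quantifies "no clear intensity dip": if the
    interpolated intensity at the center reaches ``dip_ratio`` times the mean
    retained peak intensity, the ring is treated as a filled spot and the
    segmentation fallback is used.  ``max_center_shift_px`` bounds how far
    the fitted center may drift from the clicked seed (clicks land within a
    couple of pixels of the true center; a larger drift means the fit locked
    onto a neighbouring ring).  ``merge_zone_px`` is the boundary distance
    below which two membranes are considered optically merged, used by the
    contact-aware refinement pass.
    """

    n_rays: int = 360
    r_min_px: float = 2.0
    r_max_px: float = 20.0
    radial_step_px: float = 0.25
    outlier_fraction: float = 0.10
    refit_iterations: int = 2
    dip_ratio: float = 0.7
    fallback_threshold_mode: str = "otsu"
    min_retained_rays: int = 12
    debias_radius: bool = True
    max_center_shift_px: float = 5.0
    merge_zone_px: float = 3.0
    retention_k: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.r_min_px < self.r_max_px):
            raise ValidationError("need 0 < r_min_px < r_max_px")
        if not (0 < self.outlier_fraction < 1):
            raise ValidationError("outlier_fraction must be in (0, 1)")
        if not (0 < self.dip_ratio <= 1):
            raise ValidationError("dip_ratio must be in (0, 1]")
        if self.fallback_threshold_mode not in ("otsu", "fraction_of_max"):
            raise ValidationError(
                "fallback_threshold_mode must be 'otsu' or 'fraction_of_max'"
            )
        if self.n_rays < 3 or self.radial_step_px <= 0 or self.refit_iterations < 1:
            raise ValidationError("invalid ray/step/iteration settings")


@dataclass(frozen=True)
class PolarPeakSet:
    """Per-ray membrane peak positions around one seeded center."""

    center_used: tuple[float, float]
    angles: np.ndarray          # strictly increasing, in [0, 2pi)
    peak_radius_px: np.ndarray  # per-ray radius of the intensity peak
    peak_intensity: np.ndarray
    retained: np.ndarray        # bool mask

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.retained))

    def retained_points(self) -> np.ndarray:
        """(row, col) coordinates of retained peaks, shape (n_retained, 2)."""
        m = self.retained
        r = self.peak_radius_px[m]
        th = self.angles[m]
        cr, cc = self.center_used
        return np.column_stack([cr + r * np.cos(th), cc + r * np.sin(th)])


@dataclass(frozen=True)
class RingFitResult:
    """Fitted circle for one peroxisome.

    ``n_points`` is the number of retained peak points supporting the fit
    (zero for the segmentation fallback, which uses no rays).
    """

    center: tuple[float, float]
    radius_px: float
    radius_nm: float
    circumference_nm: float
    method: str                # "radial_peak" | "segmentation_fallback"
    n_points: int
    quality: str = "ok"        # "ok" | "low_support"

    def __post_init__(self) -> None:
        if self.radius_px <= 0 or self.radius_nm <= 0:
            raise ValidationError("fitted radius must be positive")


def _make_result(
    center: tuple[float, float],
    radius_px: float,
    pixel_size_nm: float,
    method: str,
    n_points: int,
    quality: str = "ok",
) -> RingFitResult:
    radius_nm = radius_px * pixel_size_nm
    return RingFitResult(
        center=(float(center[0]), float(center[1])),
        radius_px=float(radius_px),
        radius_nm=float(radius_nm),
        circumference_nm=2.0 * math.pi * radius_nm,
        method=method,
        n_points=int(n_points),
        quality=quality,
    )


def _bilinear(image: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        image, np.vstack([np.ravel(rows), np.ravel(cols)]), order=1, mode="constant"
    ).reshape(np.shape(rows))


def _annulus_background(
    image: np.ndarray, center: tuple[float, float], r_max_px: float
) -> tuple[float, float]:
    """Median and robust spread (1.4826*MAD) in the 1.2-1.5 r_max annulus."""
    cr, cc = center
    radii = np.arange(1.2 * r_max_px, 1.5 * r_max_px + 1e-9, 1.0)
    theta = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    rr = cr + np.outer(radii, np.cos(theta))
    cc_ = cc + np.outer(radii, np.sin(theta))
    inside = (
        (rr >= 0) & (rr <= image.shape[0] - 1) & (cc_ >= 0) & (cc_ <= image.shape[1] - 1)
    )
    if not inside.any():
        raise BoundsError("background annulus lies entirely outside the image")
    vals = _bilinear(image, rr[inside], cc_[inside])
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    return med, 1.4826 * mad


def detect_peak_points(
    image: ImagePlane, center: tuple[float, float], config: FitConfig
) -> PolarPeakSet:
    """Locate the membrane intensity peak on each radial ray from ``center``.

    The radial profile (bilinear interpolation, ``r_min_px`` to ``r_max_px``
    in steps of ``radial_step_px``) is scanned for its global maximum, which
    is refined to sub-step precision with a three-point parabola.  Rays whose
    peak does not rise above the local background (annulus median +
    ``retention_k`` robust spreads) are marked non-retained.

    Raises
    ------
    BoundsError
        If ``center`` is closer than ``r_max_px`` to the image border.
    NoSignalError
        If no ray retains a peak above background.
    """
    img = image.pixels
    cr, cc = float(center[0]), float(center[1])
    m = config.r_max_px
    if not (m <= cr <= img.shape[0] - 1 - m and m <= cc <= img.shape[1] - 1 - m):
        raise BoundsError(
            f"center ({cr:.1f}, {cc:.1f}) closer than r_max={m} px to the border"
        )

    theta = np.linspace(0.0, 2.0 * np.pi, config.n_rays, endpoint=False)
    radii = np.arange(config.r_min_px, config.r_max_px + 1e-9, config.radial_step_px)
    rows = cr + np.outer(np.cos(theta), radii)
    cols = cc + np.outer(np.sin(theta), radii)
    prof = _bilinear(img, rows, cols)  # (n_rays, n_radii)

    idx = np.argmax(prof, axis=1)
    peak_r = radii[idx].astype(float)
    peak_i = prof[np.arange(len(theta)), idx].astype(float)

    # parabolic sub-step refinement where the maximum is interior
    interior = (idx > 0) & (idx < len(radii) - 1)
    if interior.any():
        i = idx[interior]
        y0 = prof[interior, i - 1]
        y1 = prof[interior, i]
        y2 = prof[interior, i + 1]
        denom = y0 - 2 * y1 + y2
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(denom < 0, 0.5 * (y0 - y2) / denom, 0.0)
        delta = np.clip(delta, -0.5, 0.5)
        peak_r[interior] = radii[i] + delta * config.radial_step_px
        peak_i[interior] = y1 - 0.25 * (y0 - y2) * delta

    # each ray's peak is a maximum over ~(r_max - r_min)/step samples, so the
    # retention threshold must sit well above the background spread to keep
    # the family-wise false-retention rate low on signal-free rays
    med, spread = _annulus_background(img, (cr, cc), config.r_max_px)
    retained = peak_i > med + config.retention_k * spread
    if not retained.any():
        raise NoSignalError(
            f"no ray peak above background at seed ({cr:.1f}, {cc:.1f})"
        )
    return PolarPeakSet(
        center_used=(cr, cc),
        angles=theta,
        peak_radius_px=peak_r,
        peak_intensity=peak_i,
        retained=retained,
    )


def exclude_outlier_peaks(peaks: PolarPeakSet, outlier_fraction: float) -> PolarPeakSet:
    """Single-pass radial outlier exclusion.

    Computes the mean radius ``m`` of the currently retained peaks and
    un-retains every peak whose relative deviation ``|r - m| / m`` exceeds
    ``outlier_fraction``.  One pass only: the mean is not recomputed after
    exclusions.  Returns a new :class:`PolarPeakSet`; the input is unchanged.
    """
    if not (0 < outlier_fraction < 1):
        raise ValidationError("outlier_fraction must be in (0, 1)")
    if peaks.n_retained < 3:
        raise ValidationError("need at least 3 retained peaks")
    r = peaks.peak_radius_px
    m = float(np.mean(r[peaks.retained]))
    keep = peaks.retained & (np.abs(r - m) / m <= outlier_fraction)
    return replace(peaks, retained=keep)


def fit_circle_lsq(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Algebraic least-squares (Kåsa) circle through ``points``.

    Solves ``2*x*a + 2*y*b + c = x^2 + y^2`` in the least-squares sense; the
    center is ``(a, b)`` and the radius ``sqrt(c + a^2 + b^2)``.  Exact for
    points lying on a true circle.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or (numerically) collinear points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 (row, col) points")
    x, y = pts[:, 0], pts[:, 1]
    # shift to the centroid for conditioning
    mx, my = x.mean(), y.mean()
    u, v = x - mx, y - my
    A = np.column_stack([2 * u, 2 * v, np.ones_like(u)])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 3:
        raise DegenerateGeometryError("points are collinear; no unique circle")
    b = u * u + v * v
    (a, c, d), *_ = np.linalg.lstsq(A, b, rcond=None)
    r2 = d + a * a + c * c
    if r2 <= 0:
        raise DegenerateGeometryError("degenerate circle (non-positive radius)")
    return (float(a + mx), float(c + my)), float(np.sqrt(r2))


def segment_fallback(
    image: ImagePlane,
    center: tuple[float, float],
    config: FitConfig,
    window_half_px: float | None = None,
) -> RingFitResult:
    """Threshold-based fit for very small rings rendered as filled spots.

    A window of half-size ``1.5 * r_max_px`` around the seed (or
    ``window_half_px`` when a size hint is available) is thresholded (Otsu,
    or half of the window maximum), the connected component containing — or
    nearest to — the seed is selected, and the circle is read off the
    component: the intensity-weighted centroid is the center and half the
    major axis (from second central moments of the binary component) the
    radius.
    """
    img = image.pixels
    cr, cc = float(center[0]), float(center[1])
    half = int(math.ceil(window_half_px if window_half_px is not None
                         else 1.5 * config.r_max_px))
    r0, r1 = max(0, int(round(cr)) - half), min(img.shape[0], int(round(cr)) + half + 1)
    c0, c1 = max(0, int(round(cc)) - half), min(img.shape[1], int(round(cc)) + half + 1)
    win = img[r0:r1, c0:c1]
    if win.size == 0 or not np.any(win > 0):
        raise NoSignalError("empty window at seed; nothing to segment")

    if config.fallback_threshold_mode == "otsu":
        thr = filters.threshold_otsu(win)
    else:
        thr = 0.5 * float(win.max())
    mask = win > thr
    if not mask.any():
        raise NoSignalError("thresholding produced an empty segmentation")

    labels = measure.label(mask)
    seed_rc = (int(round(cr)) - r0, int(round(cc)) - c0)
    lab = 0
    if 0 <= seed_rc[0] < labels.shape[0] and 0 <= seed_rc[1] < labels.shape[1]:
        lab = int(labels[seed_rc])
    props = measure.regionprops(labels, intensity_image=win)
    if lab == 0:
        # nearest component to the seed (pixel-to-seed distance)
        best, bestd = None, np.inf
        for p in props:
            d = np.min(
                (p.coords[:, 0] - seed_rc[0]) ** 2 + (p.coords[:, 1] - seed_rc[1]) ** 2
            )
            if d < bestd:
                best, bestd = p, d
        prop = best
    else:
        prop = next(p for p in props if p.label == lab)
    assert prop is not None

    wr, wc = prop.centroid_weighted
    radius_px = 0.5 * prop.axis_major_length
    if radius_px <= 0:
        raise NoSignalError("segmented object has zero extent")
    return _make_result(
        center=(wr + r0, wc + c0),
        radius_px=radius_px,
        pixel_size_nm=image.pixel_size_nm,
        method="segmentation_fallback",
        n_points=0,
    )


def _crest_radius(r: float, sigma: float) -> float:
    """Crest position of a Gaussian-blurred infinitely thin ring of radius r.

    The blurred radial profile is ``exp(-(rho^2 + r^2)/(2 sigma^2)) *
    I0(rho r / sigma^2)``; its maximum satisfies ``rho / r = I1(x)/I0(x)``
    with ``x = rho r / sigma^2`` and lies inward of ``r`` (curvature bias,
    about ``sigma^2 / (2 r)`` for ``r >> sigma``).  Solved by fixed-point
    iteration.
    """
    from scipy.special import i0e, i1e

    rho = max(r, 1e-6)
    for _ in range(60):
        x = rho * r / (sigma * sigma)
        rho_new = r * (i1e(x) / i0e(x)) if x > 0 else 0.0
        if abs(rho_new - rho) < 1e-12:
            rho = rho_new
            break
        rho = rho_new
    return rho


def _profile_sigma(
    image: np.ndarray, center: tuple[float, float], radius_px: float, config: FitConfig
) -> float | None:
    """Gaussian-equivalent width of the mean radial profile around the crest.

    Measured as half-width at half maximum (above the profile minimum) of the
    angle-averaged radial profile, converted via FWHM = 2.355 sigma.  Returns
    ``None`` when the half-maximum is not bracketed inside the scan range.
    """
    radii = np.arange(config.r_min_px, config.r_max_px + 1e-9, config.radial_step_px)
    theta = np.linspace(0.0, 2.0 * np.pi, config.n_rays, endpoint=False)
    rows = center[0] + np.outer(np.cos(theta), radii)
    cols = center[1] + np.outer(np.sin(theta), radii)
    prof = _bilinear(image, rows, cols).mean(axis=0)
    i_pk = int(np.argmax(prof))
    base = float(prof.min())
    half = base + 0.5 * (prof[i_pk] - base)
    left = right = None
    for i in range(i_pk, 0, -1):
        if prof[i - 1] <= half:
            f = (prof[i] - half) / (prof[i] - prof[i - 1])
            left = radii[i] - f * config.radial_step_px
            break
    for i in range(i_pk, len(radii) - 1):
        if prof[i + 1] <= half:
            f = (prof[i] - half) / (prof[i] - prof[i + 1])
            right = radii[i] + f * config.radial_step_px
            break
    if left is None or right is None or right <= left:
        return None
    return (right - left) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _debias_radius(
    image: np.ndarray, center: tuple[float, float], radius_px: float, config: FitConfig
) -> float:
    """Invert the crest-shift relation to recover the true ring radius.

    The fitted radius is the crest of the PSF-blurred membrane, which sits
    inward of the true radius for curved rings.  Using the measured profile
    width as the blur scale, the relation ``crest(r) = rho_hat`` is solved
    for ``r``.  Falls back to the uncorrected radius when the width cannot
    be measured or the correction is negligible or unstable.
    """
    from scipy.optimize import brentq

    sigma = _profile_sigma(image, center, radius_px, config)
    if sigma is None or sigma <= 0.05 or radius_px <= sigma:
        return radius_px
    hi = radius_px + 4.0 * sigma
    try:
        f = lambda r: _crest_radius(r, sigma) - radius_px  # noqa: E731
        if f(hi) <= 0:
            return radius_px
        return float(brentq(f, radius_px, hi, xtol=1e-6))
    except ValueError:
        return radius_px


def fit_ring(
    image: ImagePlane, seed: tuple[float, float], config: FitConfig | None = None
) -> RingFitResult:
    """Full per-peroxisome ring fit.

    Peaks are detected from the seed; if the interpolated intensity at the
    center reaches ``dip_ratio`` times the mean retained peak intensity (no
    clear central dip — a very small, filled ring), the segmentation fallback
    is used.  Otherwise outlier peaks are excluded and a least-squares circle
    fitted, re-shooting the rays from the refined center ``refit_iterations``
    times.  Deterministic for fixed inputs.
    """
    config = config or FitConfig()
    peaks = detect_peak_points(image, seed, config)

    center_val = float(_bilinear(image.pixels, np.array(seed[0]), np.array(seed[1])))
    mean_peak = float(np.mean(peaks.peak_intensity[peaks.retained]))
    r_med = float(np.median(peaks.peak_radius_px[peaks.retained]))
    if center_val >= config.dip_ratio * mean_peak:
        return segment_fallback(image, seed, config, window_half_px=1.5 * r_med + 3.0)

    def narrowed(r_est: float) -> FitConfig:
        # robust scan-range initialization: in crowded fields a full-range
        # global maximum can lock onto a neighbouring ring's bright patch,
        # so refits scan only a band around the current radius estimate
        lo = max(config.r_min_px, 0.6 * r_est)
        hi = min(config.r_max_px, 1.6 * r_est + 2.0)
        if hi - lo < 4.0 * config.radial_step_px:
            return config
        return replace(config, r_min_px=lo, r_max_px=hi)

    def seed_anchored_fit() -> tuple[tuple[float, float], float, int]:
        # recovery path when the fit drifts onto a neighbouring ring: rays
        # are re-shot from the clicked seed and inliers selected against the
        # robust median radius, which tolerates heavy neighbour contamination
        pk = detect_peak_points(image, seed, narrowed(r_med))
        r = pk.peak_radius_px
        keep = pk.retained & (np.abs(r - r_med) / r_med <= 2.0 * config.outlier_fraction)
        if keep.sum() < 3:
            raise NoSignalError("seed-anchored recovery found too few inlier rays")
        pts = replace(pk, retained=keep).retained_points()
        c, rad = fit_circle_lsq(pts)
        return c, rad, int(keep.sum())

    center = peaks.center_used
    quality = "ok"
    n_points = 0
    radius_px = r_med
    for _it in range(config.refit_iterations):
        peaks = detect_peak_points(image, center, narrowed(radius_px))
        kept = exclude_outlier_peaks(peaks, config.outlier_fraction)
        n_points = kept.n_retained
        if n_points < 3:
            return segment_fallback(image, seed, config,
                                    window_half_px=1.5 * radius_px + 3.0)
        if n_points < config.min_retained_rays:
            quality = "low_support"
        center, radius_px = fit_circle_lsq(kept.retained_points())
        if math.hypot(center[0] - seed[0], center[1] - seed[1]) > config.max_center_shift_px:
            center, radius_px, n_points = seed_anchored_fit()
            if (math.hypot(center[0] - seed[0], center[1] - seed[1])
                    > config.max_center_shift_px):
                raise NoSignalError(
                    "fitted center keeps drifting away from the seeded position"
                )
    assert radius_px is not None
    if config.debias_radius:
        radius_px = _debias_radius(image.pixels, center, radius_px, config)
    return _make_result(
        center=center,
        radius_px=radius_px,
        pixel_size_nm=image.pixel_size_nm,
        method="radial_peak",
        n_points=n_points,
        quality=quality,
    )


def refine_ring_fits(
    image: ImagePlane,
    fits: list[RingFitResult],
    config: FitConfig | None = None,
    passes: int = 2,
) -> list[RingFitResult]:
    """Contact-aware joint refinement of all ring fits of one image.

    Where two organelles touch, their blurred membrane signals merge and the
    radial crest sits between the two true circles, biasing every single-ring
    fit slightly outward at the contact.  Knowing all fitted circles, rays
    whose crest point lies within ``merge_zone_px`` (boundary-to-boundary) of
    another fitted ring are excluded and the circle is re-fitted from the
    uncontaminated arc.  Rings fitted by the segmentation fallback and rings
    left with too few clean rays are returned unchanged.
    """
    config = config or FitConfig()
    for _ in range(passes):
        new_fits: list[RingFitResult] = []
        for i, fit in enumerate(fits):
            if fit.method != "radial_peak":
                new_fits.append(fit)
                continue
            lo = max(config.r_min_px, 0.6 * fit.radius_px)
            hi = min(config.r_max_px, 1.6 * fit.radius_px + 2.0)
            cfg = (replace(config, r_min_px=lo, r_max_px=hi)
                   if hi - lo >= 4.0 * config.radial_step_px else config)
            try:
                peaks = detect_peak_points(image, fit.center, cfg)
            except (BoundsError, NoSignalError):
                new_fits.append(fit)
                continue
            th = peaks.angles
            pr = fit.center[0] + fit.radius_px * np.cos(th)
            pc = fit.center[1] + fit.radius_px * np.sin(th)
            clean = np.ones(len(th), dtype=bool)
            for j, other in enumerate(fits):
                if j == i:
                    continue
                d = np.abs(np.hypot(pr - other.center[0], pc - other.center[1])
                           - other.radius_px)
                clean &= d > config.merge_zone_px
            keep = peaks.retained & clean
            if keep.sum() < max(3, config.min_retained_rays):
                new_fits.append(fit)
                continue
            try:
                kept = exclude_outlier_peaks(replace(peaks, retained=keep),
                                             config.outlier_fraction)
                if kept.n_retained < 3:
                    new_fits.append(fit)
                    continue
                center, radius = fit_circle_lsq(kept.retained_points())
            except (DegenerateGeometryError, ValidationError):
                new_fits.append(fit)
                continue
            if config.debias_radius:
                radius = _debias_radius(image.pixels, center, radius, config)
            new_fits.append(
                _make_result(center, radius, image.pixel_size_nm,
                             "radial_peak", kept.n_retained, fit.quality)
            )
        fits = new_fits
    return fits
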