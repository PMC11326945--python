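"""Ground-truthed synthetic two-channel nanoscopy scenes.

The generator emulates the statistical structure the downstream analysis
assumes: ring-shaped membrane labels with patchy (von Mises mixture) angular
intensity, a companion channel whose angular truth is coupled to the membrane
channel by a mixing weight ``coupling_alpha``, clusters of mutually tangent
rings, Gaussian PSF blur at two scales (STED vs confocal), a constant
background, and Poisson shot noise.  Every scene carries its full ground
truth — true circles, true angular emission profiles, and the expected
Between/Outside contact labels — so each pipeline stage can be verified
without real data.

Channel-truth model, per ring (K angles):

* channel 1 (membrane):  ``baseline + sum_j amp * vonMises(theta; mu_j, kappa)``
  with each von Mises bump normalized to unit peak;
* channel 2 (companion): ``alpha * t1/mean(t1) + (1-alpha) * t2/mean(t2)``
  where ``t2`` is an independent draw from the same patch model, optionally
  multiplied by ``outside_enrichment_beta`` over the ring's Outside arcs.

With ``coupling_alpha = 1`` the channel-2 truth is exactly proportional to
channel 1; with ``coupling_alpha = 0`` the two are independent.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import BoundsError, PlacementError, ValidationError
from .ring_fitting import ImagePlane

__all__ = [
    "SceneConfig",
    "TrueRing",
    "SceneGroundTruth",
    "generate_scene",
    "render_scene",
    "expected_labels",
    "K_ANGLES",
]

K_ANGLES = 360
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...
_CONTACT_GAP_NM = 30.0  # boundary gap defining Outside arcs for planted enrichment


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe the imaging regime the pipeline targets: 20 nm pixels,
    60 nm STED and 250 nm confocal FWHM, rings of 120–300 nm radius (typical
    yeast peroxisomes), 2–5 membrane patches of ~3x baseline amplitude with
    von Mises concentration 3 (angular width of roughly 35 degrees).
    """

    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 20.0
    n_cells: int = 6
    rings_per_cell_range: tuple[int, int] = (1, 4)
    radius_range_nm: tuple[float, float] = (120.0, 300.0)
    cluster_probability: float = 0.6
    patch_count_range: tuple[int, int] = (2, 5)
    patch_concentration: float = 3.0
    patch_amplitude: float = 3.0
    coupling_alpha: float = 0.7
    outside_enrichment_beta: float = 1.0
    psf_fwhm_sted_nm: float = 60.0
    psf_fwhm_conf_nm: float = 250.0
    background_level: float = 2.0
    photon_budget: float = 300.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        def ordered(pair):
            return pair[0] <= pair[1]

        if not (
            ordered(self.rings_per_cell_range)
            and ordered(self.radius_range_nm)
            and ordered(self.patch_count_range)
        ):
            raise ValidationError("range fields must satisfy min <= max")
        if self.radius_range_nm[0] < 2.0 * self.pixel_size_nm:
            raise ValidationError("minimum radius must be >= 2 pixels")
        if self.psf_fwhm_conf_nm <= self.psf_fwhm_sted_nm:
            raise ValidationError("confocal FWHM must exceed STED FWHM")
        if not (0.0 <= self.cluster_probability <= 1.0):
            raise ValidationError("cluster_probability must be in [0, 1]")
        if not (0.0 <= self.coupling_alpha <= 1.0):
            raise ValidationError("coupling_alpha must be in [0, 1]")
        if self.outside_enrichment_beta <= 0:
            raise ValidationError("outside_enrichment_beta must be positive")
        if min(self.pixel_size_nm, self.patch_concentration, self.patch_amplitude,
               self.photon_budget) <= 0 or self.background_level < 0:
            raise ValidationError("scale parameters out of range")
        if self.n_cells < 1 or self.rings_per_cell_range[0] < 1:
            raise ValidationError("need at least one cell and one ring per cell")


@dataclass(frozen=True)
class TrueRing:
    cell_id: int
    center_px: tuple[float, float]  # (row, col)
    radius_nm: float


@dataclass
class SceneGroundTruth:
    """True geometry and emission of a generated scene.

    ``angular_truth_ch1`` / ``angular_truth_ch2`` have shape (n_rings, K);
    ``labels_between`` is boolean of the same shape (True = Between, i.e. the
    boundary point lies within the contact gap of another ring).
    """

    rings: list[TrueRing]
    angular_truth_ch1: np.ndarray
    angular_truth_ch2: np.ndarray
    labels_between: np.ndarray
    params: SceneConfig

    @property
    def angles(self) -> np.ndarray:
        return np.linspace(0.0, 2.0 * math.pi, K_ANGLES, endpoint=False)

    def to_json(self) -> str:
        doc = {
            "params": asdict(self.params),
            "rings": [
                {
                    "cell_id": r.cell_id,
                    "center_row_px": r.center_px[0],
                    "center_col_px": r.center_px[1],
                    "radius_nm": r.radius_nm,
                }
                for r in self.rings
            ],
            "angular_truth_ch1": self.angular_truth_ch1.tolist(),
            "angular_truth_ch2": self.angular_truth_ch2.tolist(),
            "labels_between": self.labels_between.astype(int).tolist(),
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "SceneGroundTruth":
        doc = json.loads(text)
        p = doc["params"]
        for key in ("image_size_px", "rings_per_cell_range", "radius_range_nm",
                    "patch_count_range"):
            p[key] = tuple(p[key])
        params = SceneConfig(**p)
        rings = [
            TrueRing(r["cell_id"], (r["center_row_px"], r["center_col_px"]), r["radius_nm"])
            for r in doc["rings"]
        ]
        return cls(
            rings=rings,
            angular_truth_ch1=np.asarray(doc["angular_truth_ch1"], dtype=float),
            angular_truth_ch2=np.asarray(doc["angular_truth_ch2"], dtype=float),
            labels_between=np.asarray(doc["labels_between"], dtype=bool),
            params=params,
        )


def _patch_profile(rng: np.random.Generator, cfg: SceneConfig, theta: np.ndarray) -> np.ndarray:
    """Baseline-plus-patches angular emission, von Mises bumps at unit peak."""
    n = int(rng.integers(cfg.patch_count_range[0], cfg.patch_count_range[1] + 1))
    prof = np.ones_like(theta)
    for _ in range(n):
        mu = rng.uniform(0.0, 2.0 * math.pi)
        bump = np.exp(cfg.patch_concentration * (np.cos(theta - mu) - 1.0))
        prof = prof + cfg.patch_amplitude * bump
    return prof


def _place_rings(rng: np.random.Generator, cfg: SceneConfig) -> list[TrueRing]:
    h, w = cfg.image_size_px
    px = cfg.pixel_size_nm
    r_max_px = cfg.radius_range_nm[1] / px
    # margin keeps ring + confocal blur + profiling band inside the raster
    margin = r_max_px + 3.0 * cfg.psf_fwhm_conf_nm / (_FWHM * px) + 4.0
    if 2 * margin >= min(h, w):
        raise ValidationError("image too small for the requested ring radii")
    anchor_sep = 4.0 * r_max_px + 8.0  # cells never touch across clusters
    min_outside_gap_px = 100.0 / px    # isolated rings stay clearly Outside

    anchors: list[tuple[float, float]] = []
    for _ in range(cfg.n_cells):
        for _attempt in range(2000):
            cand = (rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin))
            if all(math.hypot(cand[0] - a[0], cand[1] - a[1]) >= anchor_sep for a in anchors):
                anchors.append(cand)
                break
        else:
            raise PlacementError(
                f"could not place {cfg.n_cells} cell anchors in a {h}x{w} image"
            )

    rings: list[TrueRing] = []
    for cell_id, anchor in enumerate(anchors):
        n_rings = int(rng.integers(cfg.rings_per_cell_range[0], cfg.rings_per_cell_range[1] + 1))
        cell_rings: list[TrueRing] = []
        for k in range(n_rings):
            radius_nm = float(rng.uniform(*cfg.radius_range_nm))
            r_px = radius_nm / px
            placed = False
            for _attempt in range(500):
                if k == 0:
                    cand = anchor
                elif rng.uniform() < cfg.cluster_probability:
                    host = cell_rings[int(rng.integers(len(cell_rings)))]
                    phi = rng.uniform(0.0, 2.0 * math.pi)
                    d = (host.radius_nm + radius_nm) / px  # exactly tangent
                    cand = (
                        host.center_px[0] + d * math.cos(phi),
                        host.center_px[1] + d * math.sin(phi),
                    )
                else:
                    off = rng.uniform(-2.0 * r_max_px, 2.0 * r_max_px, size=2)
                    cand = (anchor[0] + off[0], anchor[1] + off[1])
                if not (margin <= cand[0] <= h - 1 - margin and margin <= cand[1] <= w - 1 - margin):
                    continue
                ok = True
                for other in cell_rings:
                    d_px = math.hypot(cand[0] - other.center_px[0], cand[1] - other.center_px[1])
                    sum_r_px = (radius_nm + other.radius_nm) / px
                    if d_px < sum_r_px - 1.0:  # overlap beyond contact tolerance
                        ok = False
                        break
                    if k > 0 and d_px > sum_r_px + 0.01 and d_px < sum_r_px + min_outside_gap_px:
                        ok = False  # ambiguous near-contact; retry
                        break
                if ok:
                    cell_rings.append(TrueRing(cell_id, cand, radius_nm))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place ring {k} of cell {cell_id} after bounded retries"
                )
        rings.extend(cell_rings)
    return rings


def expected_labels(truth: SceneGroundTruth, gap_nm: float) -> np.ndarray:
    """Between/Outside ground-truth labels from the true circles.

    A sampled angle on ring *i* is Between iff its boundary point lies within
    ``gap_nm`` (boundary-to-boundary) of any other ring in the scene.  This is
    the oracle the fitted-circle classifier is checked against.
    """
    if gap_nm <= 0:
        raise ValidationError("gap_nm must be positive")
    return _labels_for_rings(truth.rings, truth.params.pixel_size_nm, gap_nm)


def _labels_for_rings(rings: list[TrueRing], pixel_size_nm: float, gap_nm: float) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, K_ANGLES, endpoint=False)
    out = np.zeros((len(rings), K_ANGLES), dtype=bool)
    for i, ri in enumerate(rings):
        r_px = ri.radius_nm / pixel_size_nm
        pr = ri.center_px[0] + r_px * np.cos(theta)
        pc = ri.center_px[1] + r_px * np.sin(theta)
        between = np.zeros(K_ANGLES, dtype=bool)
        for j, rj in enumerate(rings):
            if j == i:
                continue
            dist_px = np.hypot(pr - rj.center_px[0], pc - rj.center_px[1])
            gap = np.abs(dist_px * pixel_size_nm - rj.radius_nm)
            between |= gap <= gap_nm
        out[i] = between
    return out


def generate_scene(config: SceneConfig) -> SceneGroundTruth:
    """Draw ring geometry and per-ring angular truths for both channels.

    Deterministic: the same ``config`` (including ``rng_seed``) produces a
    bit-identical :class:`SceneGroundTruth`.
    """
    rng = np.random.default_rng(config.rng_seed)
    rings = _place_rings(rng, config)
    theta = np.linspace(0.0, 2.0 * math.pi, K_ANGLES, endpoint=False)

    labels = _labels_for_rings(rings, config.pixel_size_nm, _CONTACT_GAP_NM)
    t1 = np.empty((len(rings), K_ANGLES))
    t2 = np.empty_like(t1)
    a = config.coupling_alpha
    for i in range(len(rings)):
        x = _patch_profile(rng, config, theta)
        indep = _patch_profile(rng, config, theta)
        y = a * x / x.mean() + (1.0 - a) * indep / indep.mean()
        if config.outside_enrichment_beta != 1.0:
            y = np.where(labels[i], y, y * config.outside_enrichment_beta)
        t1[i] = x
        t2[i] = y
    return SceneGroundTruth(
        rings=rings,
        angular_truth_ch1=t1,
        angular_truth_ch2=t2,
        labels_between=labels,
        params=config,
    )


def _deposit_ring(
    raster: np.ndarray, ring: TrueRing, truth_row: np.ndarray, pixel_size_nm: float
) -> None:
    """Splat the angular truth onto the circle with bilinear weights.

    Each dense sample deposits ``truth * arc_length`` so the total deposited
    energy is the line integral of the truth and independent of sampling
    density.
    """
    r_px = ring.radius_nm / pixel_size_nm
    m = max(K_ANGLES, int(math.ceil(2.0 * math.pi * r_px / 0.25)))
    th = np.linspace(0.0, 2.0 * math.pi, m, endpoint=False)
    base = np.linspace(0.0, 2.0 * math.pi, K_ANGLES + 1)
    vals = np.interp(th, base, np.append(truth_row, truth_row[0]))
    vals = vals * (2.0 * math.pi * r_px / m)  # arc-length weight (px)
    rows = ring.center_px[0] + r_px * np.cos(th)
    cols = ring.center_px[1] + r_px * np.sin(th)
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= raster.shape[0] - 1 or cols.max() >= raster.shape[1] - 1):
        raise BoundsError(
            f"ring at ({ring.center_px[0]:.1f}, {ring.center_px[1]:.1f}) "
            f"r={ring.radius_nm:.0f} nm extends beyond the image"
        )
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    np.add.at(raster, (r0, c0), vals * (1 - fr) * (1 - fc))
    np.add.at(raster, (r0, c0 + 1), vals * (1 - fr) * fc)
    np.add.at(raster, (r0 + 1, c0), vals * fr * (1 - fc))
    np.add.at(raster, (r0 + 1, c0 + 1), vals * fr * fc)


def render_scene(
    truth: SceneGroundTruth, noise: bool = True
) -> tuple[ImagePlane, ImagePlane, pd.DataFrame]:
    """Rasterize both channels and emit a clicked-centers table.

    Each ring's angular truth is deposited on its circle, blurred with the
    channel's Gaussian PSF, scaled by ``photon_budget``, offset by the
    background, and (optionally) Poisson-sampled.  The centers table carries
    the true centers jittered by up to 2 px to emulate manual clicking.
    """
    cfg = truth.params
    h, w = cfg.image_size_px
    planes = []
    for fwhm, which, truths in (
        (cfg.psf_fwhm_sted_nm, "sted", truth.angular_truth_ch1),
        (cfg.psf_fwhm_conf_nm, "confocal", truth.angular_truth_ch2),
    ):
        raster = np.zeros((h, w), dtype=float)
        for ring, row in zip(truth.rings, truths):
            _deposit_ring(raster, ring, row, cfg.pixel_size_nm)
        sigma_px = fwhm / (_FWHM * cfg.pixel_size_nm)
        raster = ndimage.gaussian_filter(raster, sigma_px)
        raster = raster * cfg.photon_budget + cfg.background_level
        planes.append((which, raster))

    if noise:
        noise_rng = np.random.default_rng([cfg.rng_seed, 7])
        planes = [(which, noise_rng.poisson(np.clip(r, 0, None)).astype(float))
                  for which, r in planes]

    jitter_rng = np.random.default_rng([cfg.rng_seed, 3])
    rows = []
    for ring_id, ring in enumerate(truth.rings):
        jr, jc = jitter_rng.uniform(-2.0, 2.0, size=2)
        rows.append(
            {
                "image_id": 0,
                "cell_id": ring.cell_id,
                "row_px": ring.center_px[0] + jr,
                "col_px": ring.center_px[1] + jc,
                "ring_id": ring_id,
            }
        )
    centers = pd.DataFrame(rows, columns=["image_id", "cell_id", "row_px", "col_px", "ring_id"])

    sted = ImagePlane(planes[0][1], cfg.pixel_size_nm, "ch1", "sted")
    conf = ImagePlane(planes[1][1], cfg.pixel_size_nm, "ch2", "confocal")
    return sted, conf, centers
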