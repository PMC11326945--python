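"""Between/Outside classification of membrane arc samples.

A sample on ring *i* is "Between" when its boundary point lies within
``gap_nm`` (boundary-to-boundary, default 30 nm) of any other fitted ring in
the same image — i.e. at a peroxisome-peroxisome contact or inside a cluster.
All other samples are "Outside" (exposed to the cytosol).  Per-ring class
means of the companion-channel intensity feed a per-cell classification: the
cell's pooled Outside mean divided by its pooled Between mean decides the
predominant localization, and the fraction of cells classified Outside is the
condition-level readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .profile_extraction import MembraneProfile
from .ring_fitting import RingFitResult

__all__ = [
    "ContactConfig",
    "ArcLabeling",
    "PeroxisomeRecord",
    "CellRecord",
    "label_arc_samples",
    "between_outside_means",
    "classify_cell",
    "outside_percentage",
]


@dataclass(frozen=True)
class ContactConfig:
    """``gap_nm``: maximal boundary-to-boundary distance counted as contact."""

    gap_nm: float = 30.0

    def __post_init__(self) -> None:
        if self.gap_nm <= 0:
            raise ValidationError("gap_nm must be positive")


@dataclass(frozen=True)
class ArcLabeling:
    ring_id: int
    is_between: np.ndarray       # bool, length K
    gap_nm: float
    neighbor_ids: tuple[int, ...]

    @property
    def n_between(self) -> int:
        return int(np.count_nonzero(self.is_between))

    @property
    def n_outside(self) -> int:
        return len(self.is_between) - self.n_between


@dataclass
class PeroxisomeRecord:
    """Per-organelle statistics row."""

    ring_id: int
    cell_id: int
    condition: str = ""
    replicate: str = ""
    radius_nm: float = float("nan")
    circumference_nm: float = float("nan")
    n_points: int = 0
    method: str = ""
    mean_ch1: float = float("nan")
    mean_ch2: float = float("nan")
    R: float | None = None
    window: int = 0
    mean_between_ch2: float | None = None
    mean_outside_ch2: float | None = None
    mean_between_ch1: float | None = None
    mean_outside_ch1: float | None = None
    n_between: int = 0
    n_outside: int = 0
    quality: str = "ok"
    failure: str = ""            # empty for valid rows, error class name otherwise


@dataclass(frozen=True)
class CellRecord:
    cell_id: int
    condition: str
    replicate: str
    predominant: str             # "between" | "outside" | "indeterminate"
    ratio_outside_over_between: float | None
    n_rings: int


def label_arc_samples(
    index: int,
    fits: list[RingFitResult],
    profile_angles: np.ndarray,
    config: ContactConfig | None = None,
) -> ArcLabeling:
    """Label each profile angle of ring ``fits[index]`` Between or Outside.

    The point at angle theta is ``center_i + r_i * (cos t, sin t)``; it is
    Between iff ``min_j | ||p - center_j|| - r_j | * pixel_size <= gap_nm``
    over the other rings ``j`` of the same image.
    """
    config = config or ContactConfig()
    if len(fits) < 1:
        raise ValidationError("need at least one fitted ring")
    fit = fits[index]
    pixel_size_nm = fit.radius_nm / fit.radius_px
    theta = np.asarray(profile_angles, dtype=float)
    pr = fit.center[0] + fit.radius_px * np.cos(theta)
    pc = fit.center[1] + fit.radius_px * np.sin(theta)
    between = np.zeros(len(theta), dtype=bool)
    neighbors = []
    for j, other in enumerate(fits):
        if j == index:
            continue
        dist_px = np.hypot(pr - other.center[0], pc - other.center[1])
        hit = np.abs(dist_px - other.radius_px) * pixel_size_nm <= config.gap_nm
        if hit.any():
            neighbors.append(j)
            between |= hit
    return ArcLabeling(
        ring_id=index,
        is_between=between,
        gap_nm=config.gap_nm,
        neighbor_ids=tuple(neighbors),
    )


def between_outside_means(
    profile: MembraneProfile, labeling: ArcLabeling
) -> tuple[float | None, float | None, int, int]:
    """Class means of the companion-channel intensities.

    Returns ``(mean_between, mean_outside, n_between, n_outside)``; an empty
    class yields ``None`` for its mean.
    """
    mask = labeling.is_between
    if len(mask) != profile.n_samples:
        raise ValidationError(
            f"labeling length {len(mask)} != profile length {profile.n_samples}"
        )
    ch2 = profile.intensities_ch2
    n_b = int(np.count_nonzero(mask))
    n_o = len(mask) - n_b
    mean_b = float(ch2[mask].mean()) if n_b else None
    mean_o = float(ch2[~mask].mean()) if n_o else None
    return mean_b, mean_o, n_b, n_o


def _pooled(records: list[PeroxisomeRecord], which: str) -> tuple[float, float, int, int]:
    """Count-weighted pooled class means of one channel over a cell's rings."""
    mb, mo = f"mean_between_{which}", f"mean_outside_{which}"
    sum_b = sum(getattr(r, mb) * r.n_between for r in records
                if getattr(r, mb) is not None)
    n_b = sum(r.n_between for r in records if getattr(r, mb) is not None)
    sum_o = sum(getattr(r, mo) * r.n_outside for r in records
                if getattr(r, mo) is not None)
    n_o = sum(r.n_outside for r in records if getattr(r, mo) is not None)
    return sum_b, sum_o, n_b, n_o


def classify_cell(records: list[PeroxisomeRecord], rule: str = "pooled") -> CellRecord:
    """Predominant companion-protein localization of one cell.

    rule="pooled" (default): companion-channel class means are pooled over
    the cell's rings, weighted by sample counts, and the cell is "outside"
    iff pooled_outside / pooled_between > 1.  Ties classify as "between"
    (conservative).  A cell in which either class has no samples at all is
    "indeterminate" and excluded from condition percentages.

    rule="pooled_ratiometric": the pooled companion ratio is divided by the
    pooled membrane-channel ratio before thresholding at 1.  The membrane
    marker carries no localization signal of its own, so its Outside/Between
    ratio measures the purely geometric intensity transfer (two membranes
    superpose at every contact, and blur mixes cluster-interior signal);
    dividing by it isolates the companion protein's true enrichment.

    rule="brightest_ring": the single ring with the largest class mean decides
    — the cell is "outside" iff the largest per-ring class mean over both
    classes is an Outside mean.
    """
    if not records:
        raise ValidationError("empty record list")
    if rule not in ("pooled", "pooled_ratiometric", "brightest_ring"):
        raise ValidationError(
            "rule must be 'pooled', 'pooled_ratiometric' or 'brightest_ring'"
        )
    cell_id = records[0].cell_id
    condition = records[0].condition
    replicate = records[0].replicate

    if rule == "brightest_ring":
        best_val, best_cls = -np.inf, None
        for r in records:
            if r.mean_between_ch2 is not None and r.mean_between_ch2 > best_val:
                best_val, best_cls = r.mean_between_ch2, "between"
            if r.mean_outside_ch2 is not None and r.mean_outside_ch2 > best_val:
                best_val, best_cls = r.mean_outside_ch2, "outside"
        return CellRecord(cell_id, condition, replicate,
                          best_cls or "indeterminate", None, len(records))

    sum_b, sum_o, n_b, n_o = _pooled(records, "ch2")
    if n_b == 0 or n_o == 0 or sum_b == 0:
        return CellRecord(cell_id, condition, replicate, "indeterminate", None, len(records))
    ratio = (sum_o / n_o) / (sum_b / n_b)
    if rule == "pooled_ratiometric":
        mb1, mo1, nb1, no1 = _pooled(records, "ch1")
        if nb1 == 0 or no1 == 0 or mb1 == 0 or mo1 == 0:
            return CellRecord(cell_id, condition, replicate, "indeterminate",
                              None, len(records))
        ratio = ratio / ((mo1 / no1) / (mb1 / nb1))
    predominant = "outside" if ratio > 1.0 else "between"
    return CellRecord(cell_id, condition, replicate, predominant, ratio, len(records))


def outside_percentage(cells: list[CellRecord]) -> tuple[float | None, int]:
    """Percentage of determinate cells whose predominant class is Outside.

    Returns ``(percentage, n_indeterminate_excluded)``; the percentage is
    ``None`` when no cell is determinate.
    """
    if not cells:
        raise ValidationError("empty cell list")
    n_out = sum(1 for c in cells if c.predominant == "outside")
    n_btw = sum(1 for c in cells if c.predominant == "between")
    n_ind = len(cells) - n_out - n_btw
    if n_out + n_btw == 0:
        return None, n_ind
    return 100.0 * n_out / (n_out + n_btw), n_ind
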