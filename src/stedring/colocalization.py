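"""Per-peroxisome moving-average Pearson correlation between the channels.

The R value reported per organelle is the product-moment correlation of the
two membrane profiles after each has been smoothed with a circular moving
average (the profiles are periodic in arc position, so the window wraps
around).  Zero-variance inputs yield an undefined R, flagged explicitly and
never silently imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .profile_extraction import MembraneProfile

__all__ = ["CorrelationResult", "moving_average_circular", "pearson_r", "ring_correlation"]

DEFAULT_WINDOW = 5


@dataclass(frozen=True)
class CorrelationResult:
    ring_id: int
    R: float | None          # None when undefined (zero variance)
    window: int
    n_samples: int

    @property
    def defined(self) -> bool:
        return self.R is not None


def moving_average_circular(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with wrap-around.

    ``window`` must be odd and within ``[1, len(values)]``.  The circular
    window makes the operation a doubly stochastic linear map, so the mean of
    the output equals the mean of the input exactly.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("values must be 1D")
    k = len(x)
    if window % 2 == 0 or not (1 <= window <= k):
        raise ValidationError(f"window must be odd and in [1, {k}], got {window}")
    if window == 1:
        return x.copy()
    half = window // 2
    padded = np.concatenate([x[-half:], x, x[:half]])
    return np.convolve(padded, np.full(window, 1.0 / window), mode="valid")


def pearson_r(a: np.ndarray, b: np.ndarray) -> float | None:
    """Product-moment correlation; ``None`` when either input is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 3:
        raise ValidationError("need at least 3 samples")
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    if va == 0.0 or vb == 0.0:
        return None
    return float((da @ db) / np.sqrt(va * vb))


def ring_correlation(
    profile: MembraneProfile, window: int = DEFAULT_WINDOW, ring_id: int = 0
) -> CorrelationResult:
    """R of the moving averages of the two channel profiles of one ring."""
    r = pearson_r(
        moving_average_circular(profile.intensities_ch1, window),
        moving_average_circular(profile.intensities_ch2, window),
    )
    return CorrelationResult(
        ring_id=ring_id, R=r, window=window, n_samples=profile.n_samples
    )
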