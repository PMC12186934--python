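"""Signal-bias correction and MagDensity summarization.

The measured fat fraction FF = S_fat/(S_fat+S_water) is biased relative to
the volumetric fat fraction by proton-density and T1 differences between
fat and water and by residual water in adipose tissue.  At each voxel a
linear model relates signals to volumes:

    S_fat   = a V_fat + b V_water
    S_water = c V_fat + d V_water

The correction factors are estimated from reference regions of "pure" fat
(subcutaneous fat; V_fat = 1) and "pure" water (pectoral muscle; V_water = 1)
sampled on the fat-fraction map.  Under the normalization a + c = b + d = 1
(total signal of each pure tissue scaled to one; volumes as fractions with
V_fat + V_water = 1), the measured fat signal fraction of a voxel is
s = a V_fat + b V_water, so

    FraWater = V_water = (a - s) / (a - b)

and MagDensity is the mean FraWater over the segmented breast, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateReferenceError, DomainError, SingularCorrectionError

__all__ = [
    "CorrectionFactors",
    "DensityRecord",
    "sample_reference",
    "estimate_correction_factors",
    "average_factors",
    "frawater_map",
    "magdensity",
]


@dataclass(frozen=True)
class CorrectionFactors:
    """Linear signal-model correction coefficients (a+c = b+d = 1 closure)."""

    a: float
    b: float
    c: float
    d: float
    source: str = "per-image"
    n_images: int = 1

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d)
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise DomainError(f"correction factors outside [0, 1]: {vals}")
        if abs(self.a + self.c - 1.0) > 1e-9 or abs(self.b + self.d - 1.0) > 1e-9:
            raise DomainError("normalization a+c = b+d = 1 violated")
        if self.a <= self.b:
            raise DegenerateReferenceError(
                f"a={self.a} must exceed b={self.b} (fat reference must be fattier)"
            )


@dataclass(frozen=True)
class DensityRecord:
    """Per-breast MagDensity value (percent) with its provenance."""

    subject_id: str
    side: str
    scanner: str
    magdensity: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise DomainError(f"side must be 'L' or 'R', got {self.side!r}")
        if not 0.0 <= self.magdensity <= 100.0:
            raise DomainError(f"magdensity {self.magdensity} outside [0, 100]")
        if self.n_voxels <= 0:
            raise DomainError("n_voxels must be positive")


def _trimmed_mean(values: np.ndarray, proportion: float = 0.2) -> float:
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise DomainError("reference ROI has no valid voxels")
    return float(stats.trim_mean(values, proportiontocut=proportion))


def sample_reference(
    ff_map: np.ndarray,
    fat_roi: np.ndarray,
    water_roi: np.ndarray,
    *,
    trim: float = 0.2,
) -> tuple[float, float]:
    """Robust reference fat-fraction values from pure-fat and pure-water ROIs.

    Returns the 20%-trimmed mean (per side) of valid fat-fraction voxels in
    each ROI; robust to partial-volume outliers at ROI edges.  Raises
    :class:`DegenerateReferenceError` if the fat reference does not exceed
    the water reference, which signals swapped or mis-placed ROIs.
    """
    fat_roi = np.asarray(fat_roi, dtype=bool)
    water_roi = np.asarray(water_roi, dtype=bool)
    if not fat_roi.any() or not water_roi.any():
        raise DomainError("reference ROIs must be non-empty")
    ff_fat = _trimmed_mean(np.asarray(ff_map)[fat_roi], trim)
    ff_water = _trimmed_mean(np.asarray(ff_map)[water_roi], trim)
    if ff_fat <= ff_water:
        raise DegenerateReferenceError(
            f"fat reference FF {ff_fat:.3f} <= water reference FF {ff_water:.3f}"
        )
    return ff_fat, ff_water


def estimate_correction_factors(
    ff_fat_ref: float, ff_water_ref: float
) -> CorrectionFactors:
    """Correction factors from the two pure-region fat-fraction observations.

    Substituting (V_fat, V_water) = (1, 0) and (0, 1) into the linear signal
    model under the a+c = b+d = 1 normalization gives a = FF(pure fat),
    b = FF(pure water), c = 1-a, d = 1-b.
    """
    if not 0.0 <= ff_water_ref < ff_fat_ref <= 1.0:
        raise DegenerateReferenceError(
            f"require 0 <= FF_water ({ff_water_ref}) < FF_fat ({ff_fat_ref}) <= 1"
        )
    a = float(ff_fat_ref)
    b = float(ff_water_ref)
    return CorrectionFactors(a=a, b=b, c=1.0 - a, d=1.0 - b, source="per-image")


def average_factors(per_image: Sequence[CorrectionFactors]) -> CorrectionFactors:
    """Componentwise mean of per-image factors -> scanner-specific set."""
    if len(per_image) == 0:
        raise DomainError("no per-image factor sets to average")
    a = float(np.mean([f.a for f in per_image]))
    b = float(np.mean([f.b for f in per_image]))
    c = float(np.mean([f.c for f in per_image]))
    d = float(np.mean([f.d for f in per_image]))
    return CorrectionFactors(
        a=a, b=b, c=c, d=d, source="scanner-averaged", n_images=len(per_image)
    )


def frawater_map(
    ff_map: np.ndarray,
    factors: CorrectionFactors,
    *,
    with_stats: bool = False,
):
    """Bias-corrected volumetric water fraction per voxel.

    For measured fat signal fraction s: V_fat = (s-b)/(a-b) and
    FraWater = 1 - V_fat = (a-s)/(a-b), clamped to [0, 1].  NaN (invalid)
    voxels propagate.  With ``with_stats`` also returns the fraction of
    valid voxels that required clamping.
    """
    if abs(factors.a - factors.b) < 1e-12:
        raise SingularCorrectionError("a == b: correction not invertible")
    ff_map = np.asarray(ff_map, dtype=float)
    raw = (factors.a - ff_map) / (factors.a - factors.b)
    fra = np.clip(raw, 0.0, 1.0)
    fra = np.where(np.isfinite(ff_map), fra, np.nan)
    if not with_stats:
        return fra
    valid = np.isfinite(raw)
    n_valid = int(valid.sum())
    # float round-off at the exact reference values is not clamping
    clipped = valid & ((raw < -1e-9) | (raw > 1.0 + 1e-9))
    clip_fraction = float(clipped.sum() / n_valid) if n_valid else 0.0
    return fra, clip_fraction


def magdensity(frawater: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """MagDensity: 100 x mean FraWater over valid masked voxels.

    Returns (percent, n_voxels used).
    """
    mask = np.asarray(mask, dtype=bool)
    vals = np.asarray(frawater)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise DomainError("breast mask contains no valid voxels")
    return 100.0 * float(vals.mean()), int(vals.size)
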