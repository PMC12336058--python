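"""Threshold-independent bootstrap laterality index for ROI statistic maps.

Given the voxel statistic values of a left- and right-hemisphere region of
interest (e.g. the middle-cerebral-artery territory of a verbal-fluency
contrast map), the index resamples supra-threshold voxels across a ladder
of thresholds:

1. thresholds are ``n_thresholds`` equally spaced levels from 0
   (exclusive) to the maximum statistic across both hemispheres;
2. at each admissible threshold, ``n_boot`` bootstrap resamples of size
   ``ceil(resample_ratio * n)`` are drawn with replacement per side and
   all ``n_boot**2`` pairwise indices ``(sum_R - sum_L)/(sum_R + sum_L)``
   are formed;
3. the central portion (after trimming ``trim`` from each tail) is
   averaged per threshold, and the overall index is the threshold-weighted
   mean of the per-threshold trimmed means (weights proportional to the
   threshold level).

The sign convention matches the Doppler laterality index: -1 means
activation confined to the left hemisphere, +1 to the right.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["StatMapROI", "BootstrapLIConfig", "ThresholdLI",
           "BootstrapLIResult", "bootstrap_li", "extract_roi_values"]


@dataclass(frozen=True)
class StatMapROI:
    """Voxel statistic values of the left and right ROI."""

    left_values: np.ndarray
    right_values: np.ndarray

    def __post_init__(self) -> None:
        lv = np.asarray(self.left_values, dtype=float).ravel()
        rv = np.asarray(self.right_values, dtype=float).ravel()
        if not (np.all(np.isfinite(lv)) and np.all(np.isfinite(rv))):
            raise ValueError("ROI statistic values must be finite")
        object.__setattr__(self, "left_values", lv)
        object.__setattr__(self, "right_values", rv)

    def swapped(self) -> "StatMapROI":
        return StatMapROI(self.right_values.copy(), self.left_values.copy())


@dataclass(frozen=True)
class BootstrapLIConfig:
    n_thresholds: int = 20
    n_boot: int = 100
    resample_ratio: float = 0.25
    trim: float = 0.25
    min_voxels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.resample_ratio <= 1.0:
            raise ValueError("resample_ratio must be in (0, 1]")
        if not 0.0 <= self.trim < 0.5:
            raise ValueError("trim must be in [0, 0.5)")
        if self.n_thresholds < 1 or self.n_boot < 1 or self.min_voxels < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class ThresholdLI:
    threshold: float
    li: float
    n_left: int
    n_right: int


@dataclass(frozen=True)
class BootstrapLIResult:
    li_overall: float
    per_threshold: tuple
    n_thresholds_used: int

    def to_dict(self) -> dict:
        return {
            "li_overall": self.li_overall,
            "n_thresholds_used": self.n_thresholds_used,
            "per_threshold": [
                {"threshold": t.threshold, "li": t.li,
                 "n_left": t.n_left, "n_right": t.n_right}
                for t in self.per_threshold],
        }


def _boot_sums(rng: np.random.Generator, values: np.ndarray, n_boot: int,
               ratio: float) -> np.ndarray:
    """Sums of ``n_boot`` with-replacement resamples of size ceil(ratio*n).

    An empty value set contributes zero sums (no supra-threshold
    activation on that side).
    """
    n = len(values)
    if n == 0:
        return np.zeros(n_boot)
    m = max(1, math.ceil(ratio * n))
    idx = rng.integers(0, n, size=(n_boot, m))
    return values[idx].sum(axis=1)


def bootstrap_li(roi: StatMapROI, cfg: BootstrapLIConfig | None = None) -> BootstrapLIResult:
    """Compute the threshold-independent bootstrap laterality index.

    A threshold is admissible when at least one hemisphere has
    ``min_voxels`` or more supra-threshold voxels; a hemisphere with no
    supra-threshold voxels contributes zero activation, so one-sided maps
    reach the -1/+1 endpoints exactly.  Raises when no threshold is
    admissible.  Deterministic under a fixed ``cfg.seed``.
    """
    cfg = cfg or BootstrapLIConfig()
    vmax = float(max(roi.left_values.max(initial=-np.inf),
                     roi.right_values.max(initial=-np.inf)))
    if not np.isfinite(vmax) or vmax <= 0:
        raise ValueError("insufficient supra-threshold voxels: no positive values")
    thresholds = vmax * np.arange(1, cfg.n_thresholds + 1) / cfg.n_thresholds
    rng = np.random.default_rng(cfg.seed)
    k_trim = None
    rows = []
    for thr in thresholds:
        lv = roi.left_values[roi.left_values >= thr]
        rv = roi.right_values[roi.right_values >= thr]
        if max(len(lv), len(rv)) < cfg.min_voxels:
            continue
        sums_l = _boot_sums(rng, lv, cfg.n_boot, cfg.resample_ratio)
        sums_r = _boot_sums(rng, rv, cfg.n_boot, cfg.resample_ratio)
        lis = (sums_r[None, :] - sums_l[:, None]) / (sums_r[None, :] + sums_l[:, None])
        lis = np.sort(lis.ravel())
        k_trim = int(cfg.trim * lis.size)
        central = lis[k_trim:lis.size - k_trim] if k_trim > 0 else lis
        rows.append(ThresholdLI(float(thr), float(central.mean()),
                                int(len(lv)), int(len(rv))))
    if not rows:
        raise ValueError(
            f"insufficient supra-threshold voxels: no threshold with >= "
            f"{cfg.min_voxels} voxels on either side")
    weights = np.array([t.threshold for t in rows])
    lis = np.array([t.li for t in rows])
    overall = float((weights * lis).sum() / weights.sum())
    return BootstrapLIResult(overall, tuple(rows), len(rows))


def extract_roi_values(volume: np.ndarray, mask_left: np.ndarray,
                       mask_right: np.ndarray) -> StatMapROI:
    """Gather statistic values where each hemisphere mask is true.

    Masks must share the volume's shape and be disjoint.
    """
    volume = np.asarray(volume, dtype=float)
    mask_left = np.asarray(mask_left, dtype=bool)
    mask_right = np.asarray(mask_right, dtype=bool)
    if volume.shape != mask_left.shape or volume.shape != mask_right.shape:
        raise ValueError("volume and masks must share the same shape")
    if np.any(mask_left & mask_right):
        raise ValueError("left and right masks overlap")
    return StatMapROI(volume[mask_left], volume[mask_right])
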