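"""Laterality index computation and hemispheric-dominance classification.

The laterality index (LI) of a session is the average, over kept epochs,
of the mean right-minus-left Delta-% CBFV difference within the period of
interest (POI).  Negative LIs indicate leftward (left-hemisphere)
dominance.  Epoch-to-epoch variability yields a participant-specific
standard error; a 95 % confidence interval around the LI drives the
trichotomous classification: if the interval contains zero the session is
labelled bilateral (BLD), otherwise left (LLD) or right (RLD) dominant by
the sign of the LI.  A fixed-cutoff classifier (|LI| <= cutoff means
bilateral) is provided for cutoff-sweep analyses.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import EpochSet, InsufficientEpochsError, PreprocessConfig

__all__ = [
    "LLD", "BLD", "RLD",
    "LateralityResult",
    "per_epoch_li",
    "compute_li",
    "split_half_li",
    "classify_ci",
    "classify_cutoff",
    "dichotomize",
]

logger = logging.getLogger(__name__)

LLD = "LLD"
BLD = "BLD"
RLD = "RLD"


@dataclass(frozen=True)
class LateralityResult:
    """Per-session laterality summary.

    ``li`` and the interval bounds are in Delta-% units; ``li_odd`` /
    ``li_even`` are the split-half LIs over odd- and even-numbered trials
    (NaN when a half is empty after QC).
    """

    li: float
    se: float
    ci_low: float
    ci_high: float
    n_epochs: int
    per_epoch_li: np.ndarray
    li_odd: float
    li_even: float
    label: str
    label_dichotomous: str

    def to_dict(self) -> dict:
        return {
            "li": self.li,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_epochs": self.n_epochs,
            "li_odd": None if math.isnan(self.li_odd) else self.li_odd,
            "li_even": None if math.isnan(self.li_even) else self.li_even,
            "label_trichotomous": self.label,
            "label_dichotomous": self.label_dichotomous,
        }


def _poi_mask(es: EpochSet, cfg: PreprocessConfig) -> np.ndarray:
    lo, hi = cfg.poi_window
    mask = (es.rel_time >= lo) & (es.rel_time < hi)
    if not mask.any():
        raise InsufficientEpochsError("POI window is empty on the epoch time grid")
    return mask


def per_epoch_li(es: EpochSet, cfg: PreprocessConfig | None = None) -> tuple:
    """Return ``(trial_indices, lis)`` for kept epochs.

    Each epoch's LI is the simple mean of (right - left) over the POI
    samples.
    """
    cfg = cfg or PreprocessConfig()
    mask = _poi_mask(es, cfg)
    kept = es.kept_epochs
    idx = np.array([e.trial_index for e in kept], dtype=int)
    lis = np.array([(e.right[mask] - e.left[mask]).mean() for e in kept])
    return idx, lis


def _ci_multiplier(n: int, ci_method: str) -> float:
    if ci_method == "normal":
        return 1.96
    if ci_method == "t":
        return float(stats.t.ppf(0.975, n - 1))
    raise ValueError(f"unknown ci_method {ci_method!r}; use 't' or 'normal'")


def compute_li(es: EpochSet, cfg: PreprocessConfig | None = None,
               ci_method: str = "t") -> LateralityResult:
    """Compute the session LI, its SE/CI, split-half LIs and the labels.

    The SE is the sample standard deviation (n-1) of the per-epoch LIs
    divided by sqrt(n); the 95 % CI uses a Student-t quantile by default
    (``ci_method='normal'`` selects the fixed 1.96 multiplier).
    Requires at least two kept epochs.
    """
    cfg = cfg or PreprocessConfig()
    if not es.baseline_corrected:
        raise InsufficientEpochsError("compute_li requires baseline-corrected epochs")
    idx, lis = per_epoch_li(es, cfg)
    n = len(lis)
    if n < 2:
        raise InsufficientEpochsError(
            f"insufficient epochs: need >= 2 kept epochs, got {n}")
    li = float(lis.mean())
    se = float(lis.std(ddof=1) / np.sqrt(n))
    half = _ci_multiplier(n, ci_method) * se
    ci_low, ci_high = li - half, li + half
    li_odd, li_even = split_half_li(es, cfg)
    label = classify_ci(li, ci_low, ci_high)
    return LateralityResult(li, se, ci_low, ci_high, n, lis, li_odd, li_even,
                            label, dichotomize(li))


def split_half_li(es: EpochSet, cfg: PreprocessConfig | None = None) -> tuple:
    """LIs restricted to odd and even trials (parity of the 1-based design
    position, not the post-QC position).  An empty half yields NaN."""
    cfg = cfg or PreprocessConfig()
    idx, lis = per_epoch_li(es, cfg)
    odd = lis[idx % 2 == 1]
    even = lis[idx % 2 == 0]
    li_odd = float(odd.mean()) if len(odd) else float("nan")
    li_even = float(even.mean()) if len(even) else float("nan")
    return li_odd, li_even


def classify_ci(li: float, ci_low: float, ci_high: float) -> str:
    """Trichotomous label from the confidence interval: bilateral when the
    interval contains zero, otherwise the side given by the sign of the LI."""
    if ci_low <= 0.0 <= ci_high:
        return BLD
    return LLD if li < 0 else RLD


def dichotomize(li: float) -> str:
    """Dichotomous left/right label by the sign of the LI.

    An exactly zero LI is resolved to "left" (and logged): a deterministic
    rule for a measure-zero event.
    """
    if li == 0.0:
        logger.warning("LI is exactly 0; dichotomous label resolved to 'left'")
        return "left"
    return "left" if li < 0 else "right"


def classify_cutoff(li: float, cutoff: float) -> str:
    """Fixed-cutoff label: bilateral iff |LI| <= cutoff, else by sign."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if abs(li) <= cutoff:
        return BLD
    return LLD if li < 0 else RLD
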