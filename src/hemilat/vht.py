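"""Visual half-field task (VHT) scoring and accuracy asymmetry.

In a VHT, lateralized words are flashed briefly in the left (LVF) or right
(RVF) visual hemifield; because each hemifield projects to the
contralateral hemisphere, the language-dominant hemisphere processes words
from the opposite hemifield more accurately.  The asymmetry index is the
normalized accuracy difference

    asymmetry = (acc_LVF - acc_RVF) / (acc_LVF + acc_RVF),

bounded in [-1, 1].  A right-visual-field advantage (left-hemisphere
dominance) yields a negative value, matching the Doppler LI sign
convention.  Central-digit control trials (fixation checks) are never
counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = ["LVF", "RVF", "VHTTrial", "VHTAsymmetry", "score_vht",
           "vht_asymmetry", "rt_asymmetry"]

LVF = "LVF"
RVF = "RVF"


@dataclass(frozen=True)
class VHTTrial:
    """One trial: the target word, its hemifield, and scored correctness.

    ``target_field`` is None for central control trials.
    """

    target_word: str
    target_field: Optional[str]
    correct: bool
    is_control: bool = False
    rt_ms: Optional[float] = None


@dataclass(frozen=True)
class VHTAsymmetry:
    acc_lvf: float
    acc_rvf: float
    asymmetry: float
    n_lvf: int
    n_rvf: int

    def to_dict(self) -> dict:
        return {"acc_lvf": self.acc_lvf, "acc_rvf": self.acc_rvf,
                "asymmetry": self.asymmetry,
                "n": {"LVF": self.n_lvf, "RVF": self.n_rvf}}


def score_vht(trials: Iterable[VHTTrial]) -> tuple:
    """Per-hemifield accuracy among non-control trials.

    Returns ``(acc_lvf, acc_rvf, n_per_field)`` where ``n_per_field`` maps
    field name to trial count.  Raises if either field has no trials.
    """
    counts = {LVF: 0, RVF: 0}
    correct = {LVF: 0, RVF: 0}
    for t in trials:
        if t.is_control:
            continue
        if t.target_field not in counts:
            raise ValueError(f"unknown target field {t.target_field!r}")
        counts[t.target_field] += 1
        correct[t.target_field] += int(t.correct)
    for f in (LVF, RVF):
        if counts[f] == 0:
            raise ValueError(f"no non-control trials in field {f}")
    return (correct[LVF] / counts[LVF], correct[RVF] / counts[RVF],
            dict(counts))


def vht_asymmetry(acc_lvf: float, acc_rvf: float,
                  n_per_field: Optional[dict] = None) -> VHTAsymmetry:
    """Normalized accuracy difference between hemifields.

    Undefined (raises) when both accuracies are zero.
    """
    for name, a in (("acc_lvf", acc_lvf), ("acc_rvf", acc_rvf)):
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0, 1]")
    denom = acc_lvf + acc_rvf
    if denom <= 0:
        raise ValueError("asymmetry undefined: both accuracies are zero")
    asym = (acc_lvf - acc_rvf) / denom
    n = n_per_field or {}
    return VHTAsymmetry(acc_lvf, acc_rvf, float(asym),
                        int(n.get(LVF, 0)), int(n.get(RVF, 0)))


def rt_asymmetry(trials: Iterable[VHTTrial]) -> float:
    """Secondary reaction-time index: the same normalized difference on
    per-field median RTs of correct trials, sign-inverted so that faster
    RVF responses (left-hemisphere dominance) come out negative."""
    rts = {LVF: [], RVF: []}
    for t in trials:
        if t.is_control or not t.correct or t.rt_ms is None:
            continue
        if t.target_field in rts:
            rts[t.target_field].append(t.rt_ms)
    if not rts[LVF] or not rts[RVF]:
        raise ValueError("need correct trials with RTs in both fields")
    m_l = float(np.median(rts[LVF]))
    m_r = float(np.median(rts[RVF]))
    return -(m_l - m_r) / (m_l + m_r)
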