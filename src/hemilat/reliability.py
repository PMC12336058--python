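"""Test-retest reliability battery and group-comparison statistics.

Given per-subject laterality indices and dominance labels from two
sessions, this module computes:

* ICC(A,1) — intraclass correlation from the two-way ANOVA decomposition,
  absolute agreement, single measurement, with the significance F-test on
  Satterthwaite-approximated denominator degrees of freedom (which are in
  general non-integer);
* Cohen's kappa over the fixed {LLD, BLD, RLD} label universe, with the
  large-sample Z statistic under the chance-agreement null;
* uncorrected percentage agreement for subgroups;
* Bland-Altman mean difference and 95 % limits of agreement;
* a cutoff sweep reporting, per LI cutoff, the proportion classified
  bilateral in session 1 and the fraction of those replicating in
  session 2;
* Welch and paired t-tests, a one-sided Mann-Whitney U test with effect
  size r = |z|/sqrt(N), and Spearman's rank correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .laterality import BLD, LLD, RLD, classify_cutoff

__all__ = [
    "PairedLISet",
    "ICCResult",
    "KappaResult",
    "BlandAltmanResult",
    "RankTestResult",
    "TTestResult",
    "icc_a1",
    "cohens_kappa",
    "percent_agreement",
    "bland_altman",
    "cutoff_sweep",
    "default_cutoff_grid",
    "t_test",
    "mann_whitney_onesided",
    "spearman_rho",
]

LABEL_UNIVERSE = (LLD, BLD, RLD)


@dataclass
class PairedLISet:
    """Per-subject LIs and labels from two sessions."""

    ids: np.ndarray
    li_s1: np.ndarray
    li_s2: np.ndarray
    label_s1: np.ndarray
    label_s2: np.ndarray
    subgroup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.li_s1 = np.asarray(self.li_s1, dtype=float)
        self.li_s2 = np.asarray(self.li_s2, dtype=float)
        self.label_s1 = np.asarray(self.label_s1, dtype=object)
        self.label_s2 = np.asarray(self.label_s2, dtype=object)
        n = len(self.ids)
        for name in ("li_s1", "li_s2", "label_s1", "label_s2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match ids")
        if self.subgroup is not None:
            self.subgroup = np.asarray(self.subgroup, dtype=object)
            if len(self.subgroup) != n:
                raise ValueError("subgroup length does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PairedLISet":
        sub = df["subgroup"].to_numpy() if "subgroup" in df.columns else None
        return cls(df["id"].to_numpy(), df["li_s1"].to_numpy(),
                   df["li_s2"].to_numpy(), df["label_s1"].to_numpy(),
                   df["label_s2"].to_numpy(), sub)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"id": self.ids, "li_s1": self.li_s1, "li_s2": self.li_s2,
                "label_s1": self.label_s1, "label_s2": self.label_s2}
        if self.subgroup is not None:
            data["subgroup"] = self.subgroup
        return pd.DataFrame(data)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    f: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    z: float
    p: float
    contingency: np.ndarray
    categories: tuple = LABEL_UNIVERSE


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # U of the first sample (R's W convention)
    p: float
    effect_r: float
    z: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------

def icc_a1(s1, s2) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    Uses the mean squares of the subjects-by-sessions ANOVA table,

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E)),

    with k = 2 sessions.  The F-test of zero ICC follows the
    McGraw & Wong construction with the denominator degrees of freedom
    approximated by Satterthwaite's method, so df2 is generally
    non-integer.  Because the mixing weights depend on the estimated ICC,
    df2 also varies with the data.
    """
    x = np.column_stack([np.asarray(s1, float), np.asarray(s2, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = ((x - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total <= 0:
        raise ValueError("degenerate data: zero total variance")
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))

    # Significance test: F = MS_R / (a MS_C + b MS_E) against
    # F(n-1, v) with Satterthwaite df v; a, b use the estimated ICC.
    df1 = float(n - 1)
    if icc < 1.0:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        denom = a * ms_c + b * ms_e
    else:  # perfect agreement: the weights diverge
        denom = 0.0
    if not np.isfinite(denom) or denom <= 0:
        # perfect agreement or degenerate denominator: fall back to the
        # null-weights test F = MS_R / MS_E
        f = np.inf if ms_e == 0 else ms_r / ms_e
        df2 = float((n - 1) * (k - 1))
        p = 0.0 if not np.isfinite(f) else float(stats.f.sf(f, df1, df2))
        return ICCResult(float(icc), float(f), df1, df2, p)
    f = ms_r / denom
    num = (a * ms_c + b * ms_e) ** 2
    den = (a * ms_c) ** 2 / (k - 1) + (b * ms_e) ** 2 / ((n - 1) * (k - 1))
    df2 = float(num / den) if den > 0 else float((n - 1) * (k - 1))
    p = float(stats.f.sf(f, df1, df2))
    return ICCResult(float(icc), float(f), df1, df2, p)


# ---------------------------------------------------------------------------
# categorical agreement
# ---------------------------------------------------------------------------

def cohens_kappa(labels1, labels2, categories=LABEL_UNIVERSE) -> KappaResult:
    """Cohen's kappa over a fixed category universe.

    Expected agreement comes from the marginal products; absent categories
    contribute zero marginals.  Z is kappa divided by its large-sample
    standard error under the chance-agreement null (Fleiss), with a
    one-sided p-value for kappa > 0.
    """
    l1 = np.asarray(labels1, dtype=object)
    l2 = np.asarray(labels2, dtype=object)
    if len(l1) != len(l2) or len(l1) < 2:
        raise ValueError("label lists must have equal length >= 2")
    cats = list(categories)
    unknown = (set(l1) | set(l2)) - set(cats)
    if not set(l1) <= set(cats) or not set(l2) <= set(cats):
        raise ValueError(f"labels outside category universe {cats}: {unknown}")
    n = len(l1)
    kcat = len(cats)
    table = np.zeros((kcat, kcat), dtype=int)
    index = {c: i for i, c in enumerate(cats)}
    for a, b in zip(l1, l2):
        table[index[a], index[b]] += 1
    p = table / n
    po = np.trace(p)
    pr = p.sum(axis=1)  # rater-1 marginals
    pc = p.sum(axis=0)  # rater-2 marginals
    pe = float((pr * pc).sum())
    if pe >= 1.0:
        return KappaResult(float("nan"), float("nan"), float("nan"), table, tuple(cats))
    kappa = (po - pe) / (1.0 - pe)
    var0 = (pe + pe ** 2 - float((pr * pc * (pr + pc)).sum())) / (n * (1.0 - pe) ** 2)
    if var0 <= 0:
        z, pval = float("nan"), float("nan")
    else:
        z = kappa / math.sqrt(var0)
        pval = float(stats.norm.sf(z))
    return KappaResult(float(kappa), float(z), pval, table, tuple(cats))


def percent_agreement(labels1, labels2, subgroup_mask=None) -> tuple:
    """Fraction of (subgroup) subjects with identical labels in both
    sessions.  Returns ``(fraction, display_percent)`` where the display
    value is rounded to an integer percent."""
    l1 = np.asarray(labels1, dtype=object)
    l2 = np.asarray(labels2, dtype=object)
    if len(l1) != len(l2):
        raise ValueError("label lists must have equal length")
    if subgroup_mask is not None:
        mask = np.asarray(subgroup_mask, dtype=bool)
        l1, l2 = l1[mask], l2[mask]
    if len(l1) == 0:
        raise ValueError("empty subgroup")
    frac = float((l1 == l2).mean())
    return frac, int(round(frac * 100.0))


# ---------------------------------------------------------------------------
# agreement of continuous LIs
# ---------------------------------------------------------------------------

def bland_altman(s1, s2) -> BlandAltmanResult:
    """Mean session difference (session1 - session2), its sample SD, and
    the 95 % limits of agreement (mean +/- 1.96 SD)."""
    x = np.asarray(s1, dtype=float)
    y = np.asarray(s2, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need >= 2 paired observations")
    diffs = x - y
    means = 0.5 * (x + y)
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    half = 1.96 * sd_diff
    return BlandAltmanResult(mean_diff, sd_diff, mean_diff - half,
                             mean_diff + half, means, diffs)


def default_cutoff_grid() -> np.ndarray:
    """The standard cutoff ladder 0.0, 0.1, ..., 1.5 (16 values)."""
    return np.round(np.arange(0.0, 1.5 + 1e-9, 0.1), 10)


def cutoff_sweep(li_s1, li_s2, cutoffs=None) -> pd.DataFrame:
    """Fixed-cutoff bilaterality replication table.

    For each cutoff c: the proportion of subjects with |LI| <= c in
    session 1, and among those, the proportion also bilateral in
    session 2 (NaN when no subject is bilateral in session 1).
    """
    x = np.asarray(li_s1, dtype=float)
    y = np.asarray(li_s2, dtype=float)
    if len(x) != len(y):
        raise ValueError("sessions must have equal length")
    cuts = default_cutoff_grid() if cutoffs is None else np.asarray(cutoffs, float)
    if np.any(cuts < 0) or np.any(np.diff(cuts) < 0):
        raise ValueError("cutoffs must be non-negative and sorted")
    rows = []
    for c in cuts:
        bi1 = np.array([classify_cutoff(v, c) == BLD for v in x])
        prop1 = float(bi1.mean()) if len(x) else float("nan")
        if bi1.any():
            rep = float(np.array(
                [classify_cutoff(v, c) == BLD for v in y[bi1]]).mean())
        else:
            rep = float("nan")
        rows.append({"cutoff": float(c),
                     "prop_bilateral_session1": prop1,
                     "prop_bilateral_replicated": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def t_test(x, y, paired: bool = False, alternative: str = "two-sided") -> TTestResult:
    """Welch two-sample t-test (unpaired) or paired t-test.

    Welch uses the Satterthwaite degrees of freedom; the paired test uses
    n-1.  Zero-variance inputs where the statistic is undefined raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("paired test needs equal lengths >= 2")
        diffs = x - y
        if diffs.std(ddof=1) == 0:
            raise ValueError("zero-variance differences: paired t undefined")
        res = stats.ttest_rel(x, y, alternative=alternative)
        return TTestResult(float(res.statistic), float(len(x) - 1), float(res.pvalue))
    if len(x) < 2 or len(y) < 2:
        raise ValueError("unpaired test needs >= 2 observations per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups: Welch t undefined")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def _mw_z(x: np.ndarray, y: np.ndarray, u1: float, alternative: str) -> float:
    """Normal-approximation z for the Mann-Whitney U of the first sample,
    with tie correction and a continuity correction of 0.5 in the
    direction of the alternative."""
    n1, n2 = len(x), len(y)
    nt = n1 + n2
    mu = n1 * n2 / 2.0
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (nt * (nt - 1)) if nt > 1 else 0.0
    var = n1 * n2 / 12.0 * ((nt + 1) - tie_term)
    if var <= 0:
        return 0.0
    if alternative == "greater":
        return (u1 - mu - 0.5) / math.sqrt(var)
    if alternative == "less":
        return (u1 - mu + 0.5) / math.sqrt(var)
    # two-sided: shift toward the null
    cc = 0.5 if u1 > mu else (-0.5 if u1 < mu else 0.0)
    return (u1 - mu - cc) / math.sqrt(var)


def mann_whitney_onesided(x, y, alternative: str = "less") -> RankTestResult:
    """Mann-Whitney U test with the statistic of the first sample
    (R's ``W`` convention) and effect size r = |z| / sqrt(n1 + n2).

    The p-value is computed by exact enumeration when the samples are
    small (min(n1, n2) <= 8 and n1 + n2 <= 20) and tie-free; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    small = min(n1, n2) <= 8 and n1 + n2 <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=True)
    u1 = float(res.statistic)
    z = _mw_z(x, y, u1, alternative)
    effect_r = abs(z) / math.sqrt(n1 + n2)
    return RankTestResult(u1, float(res.pvalue), float(effect_r), float(z))


def spearman_rho(x, y) -> tuple:
    """Spearman rank correlation with average ranks for ties; p from the
    t approximation.  Constant input yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal lengths >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
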