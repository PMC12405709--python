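"""Statistical toolkit for the decoding analysis.

Rank-based ROC AUC, the Friedman repeated-measures test with Kendall's
coefficient of concordance w = chi2 / (n (k - 1)), Tukey-style post-hoc
rank comparisons, and Bonferroni-corrected -log10(p) significance
thresholds.  Everything is nonparametric, matching the analysis design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

#: Cohen-style interpretation bands for Kendall's w
EFFECT_BANDS = ((0.5, "large"), (0.3, "moderate"), (0.1, "small"))


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with average ranks on ties.

    Equals P(score+ > score-) + 0.5 P(score+ = score-); 0.5 is chance,
    1.0 perfect separation of the +1 class above the -1 class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == np.max(labels)
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = sps.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def kendalls_w(chi2: float, n: int, k: int) -> float:
    """Kendall's coefficient of concordance, w = chi2 / (n (k - 1))."""
    if n < 1 or k < 2:
        raise ValueError("need n >= 1 subjects and k >= 2 conditions")
    if chi2 < 0:
        raise ValueError("chi2 must be non-negative")
    return float(np.clip(chi2 / (n * (k - 1)), 0.0, 1.0))


def effect_label(w: float) -> str:
    for cut, label in EFFECT_BANDS:
        if w >= cut:
            return label
    return "negligible"


def bonferroni_neglog(alpha: float = 0.05, m: int = 19) -> float:
    """-log10 of the Bonferroni-corrected significance level alpha/m."""
    if not (0 < alpha < 1) or m < 1:
        raise ValueError("alpha in (0,1) and m >= 1 required")
    return float(-np.log10(alpha / m))


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    n: int
    k: int
    w: float
    posthoc: np.ndarray = field(default=None)   # k x k pairwise p-values

    def to_dict(self) -> dict:
        pairs = []
        if self.posthoc is not None:
            for i in range(self.k):
                for j in range(i + 1, self.k):
                    pairs.append({"pair": [i, j],
                                  "p": float(self.posthoc[i, j])})
        return {"chi2": self.chi2, "df": self.df, "p": self.p,
                "n": self.n, "k": self.k, "w": round(self.w, 2),
                "effect_label": effect_label(self.w), "posthoc": pairs}


def friedman(data, with_posthoc: bool = True) -> FriedmanResult:
    """Friedman repeated-measures test on an n-subjects x k-conditions table.

    Within-subject average ranks; the chi-square statistic uses the
    standard tie-corrected denominator.  Degenerate all-tied data returns
    chi2 = 0, p = 1.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be subjects x conditions")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need n >= 2 subjects and k >= 2 conditions")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported")

    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    rsum = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rsum ** 2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts ** 3 - counts)
    denom = 1.0 - ties / (n * k * (k ** 2 - 1))
    if denom <= 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = chi2 / denom
        p = float(sps.chi2.sf(chi2, k - 1))
    res = FriedmanResult(float(chi2), k - 1, p, n, k,
                         kendalls_w(float(chi2), n, k))
    if with_posthoc:
        res.posthoc = posthoc_ranks(x)
    return res


def posthoc_ranks(data) -> np.ndarray:
    """Tukey-style pairwise comparison of mean within-subject ranks.

    q = |mean-rank difference| / SE with SE = sqrt(k (k + 1) / (12 n)),
    referred to the studentized-range distribution (infinite df).
    Returns a symmetric k x k matrix of p-values with unit diagonal.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if k < 2:
        raise ValueError("need k >= 2 conditions")
    mean_ranks = np.apply_along_axis(sps.rankdata, 1, x).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(mean_ranks[i] - mean_ranks[j]) / se
            pij = float(np.clip(sps.studentized_range.sf(q, k, np.inf),
                                0.0, 1.0))
            p[i, j] = p[j, i] = pij
    return p
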