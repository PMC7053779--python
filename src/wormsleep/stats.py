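"""Hypothesis tests used across the trial analysis.

* Paired comparisons (the same worms before vs during stimulation) use the
  Wilcoxon signed-rank test.  For n <= 25 informative pairs the null
  distribution is enumerated exactly via a generating-function convolution
  over the (doubled, so tie-midranks stay integral) ranks; above that a
  normal approximation with continuity and tie corrections is used.  Zero
  differences are dropped (Wilcoxon's convention).
* Sleep fractions (pooled quiescent/mobile frame counts) are compared with
  Fisher's exact test (scipy's hypergeometric two-sided rule).
* Between-strain comparisons gate on Shapiro-Wilk normality of both samples
  at alpha = 0.05: Welch's t if both pass, two-sample Kolmogorov-Smirnov
  otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .types import StatResult

__all__ = ["wilcoxon_signed_rank", "fisher_exact_2x2", "compare_groups"]

_EXACT_MAX_N = 25


def wilcoxon_signed_rank(differences) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired differences."""
    d = np.asarray(differences, float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a 1-D vector of at least 2 paired differences")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        return StatResult("wilcoxon_signed_rank", 0.0, 1.0, 0, exact=True,
                          degenerate=True, detail={"note": "all differences zero"})
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if n <= _EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w_plus)
        exact = True
        method = "exact_enumeration"
    else:
        p = _normal_approx_p(ranks, w_plus, n)
        exact = False
        method = "normal_approximation"
    return StatResult("wilcoxon_signed_rank", w_plus, p, n, exact=exact,
                      detail={"method": method, "n_zeros": int(d.size - n)})


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    # doubled ranks are integers even with .5 midranks
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    coef = np.zeros(total + 1)
    coef[0] = 1.0
    for r in r2:
        coef[r:] += coef[:-r] if r > 0 else coef
    coef /= coef.sum()
    w2 = int(round(2 * w_plus))
    p_le = float(coef[: w2 + 1].sum())
    p_ge = float(coef[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_approx_p(ranks: np.ndarray, w_plus: float, n: int) -> float:
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        return 1.0
    diff = w_plus - mu
    # continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return StatResult("fisher_exact", float(odds), float(p), int(t.sum()),
                      exact=True, detail={"table": t.tolist()})


def compare_groups(sample_a, sample_b, alpha: float = 0.05) -> StatResult:
    """Two-sample comparison with a normality gate.

    Shapiro-Wilk runs on each sample; if both look normal (p > alpha) the
    samples are compared with Welch's unequal-variance t test, otherwise
    with the two-sample Kolmogorov-Smirnov test.  Constant samples cannot be
    assessed by Shapiro-Wilk and route to the KS branch.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    normal = True
    shapiro_ps = []
    for s in (a, b):
        if np.ptp(s) < 1e-12:
            normal = False
            shapiro_ps.append(float("nan"))
            continue
        sw = sps.shapiro(s)
        shapiro_ps.append(float(sw.pvalue))
        if sw.pvalue <= alpha:
            normal = False
    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return StatResult("welch_t", float(res.statistic), float(res.pvalue),
                          int(a.size + b.size),
                          detail={"branch": "welch", "shapiro_p": shapiro_ps})
    res = sps.ks_2samp(a, b, alternative="two-sided")
    return StatResult("kolmogorov_smirnov", float(res.statistic),
                      float(res.pvalue), int(a.size + b.size),
                      detail={"branch": "ks", "shapiro_p": shapiro_ps})
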