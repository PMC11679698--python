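"""Cross-biomonitor comparison: paired tests and major-axis (Model II) regression.

When two co-located biomonitors (e.g., leaves and transplanted lichens) are
compared, neither variable is an error-free predictor, so ordinary (Model I)
regression is inappropriate. The major axis — the first principal axis of the
2×2 covariance matrix — treats the variables symmetrically:

    slope = (s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy)

Significance of the association is assessed by permuting one variable
(statistic |r|). Whether the slope differs from 1 is assessed by randomly
swapping the coordinates within pairs, which is exchangeable under the
symmetry (slope = 1) null: the major-axis slope equals 1 exactly when
cov(y − x, y + x) = s_yy − s_xx = 0, so the statistic is |corr(y − x, y + x)|,
and a within-pair swap simply flips the sign of y − x while leaving y + x
unchanged. Both permutation p-values use the (count + 1)/(n_perm + 1)
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedEfComparison",
    "MaRegressionResult",
    "paired_ef_test",
    "major_axis_regression",
    "ma_permutation_tests",
    "compare_biomonitors",
]


@dataclass
class PairedEfComparison:
    element: str
    n_pairs: int
    route: str                       # 't_test' | 'wilcoxon'
    statistic: float
    p_two_sided: float
    direction: str                   # 'biomonitor_a_higher' | 'biomonitor_b_higher' | 'none'


@dataclass
class MaRegressionResult:
    element: str
    n_pairs: int
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    p_association: float | None = None
    p_slope_ne_1: float | None = None
    n_permutations: int | None = None
    seed: int | None = None


def paired_ef_test(ef_a: np.ndarray, ef_b: np.ndarray, alpha: float = 0.05,
                   element: str = "") -> PairedEfComparison:
    """Paired comparison of two biomonitors' per-site values for one element.

    Routed to a paired t-test when both samples pass Shapiro–Wilk normality at
    ``alpha``, otherwise to the Wilcoxon signed-rank test with Pratt handling
    of zero differences. Direction is the sign of the median difference.
    """
    a = np.asarray(ef_a, dtype=float)
    b = np.asarray(ef_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    n = a.size
    if n < 6:
        raise ValueError("need at least 6 complete pairs")
    d = a - b
    med = float(np.median(d))
    direction = ("none" if med == 0
                 else "biomonitor_a_higher" if med > 0 else "biomonitor_b_higher")
    if np.all(d == 0):
        return PairedEfComparison(element, n, "wilcoxon", 0.0, 1.0, "none")
    normal = (np.ptp(a) > 0 and np.ptp(b) > 0
              and stats.shapiro(a).pvalue >= alpha
              and stats.shapiro(b).pvalue >= alpha)
    if normal:
        res = stats.ttest_rel(a, b)
        return PairedEfComparison(element, n, "t_test",
                                  float(res.statistic), float(res.pvalue), direction)
    res = stats.wilcoxon(a, b, zero_method="pratt")
    return PairedEfComparison(element, n, "wilcoxon",
                              float(res.statistic), float(res.pvalue), direction)


def _ma_slope_from_moments(sxx: float, syy: float, sxy: float) -> float:
    if sxy == 0.0:
        if sxx == syy:
            raise ValueError("isotropic point cloud: major-axis slope undefined")
        return 0.0 if sxx > syy else np.inf
    return (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4.0 * sxy**2)) / (2.0 * sxy)


def major_axis_regression(x: np.ndarray, y: np.ndarray,
                          alpha: float = 0.05, element: str = "") -> MaRegressionResult:
    """Major-axis regression of y on x (symmetric in the two variables).

    The slope is the direction of the dominant eigenvector of the sample
    covariance matrix; swapping x and y maps it to its reciprocal. The
    confidence interval uses the standard angular method: the half-width of
    the CI of the major-axis angle derives from H = F·l₁l₂/((n−2)(l₁−l₂)²)
    with l₁ ≥ l₂ the covariance eigenvalues; limits are tan(θ ± arctan√(H/(1−H))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need n >= 3 equal-length samples")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxx + syy == 0.0:
        raise ValueError("degenerate data: zero total variance")
    slope = _ma_slope_from_moments(sxx, syy, sxy)
    intercept = float(np.mean(y) - slope * np.mean(x)) if np.isfinite(slope) else np.nan
    # angular CI
    tr, det = sxx + syy, sxx * syy - sxy**2
    disc = np.sqrt(max(tr**2 / 4.0 - det, 0.0))
    l1, l2 = tr / 2.0 + disc, tr / 2.0 - disc
    if l1 == l2:
        ci = (-np.inf, np.inf)
    else:
        F = stats.f.ppf(1.0 - alpha, 1, n - 2)
        H = F * l1 * l2 / ((n - 2) * (l1 - l2) ** 2)
        if H >= 1.0:
            ci = (-np.inf, np.inf)
        else:
            theta = np.arctan(slope) if np.isfinite(slope) else np.pi / 2.0
            phi = np.arctan(np.sqrt(H / (1.0 - H)))
            lo, hi = theta - phi, theta + phi
            if lo < -np.pi / 2 or hi > np.pi / 2:
                ci = (-np.inf, np.inf)       # interval wraps through vertical
            else:
                ci = (float(np.tan(lo)), float(np.tan(hi)))
    return MaRegressionResult(element, n, float(slope), intercept, ci)


def ma_permutation_tests(x: np.ndarray, y: np.ndarray, n_perm: int = 999,
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> dict[str, float]:
    """Permutation p-values for the major-axis regression.

    ``p_association``: y permuted against x, null distribution of |Pearson r|.
    ``p_slope_ne_1``: within-pair coordinate swaps (valid under the slope = 1
    symmetry null), two-sided via |corr(y − x, y + x)|, which is zero exactly
    when the major-axis slope is 1. Results are reproducible given
    (n_perm, seed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 6 or y.size != n:
        raise ValueError("need at least 6 pairs")
    rng = np.random.default_rng(seed) if rng is None else rng

    def _absr(a, b):
        return abs(float(np.corrcoef(a, b)[0, 1]))

    obs_r = _absr(x, y)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    Yp = y[perm_idx]
    xc = x - x.mean()
    yc = Yp - Yp.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
    perm_r = np.abs(num / den)
    p_assoc = (1.0 + np.sum(perm_r >= obs_r - 1e-12)) / (n_perm + 1.0)

    # slope = 1 iff cov(y − x, y + x) = 0; a within-pair swap flips the sign
    # of d = y − x and fixes s = y + x, so sign-flip the centred d.
    d = y - x
    s_ = y + x
    if np.ptp(d) == 0 or np.ptp(s_) == 0:
        p_slope = 1.0
    else:
        obs_t = _absr(d, s_)
        signs = np.where(rng.random((n_perm, n)) < 0.5, 1.0, -1.0)
        D = signs * d
        dc = D - D.mean(axis=1, keepdims=True)
        sc = s_ - s_.mean()
        num_d = dc @ sc
        den_d = np.sqrt((dc**2).sum(axis=1) * (sc**2).sum())
        perm_t = np.abs(num_d / den_d)
        p_slope = (1.0 + np.sum(perm_t >= obs_t - 1e-12)) / (n_perm + 1.0)
    return {"p_association": float(p_assoc), "p_slope_ne_1": float(p_slope)}


def compare_biomonitors(ef_a: pd.DataFrame, ef_b: pd.DataFrame,
                        elements: list[str] | None = None, n_perm: int = 999,
                        seed: int | None = None, alpha: float = 0.05) -> pd.DataFrame:
    """Element-wise comparison of two site×element EF matrices.

    Runs the paired normality-routed test and the major-axis regression with
    both permutation tests on the common sites of each element. Returns a tidy
    table (one row per element).
    """
    common = ef_a.index.intersection(ef_b.index)
    elements = elements or [e for e in ef_a.columns if e in ef_b.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for el in elements:
        a = ef_a.loc[common, el].to_numpy(dtype=float)
        b = ef_b.loc[common, el].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if a.size < 6:
            warnings.warn(f"{el}: fewer than 6 complete pairs; skipped")
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            # e.g. the normalizing element, whose EF is identically 1
            warnings.warn(f"{el}: degenerate (constant) EFs; skipped")
            continue
        paired = paired_ef_test(a, b, alpha=alpha, element=el)
        ma = major_axis_regression(a, b, alpha=alpha, element=el)
        perm = ma_permutation_tests(a, b, n_perm=n_perm, rng=rng)
        rows.append({
            "element": el, "n": int(a.size),
            "slope": ma.slope, "intercept": ma.intercept,
            "ci_lo": ma.slope_ci95[0], "ci_hi": ma.slope_ci95[1],
            "p_association": perm["p_association"],
            "p_slope_ne_1": perm["p_slope_ne_1"],
            "route": paired.route, "p_paired": paired.p_two_sided,
            "direction": paired.direction,
        })
    return pd.DataFrame(rows)
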