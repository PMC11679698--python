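"""PCA-based source apportionment with sampling-adequacy screening.

The procedure mirrors the standard receptor-oriented workflow for elemental
biomonitoring data:

1. Spearman rank correlations as an exploratory screen of bivariate relations.
2. Bartlett's sphericity test on the Pearson correlation matrix.
3. Iterative elimination of variables whose per-variable measure of sampling
   adequacy (MSA, the diagonal of the anti-image correlation matrix) falls
   below a threshold (default 0.5), with an optional keep-list override.
4. Overall Kaiser–Meyer–Olkin (KMO) adequacy statistic.
5. PCA of the correlation matrix, retaining components with eigenvalue > 1,
   followed by varimax rotation with Kaiser (row) normalization; loadings
   above a threshold (default 0.5) assign an element to a source.

KMO/MSA derive from partial correlations computed through the inverse of the
correlation matrix: with Q = R⁻¹, the partial correlation between variables i
and j given all others is −Q_ij / √(Q_ii·Q_jj).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .survey import ElementalSurvey

__all__ = [
    "CorrelationScreen",
    "PcaSolution",
    "spearman_screen",
    "bartlett_sphericity",
    "anti_image_msa",
    "msa_eliminate",
    "kmo",
    "varimax",
    "varimax_criterion",
    "pca_varimax",
    "apportion",
    "communalities_from_loadings",
]


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

@dataclass
class CorrelationScreen:
    method: str
    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: float = 0.05

    def significant_pairs(self) -> pd.DataFrame:
        rows = []
        els = list(self.rho.index)
        for i, a in enumerate(els):
            for b in els[i + 1:]:
                if self.p.loc[a, b] < self.alpha:
                    rows.append((a, b, self.rho.loc[a, b], self.p.loc[a, b]))
        return pd.DataFrame(rows, columns=["element_a", "element_b", "rho", "p"])


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho (full enumeration)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    pm_c = perms - ry.mean()
    num = pm_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (pm_c**2).sum(axis=1))
    rhos = np.abs(num / den)
    return float(np.mean(rhos >= obs - 1e-12))


def spearman_screen(survey: ElementalSurvey | pd.DataFrame,
                    alpha: float = 0.05) -> CorrelationScreen:
    """Pairwise Spearman correlations over exposure sites.

    Average ranks for ties; two-sided p-values use the t approximation for
    n ≥ 10 and exact rank-permutation enumeration for smaller n. Constant
    columns yield undefined correlations (NaN) with a warning.
    """
    mat = survey.exposure if isinstance(survey, ElementalSurvey) else survey
    if len(mat) < 3:
        raise ValueError("need at least 3 sites for a correlation screen")
    cols = list(mat.columns)
    X = mat.to_numpy(dtype=float)
    n = X.shape[0]
    const = [c for j, c in enumerate(cols) if np.ptp(X[:, j]) == 0]
    if const:
        warnings.warn(f"constant columns, correlation undefined: {const}")
    rho = np.full((len(cols), len(cols)), np.nan)
    p = np.full_like(rho, np.nan)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    for i, j in itertools.combinations(range(len(cols)), 2):
        if cols[i] in const or cols[j] in const:
            continue
        if n >= 10:
            r, pv = stats.spearmanr(X[:, i], X[:, j])
        else:
            r = stats.spearmanr(X[:, i], X[:, j]).statistic
            pv = _spearman_exact_p(X[:, i], X[:, j])
        rho[i, j] = rho[j, i] = r
        p[i, j] = p[j, i] = pv
    return CorrelationScreen("spearman",
                             pd.DataFrame(rho, index=cols, columns=cols),
                             pd.DataFrame(p, index=cols, columns=cols),
                             alpha)


# ---------------------------------------------------------------------------
# adequacy statistics
# ---------------------------------------------------------------------------

def _as_corr_array(corr) -> tuple[np.ndarray, list[str]]:
    if isinstance(corr, pd.DataFrame):
        return corr.to_numpy(dtype=float), list(corr.columns)
    arr = np.asarray(corr, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def bartlett_sphericity(corr, n: int) -> dict[str, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = −(n − 1 − (2p + 5)/6)·ln|R| with p(p−1)/2 degrees of freedom.
    """
    R, _ = _as_corr_array(corr)
    p = R.shape[0]
    if n <= p:
        raise ValueError("need more observations than variables")
    sign, logdet = np.linalg.slogdet(R)
    df = p * (p - 1) // 2
    if sign <= 0 or not np.isfinite(logdet):
        warnings.warn("singular correlation matrix; sphericity p-value set to 0")
        return {"chi2": np.inf, "df": df, "p": 0.0}
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    return {"chi2": float(chi2), "df": df, "p": float(stats.chi2.sf(chi2, df))}


def _partial_correlations(R: np.ndarray) -> np.ndarray:
    Q = np.linalg.inv(R)
    d = np.sqrt(np.diag(Q))
    P = -Q / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return P


def anti_image_msa(corr) -> pd.Series:
    """Per-variable MSA (diagonal of the anti-image correlation matrix)."""
    R, names = _as_corr_array(corr)
    P = _partial_correlations(R)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.where(off, R**2, 0.0).sum(axis=1)
    p2 = np.where(off, P**2, 0.0).sum(axis=1)
    den = r2 + p2
    # orthogonal variable: MSA undefined (0/0); report NaN, never auto-dropped
    vals = np.divide(r2, den, out=np.full_like(den, np.nan), where=den > 0)
    return pd.Series(vals, index=names)


def kmo(corr) -> float:
    """Overall Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = Σ r²_ij / (Σ r²_ij + Σ q²_ij) over off-diagonal cells, where q are
    partial correlations. For two variables the partial correlation equals the
    correlation, so KMO is exactly 0.5.
    """
    R, _ = _as_corr_array(corr)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular correlation matrix")
    P = _partial_correlations(R)
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R[off] ** 2).sum()
    p2 = (P[off] ** 2).sum()
    return float(r2 / (r2 + p2))


def msa_eliminate(corr, msa_threshold: float = 0.5,
                  keep: tuple[str, ...] = ()) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop the lowest-MSA variable until all MSA ≥ threshold.

    The MSA vector is recomputed after each removal. Variables in ``keep`` are
    never dropped (used when a low-MSA variable is retained on substantive
    grounds). Returns (retained variables, [(dropped variable, MSA at drop)]).
    """
    R, names = _as_corr_array(corr)
    frame = pd.DataFrame(R, index=names, columns=names)
    retained = list(names)
    dropped: list[tuple[str, float]] = []
    while True:
        msa = anti_image_msa(frame.loc[retained, retained])
        candidates = msa[(msa < msa_threshold) & ~msa.index.isin(keep)]
        if candidates.empty:
            return retained, dropped
        if len(retained) <= 3:
            raise ValueError("insufficient variables for PCA")
        worst = candidates.idxmin()
        dropped.append((worst, float(candidates[worst])))
        retained.remove(worst)


# ---------------------------------------------------------------------------
# varimax rotation and PCA
# ---------------------------------------------------------------------------

def varimax_criterion(A: np.ndarray) -> float:
    """Raw varimax criterion: sum over components of the variance of squared loadings."""
    sq = A**2
    p = A.shape[0]
    return float((sq**2).sum(axis=0).sum() / p - ((sq.sum(axis=0) / p) ** 2).sum())


def varimax(loadings: np.ndarray, kaiser: bool = True, tol: float = 1e-9,
            max_sweeps: int = 1000) -> tuple[np.ndarray, int]:
    """Varimax rotation by pairwise planar rotations.

    With ``kaiser`` the rows are normalized to unit communality before
    rotation and rescaled afterwards. Stops when a full sweep increases the
    (normalized) criterion by less than ``tol``, or after ``max_sweeps`` sweeps
    (then a warning is issued). Returns (rotated loadings, sweeps used).
    """
    A = np.asarray(loadings, dtype=float).copy()
    p, m = A.shape
    if m < 2:
        return A, 0
    h = np.sqrt((A**2).sum(axis=1))
    if kaiser:
        safe = np.where(h > 0, h, 1.0)
        A = A / safe[:, None]
    crit = varimax_criterion(A)
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        for k, l in itertools.combinations(range(m), 2):
            x, y = A[:, k], A[:, l]
            u = x**2 - y**2
            v = 2.0 * x * y
            num = 2.0 * (p * (u * v).sum() - u.sum() * v.sum())
            den = p * ((u**2 - v**2).sum()) - (u.sum() ** 2 - v.sum() ** 2)
            phi = 0.25 * np.arctan2(num, den)
            if abs(phi) < 1e-15:
                continue
            c, s = np.cos(phi), np.sin(phi)
            A[:, k], A[:, l] = c * x + s * y, -s * x + c * y
        new = varimax_criterion(A)
        if new - crit < tol:
            crit = new
            break
        crit = new
    else:
        warnings.warn(f"varimax did not converge in {max_sweeps} sweeps")
    if kaiser:
        A = A * np.where(h > 0, h, 1.0)[:, None]
    # deterministic sign: largest-magnitude loading of each component positive
    for k in range(m):
        if A[np.argmax(np.abs(A[:, k])), k] < 0:
            A[:, k] = -A[:, k]
    return A, sweeps


def communalities_from_loadings(loadings) -> pd.Series:
    """Per-variable communality: the row sum of squared loadings."""
    if isinstance(loadings, pd.DataFrame):
        return (loadings**2).sum(axis=1)
    arr = np.asarray(loadings, dtype=float)
    return pd.Series((arr**2).sum(axis=1))


@dataclass
class PcaSolution:
    """Rotated PCA solution with adequacy bookkeeping."""

    retained_variables: list[str]
    dropped_variables: list[tuple[str, float]]
    kmo: float | None
    bartlett_chi2: float | None
    bartlett_df: int | None
    bartlett_p: float | None
    eigenvalues: np.ndarray
    n_components: int
    rotated_loadings: pd.DataFrame          # variable × component
    communalities: pd.Series
    explained_variance_pct: list[float]     # per rotated component
    assignments: dict[str, list[str]] = field(default_factory=dict)
    loading_threshold: float = 0.5

    @property
    def total_variance_pct(self) -> float:
        """Total variance explained by the retained components (percent)."""
        return float(sum(self.explained_variance_pct))

    @classmethod
    def from_loadings(cls, loadings: pd.DataFrame,
                      explained_variance_pct: list[float] | None = None,
                      loading_threshold: float = 0.5) -> "PcaSolution":
        """Build a solution from a reported rotated loading matrix.

        Useful for auditing published loading tables: communalities,
        assignments and variance totals are recomputed from the loadings. When
        per-component percentages are not given they are derived from the
        rotated sums of squares.
        """
        comm = communalities_from_loadings(loadings)
        p = loadings.shape[0]
        if explained_variance_pct is None:
            explained_variance_pct = list((loadings**2).sum(axis=0) / p * 100.0)
        assignments = {
            str(c): [v for v in loadings.index if abs(loadings.loc[v, c]) > loading_threshold]
            for c in loadings.columns
        }
        return cls(
            retained_variables=list(loadings.index),
            dropped_variables=[],
            kmo=None, bartlett_chi2=None, bartlett_df=None, bartlett_p=None,
            eigenvalues=np.array([]),
            n_components=loadings.shape[1],
            rotated_loadings=loadings,
            communalities=comm,
            explained_variance_pct=[float(x) for x in explained_variance_pct],
            assignments=assignments,
            loading_threshold=loading_threshold,
        )

    def to_table(self) -> pd.DataFrame:
        tab = self.rotated_loadings.copy()
        tab["communality"] = self.communalities
        return tab


def pca_varimax(data: pd.DataFrame, eigen_cut: float = 1.0,
                loading_threshold: float = 0.5, max_sweeps: int = 1000) -> PcaSolution:
    """Correlation-matrix PCA with varimax/Kaiser rotation of eigenvalue>cut components.

    ``data`` is a site×variable matrix (elements are z-scored internally, so
    concentration scales spanning orders of magnitude are handled). Explained
    variance per component is recomputed after rotation as the column sum of
    squared loadings over the number of variables; components are reported in
    decreasing order of rotated variance.
    """
    cols = list(data.columns)
    n, p = data.shape
    if n <= p:
        warnings.warn(f"fewer sites ({n}) than recommended for {p} variables")
    R = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    eig, vec = np.linalg.eigh(R)
    order = np.argsort(eig)[::-1]
    eig, vec = eig[order], vec[:, order]
    m = int(np.sum(eig > eigen_cut))
    if m == 0:
        raise ValueError(f"no eigenvalue exceeds {eigen_cut}")
    load = vec[:, :m] * np.sqrt(eig[:m])
    rot, _ = varimax(load, kaiser=True, max_sweeps=max_sweeps)
    ssq = (rot**2).sum(axis=0)
    comp_order = np.argsort(ssq)[::-1]
    rot = rot[:, comp_order]
    ssq = ssq[comp_order]
    comp_names = [f"PC{i + 1}" for i in range(m)]
    L = pd.DataFrame(rot, index=cols, columns=comp_names)
    assignments = {
        c: [v for v in cols if abs(L.loc[v, c]) > loading_threshold]
        for c in comp_names
    }
    return PcaSolution(
        retained_variables=cols,
        dropped_variables=[],
        kmo=None, bartlett_chi2=None, bartlett_df=None, bartlett_p=None,
        eigenvalues=eig,
        n_components=m,
        rotated_loadings=L,
        communalities=communalities_from_loadings(L),
        explained_variance_pct=[float(s / p * 100.0) for s in ssq],
        assignments=assignments,
        loading_threshold=loading_threshold,
    )


def apportion(survey: ElementalSurvey | pd.DataFrame, msa_threshold: float = 0.5,
              keep: tuple[str, ...] = (), eigen_cut: float = 1.0,
              loading_threshold: float = 0.5, max_sweeps: int = 1000) -> PcaSolution:
    """Full screening + PCA procedure on exposure-site concentrations.

    Runs anti-image MSA elimination on the Pearson correlation matrix, then
    Bartlett/KMO adequacy statistics on the retained set, then the rotated PCA.
    """
    mat = survey.exposure if isinstance(survey, ElementalSurvey) else survey
    R = mat.corr(method="pearson")
    retained, dropped = msa_eliminate(R, msa_threshold, keep=keep)
    sub = mat[retained]
    bart = bartlett_sphericity(sub.corr(), n=len(sub))
    adequacy = kmo(sub.corr())
    sol = pca_varimax(sub, eigen_cut=eigen_cut,
                      loading_threshold=loading_threshold, max_sweeps=max_sweeps)
    sol.dropped_variables = dropped
    sol.kmo = adequacy
    sol.bartlett_chi2 = bart["chi2"]
    sol.bartlett_df = int(bart["df"])
    sol.bartlett_p = bart["p"]
    return sol
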