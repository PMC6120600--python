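"""Behavioural battery reduction: percentage scoring, PCA with varimax
rotation, regression-method factor scores, outlier flags and the power rule.

The battery is reduced with principal component analysis on the task
correlation matrix (tasks live on heterogeneous percentage scales, so the
covariance matrix would let high-variance tasks dominate).  Components with
eigenvalue > 1 are retained and rotated with varimax under Kaiser row
normalization; per-patient scores use the regression method, which for PCA
yields exactly orthogonal, unit-variance score columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "to_percent",
    "varimax",
    "BehavioralPCA",
    "FactorModelResults",
    "pca_varimax",
    "flag_outlier_scores",
    "min_n_for_correlation",
]


def to_percent(
    raw: float | np.ndarray,
    maximum: float | None = None,
    group_scores: np.ndarray | None = None,
) -> float | np.ndarray:
    """Convert raw task scores to percentage of the attainable maximum.

    Uses the test's published maximum when available; otherwise falls back
    to the maximum score observed in the group (so the best performer maps
    to 100).
    """
    raw = np.asarray(raw, dtype=float)
    if maximum is None:
        if group_scores is None:
            raise ValueError("need either a test maximum or group scores")
        maximum = float(np.max(group_scores))
    if maximum <= 0:
        raise ValueError("maximum must be positive")
    if np.any(raw > maximum + 1e-12):
        raise ValueError("raw score exceeds the test maximum")
    out = 100.0 * raw / maximum
    return float(out) if out.ndim == 0 else out


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings within each factor column,
    over orthogonal rotations.  With Kaiser normalization (the SPSS
    default) rows are scaled to unit communality before rotation and
    rescaled after, so every task weighs equally in the criterion.

    Returns ``(rotated_loadings, rotation)`` with
    ``rotated = loadings @ rotation`` and ``rotation`` orthogonal.
    """
    A = np.asarray(loadings, dtype=float)
    p, k = A.shape
    if k < 2:
        return A.copy(), np.eye(k)
    if kaiser_normalize:
        h = np.sqrt((A**2).sum(axis=1))
        if (h == 0).any():
            raise ValueError("zero-communality row cannot be Kaiser-normalized")
        L = A / h[:, None]
    else:
        h = None
        L = A.copy()
    # classic pairwise (Jacobi-style) sweeps: for each factor pair, the
    # planar angle maximizing the criterion has the closed form below;
    # robust where gradient methods stall at symmetric saddle points
    R = np.eye(k)
    for _ in range(max_iter):
        max_angle = 0.0
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = L[:, a], L[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                if num == 0.0 and den == 0.0:
                    continue
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-12:
                    continue
                max_angle = max(max_angle, abs(phi))
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                L[:, [a, b]] = L[:, [a, b]] @ rot
                R[:, [a, b]] = R[:, [a, b]] @ rot
        if max_angle < tol**0.5 * 1e-3:  # ~1e-9 radians
            break
    rotated = L * h[:, None] if h is not None else L
    return rotated, R


@dataclass
class FactorModelResults:
    """Fitted factor structure of a behavioural battery.

    Attributes
    ----------
    loadings : DataFrame (tasks x k)
        Varimax-rotated component loadings, sign-aligned so each factor's
        largest-magnitude loading is positive, ordered by explained
        variance.
    eigenvalues : ndarray
        All eigenvalues of the task correlation matrix, descending.
    rotation : ndarray (k x k)
        Orthogonal rotation applied to the retained components.
    scores : DataFrame (patients x k)
        Regression-method factor scores (mean 0, SD 1, mutually
        uncorrelated).
    score_coefficients : DataFrame (tasks x k)
        Weights mapping standardized task scores to factor scores.
    """

    loadings: pd.DataFrame
    eigenvalues: np.ndarray
    rotation: np.ndarray
    scores: pd.DataFrame
    score_coefficients: pd.DataFrame
    n_retained: int
    eig_threshold: float
    warnings: list[str] = field(default_factory=list)

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1).rename("communality")

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        """Share of total (task-count) variance per retained factor."""
        return (self.loadings.to_numpy() ** 2).sum(axis=0) / len(self.loadings)

    def flag_outliers(self, k_sd: float = 3.0) -> pd.Series:
        """Patients with any factor score beyond ``k_sd`` SDs of its column."""
        return flag_outlier_scores(self.scores, k_sd=k_sd)

    def summary(self) -> str:
        lines = [
            "Behavioural PCA (varimax-rotated, regression scores)",
            f"  patients: {len(self.scores)}   tasks: {len(self.loadings)}",
            f"  retained components (eigenvalue > {self.eig_threshold:g}): {self.n_retained}",
            "  eigenvalues: "
            + ", ".join(f"{e:.3f}" for e in self.eigenvalues[: max(self.n_retained, 5)]),
            "  explained variance ratio: "
            + ", ".join(f"{v:.3f}" for v in self.explained_variance_ratio),
        ]
        for w in self.warnings:
            lines.append(f"  warning: {w}")
        lines.append("")
        lines.append(self.loadings.round(3).to_string())
        return "\n".join(lines)


class BehavioralPCA:
    """PCA factor model of a patients x tasks score table.

    Parameters
    ----------
    table : DataFrame or ndarray
        Percentage scores, one row per patient; no missing cells.
    eig_threshold : float
        Retain components whose correlation-matrix eigenvalue exceeds this
        (Kaiser criterion, default 1.0).
    """

    def __init__(self, table: pd.DataFrame | np.ndarray, eig_threshold: float = 1.0):
        if isinstance(table, pd.DataFrame):
            self.table = table
        else:
            arr = np.asarray(table, dtype=float)
            self.table = pd.DataFrame(
                arr, columns=[f"task_{i + 1:02d}" for i in range(arr.shape[1])]
            )
        if self.table.isna().any().any():
            raise ValueError("missing cells; impute before fitting")
        sd = self.table.std(ddof=1)
        scale = self.table.abs().max().clip(lower=1.0)
        if (sd / scale < 1e-12).any():
            raise ValueError("constant task column; drop before fitting")
        self.eig_threshold = float(eig_threshold)

    def fit(self) -> FactorModelResults:
        X = self.table.to_numpy(dtype=float)
        n, p = X.shape
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        R = np.corrcoef(X, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(R)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]

        k = int((eigvals > self.eig_threshold).sum())
        warnings: list[str] = []
        if k < 2:
            warnings.append(
                f"only {k} component(s) above eigenvalue {self.eig_threshold:g}; "
                "degenerate structure"
            )
            k = max(k, 1)
        if n <= k:
            raise ValueError("need more patients than retained components")

        A = eigvecs[:, :k] * np.sqrt(eigvals[:k])  # unrotated loadings
        rotated, rot = varimax(A) if k >= 2 else (A.copy(), np.eye(k))

        # sign: largest-|loading| per factor positive; order by SS loadings
        signs = np.ones(k)
        for j in range(k):
            i = np.argmax(np.abs(rotated[:, j]))
            if rotated[i, j] < 0:
                signs[j] = -1.0
        rotated *= signs
        rot = rot * signs
        col_order = np.argsort(-(rotated**2).sum(axis=0))
        rotated = rotated[:, col_order]
        rot = rot[:, col_order]

        # regression-method scores: W = R^{-1} Lambda;  F = Z W
        # (pseudo-inverse covers rank-deficient correlation matrices,
        # e.g. duplicated tasks)
        W = np.linalg.pinv(R, hermitian=True) @ rotated
        F = Z @ W

        factor_names = [f"F{j + 1}" for j in range(k)]
        tasks = list(self.table.columns)
        return FactorModelResults(
            loadings=pd.DataFrame(rotated, index=tasks, columns=factor_names),
            eigenvalues=eigvals,
            rotation=rot,
            scores=pd.DataFrame(F, index=self.table.index, columns=factor_names),
            score_coefficients=pd.DataFrame(W, index=tasks, columns=factor_names),
            n_retained=k,
            eig_threshold=self.eig_threshold,
            warnings=warnings,
        )


def pca_varimax(
    table: pd.DataFrame | np.ndarray, eig_threshold: float = 1.0
) -> FactorModelResults:
    """Functional wrapper over :class:`BehavioralPCA`."""
    return BehavioralPCA(table, eig_threshold=eig_threshold).fit()


def align_factors(
    loadings: np.ndarray | pd.DataFrame,
    reference: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Match factor columns to a reference structure up to permutation/sign.

    Factor solutions are identified only up to column order and sign.
    Greedily pairs each reference column with the estimated column of
    largest |inner product|.  Returns ``(perm, signs)`` such that
    ``loadings[:, perm] * signs`` is aligned with ``reference``.
    """
    A = np.asarray(reference, dtype=float)
    B = np.asarray(loadings, dtype=float)
    if A.shape != B.shape:
        raise ValueError("loadings and reference must have equal shapes")
    k = A.shape[1]
    C = A.T @ B  # reference x estimated inner products
    perm = np.zeros(k, dtype=int)
    signs = np.zeros(k)
    avail = C.copy()
    for _ in range(k):
        i, j = np.unravel_index(np.nanargmax(np.abs(avail)), avail.shape)
        perm[i] = j
        signs[i] = 1.0 if C[i, j] >= 0 else -1.0
        avail[i, :] = np.nan
        avail[:, j] = np.nan
    return perm, signs


def flag_outlier_scores(
    scores: pd.DataFrame | np.ndarray, k_sd: float = 3.0
) -> pd.Series:
    """Flag patients with any factor score beyond ``mean +/- k_sd * SD``.

    SDs are the sample (ddof=1) column SDs of the analyzed cohort.
    """
    if isinstance(scores, pd.DataFrame):
        index = scores.index
        arr = scores.to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(scores, dtype=float))
        index = pd.RangeIndex(1, arr.shape[0] + 1, name="patient_id")
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 patients")
    sd = arr.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance factor column")
    z = (arr - arr.mean(axis=0)) / sd
    return pd.Series((np.abs(z) > k_sd).any(axis=1), index=index, name="outlier")


def min_n_for_correlation(r: float, alpha: float = 0.01, power: float = 0.8) -> int:
    """Minimum sample size to detect correlation ``r`` (Fisher-z approximation).

        n = ((z_{1-alpha/2} + z_power) / atanh(r))^2 + 3,  rounded to nearest

    Two-sided test.  At (r=0.75, alpha=0.01, power=0.8) the formula gives
    15.34 -> 15.
    """
    if not 0 < r < 1:
        raise ValueError("effect size r must be in (0, 1)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    n = ((z_a + z_b) / np.arctanh(r)) ** 2 + 3.0
    return int(np.rint(n))
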