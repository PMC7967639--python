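"""Source apportionment by principal components with varimax rotation.

Workflow mirrors the receptor-modelling convention for airborne congener
tables: z-score the samples-by-congeners matrix, gate suitability with the
Kaiser-Meyer-Olkin (KMO) measure (> 0.5) and Bartlett's test of sphericity
(significant chi-square), extract components with eigenvalue > 1 from the
correlation matrix, and varimax-rotate the loadings with Kaiser
row-normalization.  Rotated loadings are then bucketed into the usual
interpretation strengths (heavy > 0.75, moderate 0.50-0.75, weak 0.30-0.50).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted
from statsmodels.multivariate.factor_rotation import rotate_factors

LOADING_BREAKS = (0.30, 0.50, 0.75)
LOADING_LABELS = ("none", "weak", "moderate", "heavy")


def _corr(X: np.ndarray) -> np.ndarray:
    X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column: correlation matrix undefined")
    return np.corrcoef(X, rowvar=False)


def kmo_statistic(X) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum of squared off-diagonal correlations over that sum plus the
    sum of squared off-diagonal anti-image (partial) correlations.  For any
    nondegenerate two-variable dataset the partial correlation equals the
    correlation, so KMO is exactly 0.5.

    Raises on a singular correlation matrix or when all off-diagonal
    correlations vanish (0/0 is left undefined rather than coerced to 0).
    """
    R = _corr(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or logdet < -1e12:
        raise np.linalg.LinAlgError("singular correlation matrix")
    S = np.linalg.inv(R)
    d = np.sqrt(np.outer(np.diag(S), np.diag(S)))
    partial = -S / d
    off = ~np.eye(R.shape[0], dtype=bool)
    r2 = np.sum(R[off] ** 2)
    a2 = np.sum(partial[off] ** 2)
    if r2 + a2 < 1e-12:
        raise ValueError("degenerate KMO: all off-diagonal correlations are 0")
    return float(r2 / (r2 + a2))


def bartlett_sphericity(X) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln|R| on p(p-1)/2 degrees of freedom.
    Returns ``(chi2, df, p_value)``.
    """
    X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than variables ({p})")
    R = _corr(X)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise np.linalg.LinAlgError("|R| <= 0: degenerate correlation matrix")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def interpret_loading(value: float) -> str:
    """Strength label for one rotated loading (absolute-value convention)."""
    a = abs(float(value))
    if a > 1 + 1e-6:
        raise ValueError(f"loading magnitude {a} exceeds 1")
    if a > LOADING_BREAKS[2]:
        return "heavy"
    if a >= LOADING_BREAKS[1]:
        return "moderate"
    if a >= LOADING_BREAKS[0]:
        return "weak"
    return "none"


def _varimax_kaiser(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation with Kaiser row-normalization.

    Rows are scaled to unit communality before rotation and rescaled after,
    so per-variable communalities are exactly preserved.
    """
    h = np.sqrt(np.sum(loadings**2, axis=1))
    h_safe = np.where(h > 0, h, 1.0)
    rotated, T = rotate_factors(loadings / h_safe[:, None], "varimax")
    return rotated * h_safe[:, None], T


class SourcePCA(TransformerMixin, BaseEstimator):
    """Varimax-rotated PCA of a samples-by-congeners concentration table.

    Parameters
    ----------
    eigen_threshold : float, default 1.0
        Retain components whose correlation-matrix eigenvalue exceeds this
        (Kaiser criterion).
    kmo_threshold : float, default 0.5
        Warn (do not fail) when the KMO measure falls at or below this.
    bartlett_alpha : float, default 0.05
        Warn when Bartlett's sphericity test is not significant.

    Attributes
    ----------
    kmo_ : float
    bartlett_chi2_, bartlett_df_, bartlett_p_ : test of sphericity
    eigenvalues_ : (n_retained,) correlation-matrix eigenvalues > threshold
    variance_pct_ : (n_retained,) percent of total variance per rotated
        component (sum of squared rotated loadings / n_variables x 100)
    loadings_ : (n_variables, n_retained) varimax-rotated loadings
    rotation_ : orthonormal rotation matrix applied to the raw loadings
    loading_labels_ : DataFrame of strength labels per (variable, component)
    """

    def __init__(self, eigen_threshold: float = 1.0,
                 kmo_threshold: float = 0.5, bartlett_alpha: float = 0.05):
        self.eigen_threshold = eigen_threshold
        self.kmo_threshold = kmo_threshold
        self.bartlett_alpha = bartlett_alpha

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        X = check_array(X, ensure_min_samples=3, ensure_min_features=2)
        self.n_features_in_ = X.shape[1]

        self.kmo_ = kmo_statistic(X)
        if self.kmo_ <= self.kmo_threshold:
            warnings.warn(
                f"KMO {self.kmo_:.3f} <= {self.kmo_threshold}: data may be "
                "unsuitable for factor extraction", UserWarning)
        self.bartlett_chi2_, self.bartlett_df_, self.bartlett_p_ = (
            bartlett_sphericity(X))
        if self.bartlett_p_ >= self.bartlett_alpha:
            warnings.warn(
                f"Bartlett sphericity p={self.bartlett_p_:.3g} is not "
                "significant: correlations may be too weak", UserWarning)

        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        R = np.corrcoef(X, rowvar=False)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        self.all_eigenvalues_ = evals

        keep = evals > self.eigen_threshold
        k = int(keep.sum())
        if k == 0:
            raise ValueError("no component exceeds the eigenvalue threshold")
        raw = evecs[:, :k] * np.sqrt(evals[:k])
        if k >= 2:
            loadings, T = _varimax_kaiser(raw)
        else:
            warnings.warn("only one retained component: rotation skipped",
                          UserWarning)
            loadings, T = raw, np.eye(1)
        # sign convention: dominant loading of each component positive
        signs = np.sign(loadings[np.argmax(np.abs(loadings), axis=0),
                                 np.arange(k)])
        signs[signs == 0] = 1.0
        loadings = loadings * signs
        T = T * signs

        self.eigenvalues_ = evals[:k]
        self.loadings_ = loadings
        self.rotation_ = T
        self.variance_pct_ = 100.0 * np.sum(loadings**2, axis=0) / X.shape[1]
        names = getattr(self, "feature_names_in_",
                        np.array([f"x{i}" for i in range(X.shape[1])]))
        self.loading_labels_ = pd.DataFrame(
            [[interpret_loading(v) for v in row] for row in loadings],
            index=names, columns=[f"PC{i + 1}" for i in range(k)])
        return self

    def transform(self, X):
        """Component scores (regression method on standardized data)."""
        check_is_fitted(self, "loadings_")
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy(dtype=float)
        X = check_array(X)
        Z = (X - self.mean_) / self.scale_
        L = self.loadings_
        return Z @ L @ np.linalg.inv(L.T @ L)

    def communalities_(self):
        check_is_fitted(self, "loadings_")
        return np.sum(self.loadings_**2, axis=1)

    def report_frame(self) -> pd.DataFrame:
        """Long-format loading report mirroring the usual PCA table layout."""
        check_is_fitted(self, "loadings_")
        names = self.loading_labels_.index
        rows = []
        for j in range(self.loadings_.shape[1]):
            for i, sp in enumerate(names):
                rows.append({
                    "component": f"PC{j + 1}",
                    "species": sp,
                    "loading": self.loadings_[i, j],
                    "strength": self.loading_labels_.iloc[i, j],
                    "eigenvalue": self.eigenvalues_[j],
                    "variance_pct": self.variance_pct_[j],
                })
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        """Plain-text summary: per component, species with loading >= 0.30."""
        check_is_fitted(self, "loadings_")
        lines = ["Principal components analysis with varimax rotation",
                 f"KMO = {self.kmo_:.3f}; Bartlett chi2 = "
                 f"{self.bartlett_chi2_:.2f} (df {self.bartlett_df_}, "
                 f"p = {self.bartlett_p_:.3g})"]
        names = list(self.loading_labels_.index)
        for j in range(self.loadings_.shape[1]):
            lines.append(
                f"PC{j + 1}: eigenvalue {self.eigenvalues_[j]:.3f}, "
                f"{self.variance_pct_[j]:.3f}% variance")
            order = np.argsort(-np.abs(self.loadings_[:, j]))
            for i in order:
                if abs(self.loadings_[i, j]) >= LOADING_BREAKS[0]:
                    lines.append(
                        f"  {names[i]:>4s}  {self.loadings_[i, j]: .3f}  "
                        f"({self.loading_labels_.iloc[i, j]})")
        return "\n".join(lines)


def run_pca_varimax(X, eigen_threshold: float = 1.0) -> SourcePCA:
    """Functional wrapper: fit a :class:`SourcePCA` and return it."""
    return SourcePCA(eigen_threshold=eigen_threshold).fit(X)
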