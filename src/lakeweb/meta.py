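"""Cross-study comparison of web property tables.

The comparison stage mirrors the classical ADE4 workflow: a correlation-matrix
PCA of the per-web properties (S, L, D, C), a between-class ordination that
measures how much of the total inertia lies between study classes, and a
Monte-Carlo permutation test of that ratio.  Variables are centred and scaled
by their *population* (divide-by-n) standard deviation — the ADE4 convention —
so the PCA eigenvalues sum exactly to the number of variables.

The stage is exposed both as sklearn-compatible estimators
(:class:`CorrelationPCA`, :class:`BetweenClassPCA`) and as thin functional
wrappers (:func:`pca`, :func:`between_class`, :func:`permutation_test`,
:func:`run_meta`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BetweenClassPCA",
    "CorrelationPCA",
    "OrdinationResult",
    "between_class",
    "eigenvalue_report",
    "pca",
    "permutation_test",
    "run_meta",
]

VARIABLES = ["S", "L", "D", "C"]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        cols = [c for c in VARIABLES if c in X.columns] or list(X.columns)
        return X[cols].to_numpy(dtype=float), [str(c) for c in cols]
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


class CorrelationPCA(BaseEstimator, TransformerMixin):
    """PCA on the correlation matrix with population-SD scaling.

    Parameters
    ----------
    sd_form : {"population", "sample"}
        Divisor for the scaling SD: n (ADE4 convention, default) or n - 1.

    Attributes
    ----------
    mean_, scale_ : per-variable centring and scaling constants.
    eigenvalues_ : non-increasing eigenvalues of the correlation matrix;
        under population scaling they sum to the number of variables.
    components_ : (p, p) array, eigenvectors as rows (sklearn layout).
    feature_names_in_ : column names when fitted on a DataFrame.
    """

    def __init__(self, sd_form: str = "population"):
        self.sd_form = sd_form

    def fit(self, X, y=None):
        M, names = _as_matrix(X)
        if M.ndim != 2 or M.shape[0] < 2:
            raise ValueError("need a 2-D table with at least 2 rows")
        if not np.isfinite(M).all():
            raise ValueError("table contains missing or non-finite values")
        if self.sd_form not in ("population", "sample"):
            raise ValueError(f"sd_form must be population or sample, got {self.sd_form!r}")
        ddof = 0 if self.sd_form == "population" else 1
        mean = M.mean(axis=0)
        scale = M.std(axis=0, ddof=ddof)
        zero = [names[j] for j in np.nonzero(scale == 0)[0]]
        if zero:
            raise ValueError(f"zero-variance column(s): {zero}")
        Z = (M - mean) / scale
        # correlation matrix under the matching divisor
        n = M.shape[0]
        R = Z.T @ Z / (n - ddof)
        evals, evecs = np.linalg.eigh(R)
        order = np.argsort(evals)[::-1]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = M.shape[1]
        self.mean_, self.scale_ = mean, scale
        self.eigenvalues_ = np.clip(evals[order], 0.0, None)
        self.components_ = evecs[:, order].T
        return self

    def transform(self, X):
        """Row scores: standardized data projected on the eigenvectors."""
        check_is_fitted(self, "components_")
        M, _ = _as_matrix(X)
        Z = (M - self.mean_) / self.scale_
        return Z @ self.components_.T

    @property
    def variable_loadings_(self) -> np.ndarray:
        """Variable coordinates: eigenvectors scaled by sqrt(eigenvalue)."""
        check_is_fitted(self, "components_")
        return (self.components_.T * np.sqrt(self.eigenvalues_))


class BetweenClassPCA(CorrelationPCA):
    """Correlation PCA plus between-class inertia and a permutation test.

    ``fit(X, y)`` takes class labels ``y`` (study identifiers).  Total inertia
    is the mean squared norm of the standardized rows; between-class inertia
    is the same quantity for class-mean rows weighted by class sizes.  Their
    ratio is tested by permuting the labels ``n_permutations`` times;
    the P-value uses the add-one estimator
    ``(1 + #{permuted >= observed}) / (1 + n_permutations)``.

    Attributes (beyond CorrelationPCA's)
    ------------------------------------
    between_ratio_ : between-class / total inertia, in [0, 1].
    class_means_ : DataFrame of class centroid coordinates on the PCA axes.
    perm_p_ : permutation P-value (None when n_permutations == 0).
    """

    def __init__(self, sd_form: str = "population", n_permutations: int = 999,
                 random_state: int | None = None):
        super().__init__(sd_form=sd_form)
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        M, _ = _as_matrix(X)
        if len(y) != M.shape[0]:
            raise ValueError("label length does not match row count")
        classes, codes = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("between-class analysis needs >= 2 distinct classes")
        super().fit(X)
        Z = (M - self.mean_) / self.scale_
        self.between_ratio_ = float(_between_ratio(Z, codes, len(classes)))
        scores = Z @ self.components_.T
        axes = [f"axis{k+1}" for k in range(scores.shape[1])]
        self.classes_ = classes
        self.class_means_ = pd.DataFrame(
            [scores[codes == k].mean(axis=0) for k in range(len(classes))],
            index=list(classes), columns=axes,
        )
        if self.n_permutations:
            if self.n_permutations < 99:
                raise ValueError("n_permutations must be >= 99 (or 0 to skip the test)")
            rng = np.random.default_rng(self.random_state)
            hits = 0
            for _ in range(self.n_permutations):
                perm = rng.permutation(codes)
                if _between_ratio(Z, perm, len(classes)) >= self.between_ratio_ - 1e-12:
                    hits += 1
            self.perm_p_ = (1 + hits) / (1 + self.n_permutations)
        else:
            self.perm_p_ = None
        return self


def _between_ratio(Z: np.ndarray, codes: np.ndarray, k: int) -> float:
    """Between-class inertia over total inertia for standardized data Z."""
    n = Z.shape[0]
    total = float((Z ** 2).sum()) / n
    sums = np.zeros((k, Z.shape[1]))
    np.add.at(sums, codes, Z)
    counts = np.bincount(codes, minlength=k).astype(float)
    means = sums / counts[:, None]
    between = float((counts[:, None] * means ** 2).sum()) / n
    return between / total


# ---------------------------------------------------------------------------
# functional wrappers


@dataclass
class OrdinationResult:
    """Eigenstructure and class-separation summary of one property table."""

    eigenvalues: np.ndarray
    row_scores: pd.DataFrame
    variable_loadings: pd.DataFrame
    between_ratio: float | None = None
    class_centroids: pd.DataFrame | None = None
    perm_p: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def eigenvalue_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"eigenvalue": self.eigenvalues},
            index=[f"axis{k+1}" for k in range(len(self.eigenvalues))],
        )


def _table_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray, list]:
    X = table[VARIABLES]
    y = table["class_label"].to_numpy() if "class_label" in table.columns else None
    labels = (
        list(table["web_label"]) if "web_label" in table.columns else list(range(len(table)))
    )
    return X, y, labels


def pca(table: pd.DataFrame, sd_form: str = "population") -> OrdinationResult:
    """Correlation PCA of a property table (no class structure)."""
    X, _, labels = _table_xy(table)
    est = CorrelationPCA(sd_form=sd_form).fit(X)
    axes = [f"axis{k+1}" for k in range(len(est.eigenvalues_))]
    return OrdinationResult(
        eigenvalues=est.eigenvalues_,
        row_scores=pd.DataFrame(est.transform(X), index=labels, columns=axes),
        variable_loadings=pd.DataFrame(est.variable_loadings_, index=VARIABLES, columns=axes),
    )


def between_class(table: pd.DataFrame, sd_form: str = "population") -> tuple[float, pd.DataFrame]:
    """Between-class inertia ratio and class centroids (no permutation test)."""
    X, y, _ = _table_xy(table)
    if y is None:
        raise ValueError("table has no class_label column")
    est = BetweenClassPCA(sd_form=sd_form, n_permutations=0).fit(X, y)
    return est.between_ratio_, est.class_means_


def permutation_test(
    table: pd.DataFrame, n_perm: int = 999, seed: int | None = None,
    sd_form: str = "population",
) -> float:
    """Monte-Carlo P for class separation: labels permuted n_perm times."""
    X, y, _ = _table_xy(table)
    if y is None:
        raise ValueError("table has no class_label column")
    est = BetweenClassPCA(sd_form=sd_form, n_permutations=n_perm, random_state=seed).fit(X, y)
    return est.perm_p_


def run_meta(
    complete_table: pd.DataFrame,
    pelagic_table: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
    sd_form: str = "population",
) -> dict[str, OrdinationResult]:
    """Run the full comparison separately for complete and pelagic web tables.

    Returns one :class:`OrdinationResult` per model, keyed ``"complete"`` and
    ``"pelagic"``; ``eigenvalue_report`` on the pair is available via
    :func:`eigenvalue_report`.
    """
    out: dict[str, OrdinationResult] = {}
    for name, table in (("pelagic", pelagic_table), ("complete", complete_table)):
        X, y, labels = _table_xy(table)
        if y is None:
            raise ValueError(f"{name} table has no class_label column")
        est = BetweenClassPCA(sd_form=sd_form, n_permutations=n_perm, random_state=seed).fit(X, y)
        axes = [f"axis{k+1}" for k in range(len(est.eigenvalues_))]
        out[name] = OrdinationResult(
            eigenvalues=est.eigenvalues_,
            row_scores=pd.DataFrame(est.transform(X), index=labels, columns=axes),
            variable_loadings=pd.DataFrame(est.variable_loadings_, index=VARIABLES, columns=axes),
            between_ratio=est.between_ratio_,
            class_centroids=est.class_means_,
            perm_p=est.perm_p_,
            n_perm=n_perm,
            seed=seed,
        )
    return out


def eigenvalue_report(results: dict[str, OrdinationResult]) -> pd.DataFrame:
    """Two-model eigenvalue table (axes as rows, models as columns)."""
    cols = {name: res.eigenvalues for name, res in results.items()}
    n_axes = max(len(v) for v in cols.values())
    return pd.DataFrame(cols, index=[f"axis{k+1}" for k in range(n_axes)])
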