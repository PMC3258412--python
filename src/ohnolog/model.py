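"""Standardized, grand-mean-imputed logistic regression of ohnolog retention.

The modelling pipeline is:

1. **Scale** every covariate by the sample standard deviation of its
   observed values (division only — no centering, which the intercept
   absorbs).  Coefficients then read as log-odds per SD of the covariate,
   so their magnitudes are comparable across variables.
2. **Impute** each missing value with the grand mean of that variable's
   observed scaled values.  The column is deliberately *not* re-normalized
   afterwards: re-scaling would re-inflate its variance and overstate the
   importance of a variable that is mostly imputed.
3. **Fit** the maximum-likelihood logistic regression by Newton/IRLS, with
   Wald standard errors from the inverse observed information.

Both a sklearn-style estimator (:class:`RetentionLogit`, composable with
``sklearn`` model selection) and thin functional wrappers
(:func:`standardize`, :func:`impute_grand_mean`, :func:`fit_logistic`,
:func:`sensitivity_complete_case`) are provided.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import _glm

__all__ = [
    "SDScaler",
    "GrandMeanImputer",
    "RetentionLogit",
    "DesignMatrix",
    "FitResult",
    "build_design",
    "standardize",
    "impute_grand_mean",
    "fit_logistic",
    "sensitivity_complete_case",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


class SDScaler(TransformerMixin, BaseEstimator):
    """Divide each column by the sample SD of its observed values.

    Missing values are ignored when the SD is estimated and pass through
    ``transform`` unchanged.  Columns are not centered.

    Parameters
    ----------
    ddof : int, default 1
        Delta degrees of freedom of the SD estimator (1 = sample SD).
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        Xf = _as_frame(X)
        sds = {}
        for name in Xf.columns:
            col = Xf[name].to_numpy(dtype=float)
            obs = col[~np.isnan(col)]
            if np.unique(obs).size < 2:
                raise ValueError(
                    f"variable {name!r} has fewer than 2 distinct observed values"
                )
            sd = float(np.std(obs, ddof=self.ddof))
            if sd <= 0:
                raise ValueError(f"variable {name!r} has zero variance")
            sds[name] = sd
        self.scale_ = pd.Series(sds)
        self.feature_names_in_ = np.asarray(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "scale_")
        Xf = _as_frame(X)
        return Xf / self.scale_


class GrandMeanImputer(TransformerMixin, BaseEstimator):
    """Replace each missing value with the mean of that column's observed values.

    By design there is no variance correction afterwards: a column with
    fraction ``f`` of its cells imputed keeps a post-imputation SD of about
    ``sqrt(1-f)`` times its observed SD.
    """

    def fit(self, X, y=None):
        Xf = _as_frame(X)
        means = Xf.mean(axis=0, skipna=True)
        if means.isna().any():
            bad = list(means.index[means.isna()])
            raise ValueError(f"variable(s) with all values missing: {bad}")
        self.means_ = means
        self.feature_names_in_ = np.asarray(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        return _as_frame(X).fillna(self.means_)


@dataclass
class DesignMatrix:
    """Scaled, imputed numeric design ready for the logistic fit."""

    gene_ids: np.ndarray
    variable_names: list[str]
    X: np.ndarray                 # genes x variables, no intercept column
    y: np.ndarray
    imputed_mask: np.ndarray      # True where a grand mean was substituted
    scaling_sds: np.ndarray

    def __post_init__(self) -> None:
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")
        if not np.all(self.scaling_sds > 0):
            raise ValueError("scaling SDs must be positive")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]


@dataclass
class FitResult:
    """Coefficients (log-odds per covariate SD), Wald SEs and diagnostics."""

    variable_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    intercept: float
    intercept_se: float
    converged: bool
    log_likelihood: float
    n_iter: int = 0
    n_obs: int = 0
    message: str = ""

    def wald_p(self) -> np.ndarray:
        """Two-tailed normal-approximation p-values per coefficient."""
        z = self.coefficients / self.standard_errors
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable_names,
                "coefficient": self.coefficients,
                "standard_error": self.standard_errors,
                "wald_p": self.wald_p(),
            }
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["coefficients"] = [float(v) for v in self.coefficients]
        d["standard_errors"] = [float(v) for v in self.standard_errors]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


class RetentionLogit(ClassifierMixin, BaseEstimator):
    """Logistic regression of duplicate-gene persistence with SD-scaling
    and grand-mean imputation built in.

    Accepts a feature matrix that may contain NaN.  With
    ``complete_case=True`` rows with any missing covariate are dropped and
    the SDs re-estimated on the remaining rows (the sensitivity analysis);
    otherwise missing cells are grand-mean imputed after scaling.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray, (n_variables,) — log-odds per SD of each covariate.
    intercept_ : float
    bse_, intercept_se_ : Wald standard errors.
    converged_ : bool; ``fit_message_`` carries the diagnostic when False.
    llf_ : maximized log-likelihood.
    scale_ : per-variable SDs used for division.
    imputed_mask_ : boolean matrix marking grand-mean-substituted cells.
    """

    def __init__(
        self,
        ddof: int = 1,
        tol: float = _glm.TOL,
        max_iter: int = _glm.MAX_ITER,
        complete_case: bool = False,
    ):
        self.ddof = ddof
        self.tol = tol
        self.max_iter = max_iter
        self.complete_case = complete_case

    def fit(self, X, y):
        Xf = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("outcome must be binary 0/1")
        if self.complete_case:
            keep = ~Xf.isna().any(axis=1).to_numpy()
            Xf = Xf.loc[keep]
            y = y[keep]
            if Xf.shape[0] < 10 * Xf.shape[1]:
                warnings.warn(
                    f"only {Xf.shape[0]} complete cases for {Xf.shape[1]} "
                    "variables; the fit may be unstable",
                    stacklevel=2,
                )
        if Xf.shape[0] <= Xf.shape[1] + 1:
            raise ValueError("need more genes than variables")

        scaler = SDScaler(ddof=self.ddof).fit(Xf)
        scaled = scaler.transform(Xf)
        mask = scaled.isna().to_numpy()
        imputer = GrandMeanImputer().fit(scaled)
        Xd = imputer.transform(scaled).to_numpy(dtype=float)

        design = np.column_stack([np.ones(len(Xd)), Xd])
        res = _glm.fit_logit(design, y, tol=self.tol, max_iter=self.max_iter)

        self.variable_names_ = list(Xf.columns)
        self.feature_names_in_ = np.asarray(Xf.columns)
        self.n_features_in_ = Xf.shape[1]
        self.classes_ = np.array([0, 1])
        self.scale_ = scaler.scale_
        self.impute_means_ = imputer.means_
        self.imputed_mask_ = mask
        self.intercept_ = float(res.beta[0])
        self.coef_ = res.beta[1:]
        self.intercept_se_ = float(res.se[0])
        self.bse_ = res.se[1:]
        self.converged_ = res.converged
        self.llf_ = res.log_likelihood
        self.n_iter_ = res.n_iter
        self.n_obs_ = int(len(y))
        self.fit_message_ = res.message
        return self

    def _design(self, X) -> np.ndarray:
        Xf = _as_frame(X)
        scaled = Xf / self.scale_
        return scaled.fillna(self.impute_means_).to_numpy(dtype=float)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return self.intercept_ + self._design(X) @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        p1 = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def result_(self) -> FitResult:
        check_is_fitted(self, "coef_")
        return FitResult(
            variable_names=self.variable_names_,
            coefficients=self.coef_.copy(),
            standard_errors=self.bse_.copy(),
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
            converged=self.converged_,
            log_likelihood=self.llf_,
            n_iter=self.n_iter_,
            n_obs=self.n_obs_,
            message=self.fit_message_,
        )


# ---------------------------------------------------------------------------
# Functional wrappers over the estimators


def _split_features(features: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "outcome" not in features.columns:
        raise ValueError("feature table needs an 'outcome' column")
    cols = [c for c in features.columns if c != "outcome"]
    return features[cols], features["outcome"].to_numpy(dtype=float)


def standardize(
    features: pd.DataFrame, ddof: int = 1
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale covariates by their observed-value SDs; outcome untouched.

    Returns the scaled table (missing cells preserved) and the SDs used.
    """
    Xf, _ = _split_features(features)
    scaler = SDScaler(ddof=ddof).fit(Xf)
    scaled = features.copy()
    scaled[Xf.columns] = scaler.transform(Xf)
    return scaled, scaler.scale_


def impute_grand_mean(
    scaled: pd.DataFrame, scaling_sds: pd.Series
) -> DesignMatrix:
    """Grand-mean impute an SD-scaled feature table into a :class:`DesignMatrix`."""
    Xf, y = _split_features(scaled)
    mask = Xf.isna().to_numpy()
    imputer = GrandMeanImputer().fit(Xf)
    Xd = imputer.transform(Xf).to_numpy(dtype=float)
    return DesignMatrix(
        gene_ids=np.asarray(scaled.index),
        variable_names=list(Xf.columns),
        X=Xd,
        y=y,
        imputed_mask=mask,
        scaling_sds=scaling_sds.reindex(Xf.columns).to_numpy(dtype=float),
    )


def build_design(
    features: pd.DataFrame, ddof: int = 1, complete_case: bool = False
) -> DesignMatrix:
    """standardize → impute in one step (optionally complete cases only)."""
    if complete_case:
        Xf, _ = _split_features(features)
        features = features.loc[~Xf.isna().any(axis=1)]
    scaled, sds = standardize(features, ddof=ddof)
    return impute_grand_mean(scaled, sds)


def fit_logistic(
    design: DesignMatrix, tol: float = _glm.TOL, max_iter: int = _glm.MAX_ITER
) -> FitResult:
    """Maximum-likelihood logistic fit of a prepared design matrix."""
    X = np.column_stack([np.ones(design.n_genes), design.X])
    res = _glm.fit_logit(X, design.y, tol=tol, max_iter=max_iter)
    return FitResult(
        variable_names=list(design.variable_names),
        coefficients=res.beta[1:],
        standard_errors=res.se[1:],
        intercept=float(res.beta[0]),
        intercept_se=float(res.se[0]),
        converged=res.converged,
        log_likelihood=res.log_likelihood,
        n_iter=res.n_iter,
        n_obs=design.n_genes,
        message=res.message,
    )


def sensitivity_complete_case(features: pd.DataFrame, ddof: int = 1) -> FitResult:
    """Refit using only genes with no missing covariate (no imputation)."""
    Xf, y = _split_features(features)
    est = RetentionLogit(ddof=ddof, complete_case=True).fit(Xf, y)
    return est.result_()
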