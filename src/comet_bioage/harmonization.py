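"""Parametric empirical-Bayes batch harmonization (ComBat) for ROI measures.

Scanner field strength (1.5T vs 3T) induces additive and multiplicative batch
effects on regional thickness and volume measures. ComBat models each feature
as covariate effects plus a per-batch location/scale perturbation, shrinks the
per-batch estimates toward pooled parametric priors (normal for location,
inverse-gamma for scale) with moment-matched hyperparameters, and removes the
shrunken effects while adding covariate contributions back unchanged.

The model is fitted on a reference cohort (all CU subjects) and then applied
to unseen symptomatic rows using the stored per-batch parameters, so disease
effects absent from the reference are untouched by design.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import FitError, InputError


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _aprior(delta_hat):
    m, s2 = np.mean(delta_hat), np.var(delta_hat, ddof=1)
    return (2.0 * s2 + m**2) / s2


def _bprior(delta_hat):
    m, s2 = np.mean(delta_hat), np.var(delta_hat, ddof=1)
    return (m * s2 + m**3) / s2


class ComBatHarmonizer(TransformerMixin, BaseEstimator):
    """Reference-fitted parametric ComBat as a scikit-learn transformer.

    Parameters
    ----------
    tol
        Convergence tolerance on the relative change of the EB location/scale
        estimates between iterations.
    max_iter
        Cap on EB iterations per batch.

    Fitted attributes
    -----------------
    batches_ : list
        Batch labels seen at fit, in sorted order.
    covariate_names_ : list
        Covariate columns retained (constant columns are dropped and recorded
        in ``dropped_covariates_``).
    beta_cov_ : ndarray, (p, G)
        Covariate coefficients of the standardization fit.
    grand_mean_ : ndarray, (G,)
        Batch-size-weighted grand mean per feature.
    var_pooled_ : ndarray, (G,)
        Pooled residual variance per feature (1/n denominator).
    gamma_star_, delta_star_sq_ : ndarray, (B, G)
        EB-shrunken per-batch location and squared scale in standardized units.
    """

    def __init__(self, tol: float = 1e-4, max_iter: int = 1000):
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting ------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None, *, batch, covariates: pd.DataFrame | None = None):
        Y = self._as_frame(X)
        batch = pd.Series(batch, index=Y.index) if not isinstance(batch, pd.Series) else batch
        batch = batch.reindex(Y.index)
        if batch.isna().any():
            raise FitError("every reference row needs a batch label")
        cov = self._prep_covariates(covariates, Y.index, fitting=True)

        counts = batch.value_counts()
        if len(counts) < 2:
            raise FitError("ComBat needs at least 2 batches in the reference")
        if (counts < 2).any():
            small = list(counts.index[counts < 2])
            raise FitError(f"batches with fewer than 2 reference rows: {small}")
        self.batches_ = sorted(counts.index)

        n = len(Y)
        onehot = np.column_stack([(batch == b).to_numpy(float) for b in self.batches_])
        design = np.column_stack([onehot, cov]) if cov.shape[1] else onehot
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            raise FitError("singular harmonization design (collinear batch/covariate columns)")

        Yv = Y.to_numpy(float)
        B_hat, *_ = np.linalg.lstsq(design, Yv, rcond=None)
        n_b = counts.reindex(self.batches_).to_numpy(float)
        self.grand_mean_ = (n_b / n) @ B_hat[: len(self.batches_)]
        self.beta_cov_ = B_hat[len(self.batches_):]
        resid = Yv - design @ B_hat
        self.var_pooled_ = np.mean(resid**2, axis=0)
        if np.any(self.var_pooled_ <= 0):
            raise FitError("zero pooled residual variance; cannot standardize")

        stand_mean = self.grand_mean_ + (cov @ self.beta_cov_ if cov.shape[1] else 0.0)
        s = (Yv - stand_mean) / np.sqrt(self.var_pooled_)

        B, G = len(self.batches_), Yv.shape[1]
        gamma_hat = np.empty((B, G))
        delta_hat = np.empty((B, G))
        for i, b in enumerate(self.batches_):
            rows = s[(batch == b).to_numpy()]
            gamma_hat[i] = rows.mean(axis=0)
            delta_hat[i] = rows.var(axis=0, ddof=1)

        self.gamma_star_ = np.empty((B, G))
        self.delta_star_sq_ = np.empty((B, G))
        for i, b in enumerate(self.batches_):
            rows = s[(batch == b).to_numpy()]
            g_bar = gamma_hat[i].mean()
            t2 = gamma_hat[i].var(ddof=1)
            a, bp = _aprior(delta_hat[i]), _bprior(delta_hat[i])
            g_old, d_old = gamma_hat[i].copy(), delta_hat[i].copy()
            for _ in range(self.max_iter):
                g_new = _postmean(gamma_hat[i], g_bar, n_b[i], d_old, t2)
                sum2 = ((rows - g_new) ** 2).sum(axis=0)
                d_new = _postvar(sum2, n_b[i], a, bp)
                change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                             np.max(np.abs(d_new - d_old) / np.abs(d_old)))
                g_old, d_old = g_new, d_new
                if change < self.tol:
                    break
            self.gamma_star_[i], self.delta_star_sq_[i] = g_old, d_old
        if np.any(self.delta_star_sq_ <= 0):
            raise FitError("non-positive EB scale estimate")
        self.feature_names_ = list(Y.columns)
        return self

    # -- application --------------------------------------------------------

    def transform(self, X: pd.DataFrame, *, batch, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        self._check_fitted()
        Y = self._as_frame(X)
        if list(Y.columns) != self.feature_names_:
            Y = Y.reindex(columns=self.feature_names_)
            if Y.isna().any().any():
                raise InputError("data to harmonize lacks features seen at fit")
        batch = pd.Series(batch, index=Y.index) if not isinstance(batch, pd.Series) else batch
        batch = batch.reindex(Y.index)
        unseen = sorted(set(batch.dropna()) - set(self.batches_))
        if unseen or batch.isna().any():
            raise InputError(f"batch labels not seen at fit: {unseen or ['<missing>']}")
        cov = self._prep_covariates(covariates, Y.index, fitting=False)
        stand_mean = self.grand_mean_ + (cov @ self.beta_cov_ if cov.shape[1] else 0.0)
        s = (Y.to_numpy(float) - stand_mean) / np.sqrt(self.var_pooled_)
        idx = np.array([self.batches_.index(b) for b in batch])
        adj = (s - self.gamma_star_[idx]) / np.sqrt(self.delta_star_sq_[idx])
        out = adj * np.sqrt(self.var_pooled_) + stand_mean
        return pd.DataFrame(out, index=Y.index, columns=self.feature_names_)

    # -- helpers ------------------------------------------------------------

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        Y = pd.DataFrame(X)
        vals = Y.to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise InputError("ROI table contains non-finite values")
        return Y

    def _prep_covariates(self, covariates, index, *, fitting: bool) -> np.ndarray:
        if covariates is None:
            if fitting:
                self.covariate_names_ = []
                self.dropped_covariates_ = []
            if self.covariate_names_:
                raise InputError(f"covariates required: {self.covariate_names_}")
            return np.empty((len(index), 0))
        cov = pd.DataFrame(covariates).reindex(index)
        if cov.isna().any().any():
            raise InputError("covariates missing for some rows")
        if fitting:
            # constant columns (e.g. diagnosis in a CU-only reference) carry no
            # information and would make the design singular; drop and record.
            constant = [c for c in cov.columns if cov[c].nunique() <= 1]
            self.dropped_covariates_ = constant
            self.covariate_names_ = [c for c in cov.columns if c not in constant]
        missing = [c for c in self.covariate_names_ if c not in cov.columns]
        if missing:
            raise InputError(f"missing covariate columns: {missing}")
        return cov[self.covariate_names_].to_numpy(float)

    def _check_fitted(self):
        if not hasattr(self, "gamma_star_"):
            raise FitError("ComBatHarmonizer is not fitted")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        return {
            "tol": self.tol,
            "max_iter": self.max_iter,
            "batches": list(map(str, self.batches_)),
            "feature_names": self.feature_names_,
            "covariate_names": self.covariate_names_,
            "dropped_covariates": self.dropped_covariates_,
            "grand_mean": self.grand_mean_.tolist(),
            "beta_cov": self.beta_cov_.tolist(),
            "var_pooled": self.var_pooled_.tolist(),
            "gamma_star": self.gamma_star_.tolist(),
            "delta_star_sq": self.delta_star_sq_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComBatHarmonizer":
        obj = cls(tol=d["tol"], max_iter=d["max_iter"])
        obj.batches_ = list(d["batches"])
        obj.feature_names_ = list(d["feature_names"])
        obj.covariate_names_ = list(d["covariate_names"])
        obj.dropped_covariates_ = list(d["dropped_covariates"])
        obj.grand_mean_ = np.array(d["grand_mean"])
        obj.beta_cov_ = np.array(d["beta_cov"])
        obj.var_pooled_ = np.array(d["var_pooled"])
        obj.gamma_star_ = np.array(d["gamma_star"])
        obj.delta_star_sq_ = np.array(d["delta_star_sq"])
        return obj

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ComBatHarmonizer":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def fit_combat(reference: pd.DataFrame, covariates: pd.DataFrame | None, batch,
               tol: float = 1e-4, max_iter: int = 1000) -> ComBatHarmonizer:
    """Fit parametric ComBat on the reference cohort's ROI table."""
    return ComBatHarmonizer(tol=tol, max_iter=max_iter).fit(
        reference, batch=batch, covariates=covariates)


def apply_combat(model: ComBatHarmonizer, data: pd.DataFrame,
                 covariates: pd.DataFrame | None, batch) -> pd.DataFrame:
    """Harmonize rows (seen or unseen at fit) with a fitted ComBat model."""
    return model.transform(data, batch=batch, covariates=covariates)
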