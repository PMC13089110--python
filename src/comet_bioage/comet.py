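"""Cortical and MTL composites, reference w-scores, and the CoMeT index.

CoMeT (Cortico-Medial Temporal index) quantifies where a participant sits on
the cortical-predominant vs MTL-predominant spectrum of AD neurodegeneration:

    CoMeT = cortical composite w-score - MTL composite w-score

where each w-score is a covariate-adjusted z-score against the CU reference
cohort: thickness composites are adjusted for age and sex, volume composites
for age and intracranial volume. Lower CoMeT = relatively greater cortical
involvement (less typical presentation); higher = relatively greater MTL
involvement (more typical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator

from .errors import FitError, InputError

#: DKT cortical-signature regions contributing thickness to the cortical composite.
CORTICAL_THICKNESS_ROIS = (
    "inferiortemporal", "temporalpole", "superiorparietal", "precuneus",
    "supramarginal", "superiorfrontal", "middlefrontal", "fusiform",
    "inferiorparietal", "superiortemporal", "posteriorcingulate",
    "isthmuscingulate", "lateraloccipital", "middletemporal",
    "medialorbitofrontal", "cuneus", "lingual", "pericalcarine",
)
MTL_THICKNESS_ROIS = ("entorhinal", "parahippocampal")
MTL_VOLUME_ROIS = ("hippocampus", "amygdala")

HEMISPHERES = ("lh", "rh")


@dataclass(frozen=True)
class RoiSetDefinition:
    """Named ROI sets defining the cortical and MTL composites."""

    cortical_thickness_rois: tuple = CORTICAL_THICKNESS_ROIS
    mtl_thickness_rois: tuple = MTL_THICKNESS_ROIS
    mtl_volume_rois: tuple = MTL_VOLUME_ROIS

    def __post_init__(self):
        sets = [set(self.cortical_thickness_rois), set(self.mtl_thickness_rois),
                set(self.mtl_volume_rois)]
        if sum(map(len, sets)) != len(set().union(*sets)):
            raise InputError("ROI sets must be disjoint")

    @classmethod
    def from_yaml(cls, path) -> "RoiSetDefinition":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(cortical_thickness_rois=tuple(d["cortical_thickness_rois"]),
                   mtl_thickness_rois=tuple(d["mtl_thickness_rois"]),
                   mtl_volume_rois=tuple(d["mtl_volume_rois"]))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump({"cortical_thickness_rois": list(self.cortical_thickness_rois),
                            "mtl_thickness_rois": list(self.mtl_thickness_rois),
                            "mtl_volume_rois": list(self.mtl_volume_rois)}, fh)


DEFAULT_ROI_SETS = RoiSetDefinition()


def roi_columns(roi_names, kind: str) -> list[str]:
    """Expand ROI base names into bilateral column names, e.g. ``lh_precuneus_thickness``."""
    return [f"{h}_{r}_{kind}" for r in roi_names for h in HEMISPHERES]


def composite(roi: pd.DataFrame, roi_names, kind: str) -> pd.Series:
    """Bilateral-then-set average of the named ROIs.

    Per ROI, the left and right hemisphere values are averaged; the composite
    is the unweighted mean across ROIs in the set. Missing columns raise with
    the full list of absent names.
    """
    missing = [c for c in roi_columns(roi_names, kind) if c not in roi.columns]
    if missing:
        raise InputError(f"ROI table missing columns: {missing}")
    bilat = pd.DataFrame({
        r: roi[[f"lh_{r}_{kind}", f"rh_{r}_{kind}"]].mean(axis=1) for r in roi_names
    })
    return bilat.mean(axis=1).rename(f"composite_{kind}")


class WScoreModel(BaseEstimator):
    """Reference-cohort regression for w-scoring a composite measure.

    Fit ordinary least squares of the composite on the covariates over the CU
    reference (``fit(X, y)`` with ``X`` the covariate table, ``y`` the
    composite values); ``wscore(X, y)`` then returns
    ``(observed - predicted) / residual_sd_`` where ``residual_sd_`` uses the
    ``n - p`` denominator (p = number of fitted parameters incl. intercept).

    Parameters
    ----------
    covariate_names
        Ordered covariate columns; by convention ``("age", "sex")`` for
        thickness composites and ``("age", "icv")`` for volume composites.
    """

    def __init__(self, covariate_names=("age", "sex")):
        self.covariate_names = tuple(covariate_names)

    def fit(self, X: pd.DataFrame, y):
        C = self._covariate_matrix(X)
        y = np.asarray(y, dtype=float)
        n, k = C.shape
        p = k + 1
        if n <= p:
            raise FitError(f"w-score fit needs more than {p} reference subjects")
        # centre/scale covariates internally for conditioning (ICV is ~1e6,
        # sex is 0/1); exposed coefficients are back-transformed to raw units
        self._mu_ = C.mean(axis=0)
        sd = C.std(axis=0, ddof=0)
        self._scale_ = np.where(sd > 0, sd, 1.0)
        A = np.column_stack([np.ones(n), (C - self._mu_) / self._scale_])
        if np.linalg.matrix_rank(A) < p:
            raise FitError("singular w-score design")
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        rsd = float(np.sqrt(np.sum(resid**2) / (n - p)))
        if rsd <= np.finfo(float).eps * max(1.0, np.abs(y).max()) * n:
            raise FitError("zero residual variance in the reference fit; "
                           "w-scores need nonzero residual SD")
        self._coef_std_ = coef
        self.coef_ = coef[1:] / self._scale_
        self.intercept_ = float(coef[0] - np.sum(coef[1:] * self._mu_ / self._scale_))
        self.residual_sd_ = rsd
        self.n_ = n
        self.p_ = p
        return self

    def predict(self, X: pd.DataFrame):
        self._check_fitted()
        C = self._covariate_matrix(X)
        A = np.column_stack([np.ones(len(C)), (C - self._mu_) / self._scale_])
        return A @ self._coef_std_

    def wscore(self, X: pd.DataFrame, y) -> np.ndarray:
        """(observed - predicted) / reference residual SD."""
        return (np.asarray(y, dtype=float) - self.predict(X)) / self.residual_sd_

    def _covariate_matrix(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.covariate_names if c not in X.columns]
        if missing:
            raise InputError(f"missing covariate columns: {missing}")
        cov = X[list(self.covariate_names)].to_numpy(dtype=float)
        if not np.all(np.isfinite(cov)):
            raise InputError("non-finite covariate values")
        return cov

    def _check_fitted(self):
        if not hasattr(self, "residual_sd_"):
            raise FitError("WScoreModel is not fitted")


def fit_wscore_model(reference_values, covariates: pd.DataFrame, kind: str) -> WScoreModel:
    """Fit a w-score model on the CU reference for a thickness or volume composite."""
    if kind not in ("thickness", "volume"):
        raise InputError("kind must be 'thickness' or 'volume'")
    names = ("age", "sex") if kind == "thickness" else ("age", "icv")
    return WScoreModel(covariate_names=names).fit(covariates, reference_values)


def wscore(value, covariate_row, model: WScoreModel):
    """w-score one or more observations under a fitted reference model."""
    X = pd.DataFrame(covariate_row)
    return model.wscore(X, value)


def comet_score(cortical_w, mtl_w):
    """CoMeT = cortical w-score minus MTL w-score (lower = more cortical)."""
    c = np.asarray(cortical_w, dtype=float)
    m = np.asarray(mtl_w, dtype=float)
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(m))):
        raise InputError("w-scores must be finite")
    out = c - m
    return out[()] if out.ndim == 0 else out


def mtl_composite_w(roi: pd.DataFrame, covariates: pd.DataFrame,
                    thickness_model: WScoreModel, volume_model: WScoreModel,
                    roi_sets: RoiSetDefinition = DEFAULT_ROI_SETS) -> pd.Series:
    """MTL composite w-score: mean of the thickness and volume sub-w-scores.

    The MTL mixes thickness ROIs (entorhinal, parahippocampal) and volume
    ROIs (hippocampus, amygdala), which carry different covariate
    adjustments; each sub-composite is w-scored under its own model and the
    two sub-w-scores are averaged.
    """
    thick = composite(roi, roi_sets.mtl_thickness_rois, "thickness")
    vol = composite(roi, roi_sets.mtl_volume_rois, "volume")
    w_thick = thickness_model.wscore(covariates.loc[roi.index], thick)
    w_vol = volume_model.wscore(covariates.loc[roi.index], vol)
    return pd.Series((w_thick + w_vol) / 2.0, index=roi.index, name="mtl_w")


@dataclass
class CometModels:
    """The three CU-fitted w-score models backing a CoMeT computation."""

    cortical: WScoreModel
    mtl_thickness: WScoreModel
    mtl_volume: WScoreModel
    roi_sets: RoiSetDefinition = field(default_factory=RoiSetDefinition)


def fit_comet_models(roi_reference: pd.DataFrame, covariates_reference: pd.DataFrame,
                     roi_sets: RoiSetDefinition = DEFAULT_ROI_SETS) -> CometModels:
    """Fit the cortical and MTL w-score models on the CU reference cohort."""
    cov = covariates_reference.loc[roi_reference.index]
    cortical = fit_wscore_model(
        composite(roi_reference, roi_sets.cortical_thickness_rois, "thickness"), cov, "thickness")
    mtl_t = fit_wscore_model(
        composite(roi_reference, roi_sets.mtl_thickness_rois, "thickness"), cov, "thickness")
    mtl_v = fit_wscore_model(
        composite(roi_reference, roi_sets.mtl_volume_rois, "volume"), cov, "volume")
    return CometModels(cortical=cortical, mtl_thickness=mtl_t, mtl_volume=mtl_v,
                       roi_sets=roi_sets)


def compute_comet(roi: pd.DataFrame, covariates: pd.DataFrame,
                  models: CometModels) -> pd.DataFrame:
    """Score participants: cortical w, MTL w and CoMeT, indexed by participant id."""
    cov = covariates.loc[roi.index]
    cort = composite(roi, models.roi_sets.cortical_thickness_rois, "thickness")
    cortical_w = pd.Series(models.cortical.wscore(cov, cort), index=roi.index, name="cortical_w")
    mtl_w = mtl_composite_w(roi, cov, models.mtl_thickness, models.mtl_volume, models.roi_sets)
    return pd.DataFrame({
        "cortical_w": cortical_w,
        "mtl_w": mtl_w,
        "comet": comet_score(cortical_w, mtl_w),
    }).rename_axis("participant_id")
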