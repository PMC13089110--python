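"""Linear epigenetic clocks and the biological age gap (BAG).

A clock is a linear predictor over CpG beta values, optionally followed by the
log-linear adult age anti-transform used by pan-tissue clocks. The biological
age gap is the residual from regressing clock-predicted age on chronological
age over a cohort; per-clock gaps are averaged to reduce clock-specific noise,
and the averaged BAG is stratified into accelerated / neutral / decelerated
groups at +/- k reference SD (k = 0.5 by default).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.linear_model import LinearRegression

from .errors import AlignmentError, EstimationError, InputError, MissingCpGError, StratificationError

TRANSFORMS = ("identity", "log_linear_adult")

#: Default SD multiplier for biological-age group stratification.
DEFAULT_SD_MULTIPLIER = 0.5


@dataclass
class ClockModel:
    """A named linear epigenetic clock.

    Attributes
    ----------
    name
        Clock identifier.
    intercept
        Intercept of the linear predictor, in transformed-age units.
    coefficients
        CpG id -> weight mapping (transformed-age units per beta unit).
    transform
        ``identity`` (predictor is age in years) or ``log_linear_adult``
        (predictor is log-linear transformed age, anti-transformed around
        ``adult_age``).
    adult_age
        Knot of the log-linear transform, in years.
    """

    name: str
    intercept: float
    coefficients: dict[str, float] = field(default_factory=dict)
    transform: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self):
        if self.transform not in TRANSFORMS:
            raise InputError(f"unknown clock transform '{self.transform}'")
        if not self.coefficients:
            raise InputError(f"clock '{self.name}' has no CpG coefficients")
        if self.adult_age <= 0:
            raise InputError("adult_age must be positive")


def anti_transform_age(m, adult_age: float = 20.0):
    """Map the linear predictor of a log-linear clock back to years.

    ``m < 0`` -> ``(adult_age + 1) * exp(m) - 1`` (paediatric branch);
    ``m >= 0`` -> ``adult_age + m * (adult_age + 1)``. The fixed point
    ``m = 0`` maps to ``adult_age``.
    """
    m = np.asarray(m, dtype=float)
    out = np.where(m < 0, (adult_age + 1.0) * np.exp(m) - 1.0,
                   adult_age + m * (adult_age + 1.0))
    return out[()] if out.ndim == 0 else out


def transform_age(age, adult_age: float = 20.0):
    """Inverse of :func:`anti_transform_age`: years -> linear-predictor units."""
    age = np.asarray(age, dtype=float)
    if np.any(age <= -1):
        raise InputError("transform_age requires age > -1")
    out = np.where(age < adult_age, np.log((age + 1.0) / (adult_age + 1.0)),
                   (age - adult_age) / (adult_age + 1.0))
    return out[()] if out.ndim == 0 else out


def select_replicate(matrix: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep one technical replicate per participant, chosen uniformly.

    ``matrix`` rows are indexed by ``(participant_id, replicate)`` (a
    MultiIndex) or plainly by participant id, in which case it is returned
    unchanged. The choice is uniform within each replicate group and
    deterministic under ``seed``. The result is indexed by participant id,
    preserving first-appearance participant order.
    """
    if matrix.index.nlevels == 1:
        return matrix
    rng = np.random.default_rng(seed)
    pids = matrix.index.get_level_values(0)
    keep = []
    for pid in pids.unique():
        rows = np.flatnonzero(pids == pid)
        keep.append(rows[rng.integers(len(rows))])
    out = matrix.iloc[keep]
    out.index = out.index.get_level_values(0)
    return out.rename_axis("participant_id")


def apply_clock(matrix: pd.DataFrame, clock: ClockModel) -> pd.Series:
    """Predict age (years) for every row of a methylation beta matrix.

    Raises :class:`MissingCpGError` listing absent CpGs; there is no silent
    imputation.
    """
    cpgs = list(clock.coefficients)
    missing = [c for c in cpgs if c not in matrix.columns]
    if missing:
        raise MissingCpGError(clock.name, missing)
    weights = np.array([clock.coefficients[c] for c in cpgs])
    m = clock.intercept + matrix[cpgs].to_numpy(dtype=float) @ weights
    if clock.transform == "log_linear_adult":
        m = anti_transform_age(m, clock.adult_age)
    return pd.Series(np.atleast_1d(m), index=matrix.index, name=clock.name)


class AgeResidualizer(BaseEstimator):
    """Residualize clock-predicted ages on chronological age (OLS, per clock).

    A scikit-learn style estimator: ``fit(X, y)`` with ``X`` the chronological
    ages, shape ``(n, 1)`` or ``(n,)``, and ``y`` the predicted biological
    ages, shape ``(n,)`` or ``(n, k)`` for k clocks. ``residuals(X, y)``
    returns ``y - predict(X)``; on the fitting cohort the residuals sum to
    zero and are uncorrelated with chronological age by construction.
    """

    def fit(self, X, y):
        X = self._check_X(X)
        if X.shape[0] < 3:
            raise EstimationError("BAG regression needs at least 3 participants")
        if np.ptp(X) == 0:
            raise EstimationError("chronological ages are all equal; BAG regression is degenerate")
        self.model_ = LinearRegression().fit(X, np.asarray(y, dtype=float))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        return self.model_.predict(self._check_X(X))

    def residuals(self, X, y):
        return np.asarray(y, dtype=float) - self.predict(X)

    @staticmethod
    def _check_X(X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1 or not np.all(np.isfinite(X)):
            raise InputError("chronological age must be a finite 1-column array")
        return X


def compute_bag(predicted: pd.Series, chronological: pd.Series) -> pd.Series:
    """Per-clock biological age gap: OLS residual of predicted on chronological age."""
    if not predicted.index.equals(chronological.index):
        predicted, chronological = predicted.align(chronological, join="inner")
        if predicted.empty:
            raise AlignmentError("predicted and chronological ages share no participants")
    res = AgeResidualizer().fit(chronological, predicted)
    return pd.Series(res.residuals(chronological, predicted),
                     index=predicted.index, name=getattr(predicted, "name", "bag"))


def average_bag(per_clock_residuals: pd.DataFrame | dict) -> pd.Series:
    """Element-wise mean of per-clock residual vectors aligned on participants."""
    if isinstance(per_clock_residuals, dict):
        idx = None
        for name, v in per_clock_residuals.items():
            v = pd.Series(v)
            if idx is not None and not v.index.equals(idx):
                raise AlignmentError(f"residual vector '{name}' is not aligned with the others")
            idx = v.index
        per_clock_residuals = pd.DataFrame(per_clock_residuals)
    return per_clock_residuals.mean(axis=1).rename("bag")


def stratify_bag(bag: pd.Series, k: float = DEFAULT_SD_MULTIPLIER) -> pd.Series:
    """Stratify BAG into accelerated / neutral / decelerated at +/- k sample SD.

    z-scores use the supplied cohort's mean and sample SD (ddof=1); the
    boundary |z| = k belongs to the extreme groups.
    """
    if k <= 0:
        raise InputError("SD multiplier k must be positive")
    bag = pd.Series(bag, dtype=float)
    if len(bag) < 2:
        raise StratificationError("stratification needs at least 2 participants")
    sd = bag.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise StratificationError("BAG sample SD is zero; groups are undefined")
    z = (bag - bag.mean()) / sd
    out = pd.Series("neutral", index=bag.index, dtype=object, name="bio_age_group")
    out[z >= k] = "accelerated"
    out[z <= -k] = "decelerated"
    return out


def compute_bag_table(matrix: pd.DataFrame, clocks: list[ClockModel],
                      chronological: pd.Series,
                      k: float = DEFAULT_SD_MULTIPLIER) -> pd.DataFrame:
    """Apply clocks, residualize, average and stratify in one pass.

    ``matrix`` must have one row per participant (replicates already
    resolved); ``chronological`` is indexed by participant id. Returns a
    table with ``predicted_<clock>``, ``residual_<clock>``, ``bag`` and
    ``bio_age_group`` columns indexed by participant id.
    """
    chron = chronological.reindex(matrix.index)
    if chron.isna().any():
        missing = list(chron.index[chron.isna()][:5])
        raise AlignmentError(f"chronological age missing for participants {missing}")
    out = {}
    residuals = {}
    for clock in clocks:
        pred = apply_clock(matrix, clock)
        out[f"predicted_{clock.name}"] = pred
        residuals[clock.name] = compute_bag(pred, chron)
        out[f"residual_{clock.name}"] = residuals[clock.name]
    bag = average_bag(pd.DataFrame(residuals))
    out["bag"] = bag
    out["bio_age_group"] = stratify_bag(bag, k)
    return pd.DataFrame(out).rename_axis("participant_id")


# ---------------------------------------------------------------------------
# Clock file format: CSV with a '#'-prefixed header block declaring name,
# transform and adult_age, then CpG_id,coefficient rows with the intercept
# stored as the "(Intercept)" row. Published coefficient files in this layout
# can be dropped in; none are bundled.

def write_clock(clock: ClockModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# clock_name: {clock.name}\n")
        fh.write(f"# transform: {clock.transform}\n")
        fh.write(f"# adult_age: {float(clock.adult_age)!r}\n")
        fh.write("CpG_id,coefficient\n")
        fh.write(f"(Intercept),{float(clock.intercept)!r}\n")
        for cpg, coef in clock.coefficients.items():
            fh.write(f"{cpg},{float(coef)!r}\n")


def read_clock(path) -> ClockModel:
    meta = {}
    body = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                body.append(line)
    if "clock_name" not in meta:
        raise InputError(f"clock file {path} lacks a '# clock_name:' header")
    table = pd.read_csv(io.StringIO("".join(body)))
    if list(table.columns) != ["CpG_id", "coefficient"]:
        raise InputError(f"clock file {path} must have columns CpG_id,coefficient")
    is_intercept = table["CpG_id"] == "(Intercept)"
    if is_intercept.sum() != 1:
        raise InputError(f"clock file {path} must contain exactly one (Intercept) row")
    intercept = float(table.loc[is_intercept, "coefficient"].iloc[0])
    coefs = dict(zip(table.loc[~is_intercept, "CpG_id"],
                     table.loc[~is_intercept, "coefficient"].astype(float)))
    return ClockModel(name=meta["clock_name"], intercept=intercept, coefficients=coefs,
                      transform=meta.get("transform", "identity"),
                      adult_age=float(meta.get("adult_age", 20.0)))
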