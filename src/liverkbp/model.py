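"""Knowledge-based OAR constraint models driven by RTL.

The model predicts, for each organ at risk, an achievable dose/volume bound
from a single geometric feature: RTL, the PTV-to-liver volume ratio.  Three
rule families cover the organs:

* normal-liver relative volumes (V5, V10, V20, V30) — ordinary least squares
  on RTL followed by a downward *coverage shift* of the intercept so that at
  least a fraction 1 - q (default 95%) of the historical plans lie on or
  above the line: the bound is achievable for nearly every geometry seen in
  the knowledge cohort;
* kidney mean doses and cord-PRV maximum dose — plain OLS on RTL;
* stomach V20, small-bowel V15, heart mean and esophagus maximum — organs
  whose dose is driven by target position rather than size, modelled as the
  population median, independent of RTL.

The regression primitives are scikit-learn style estimators
(:class:`QuantileShiftedLinearRegression`, :class:`MedianConstantModel`) and
the cohort-level fit is :class:`KnowledgeModelBuilder`; the module-level
functions ``fit_linear`` / ``coverage_shift`` / ``fit_constant`` /
``build_model`` are thin wrappers over them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DomainError, FitError, SchemaError

__all__ = [
    "QuantileShiftedLinearRegression",
    "MedianConstantModel",
    "fit_linear",
    "coverage_shift",
    "fit_constant",
    "MetricSpec",
    "DEFAULT_FITTING_SPEC",
    "ConstraintRule",
    "GeneralSettings",
    "KnowledgeModel",
    "KnowledgeModelBuilder",
    "build_model",
    "load_reference_model",
]


def _as_1d(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 1:
        arr = arr[:, 0]
    if arr.ndim != 1:
        raise FitError(f"expected a single predictor, got shape {arr.shape}")
    return arr


class QuantileShiftedLinearRegression(RegressorMixin, BaseEstimator):
    """OLS line with an optional downward quantile shift of the intercept.

    After fitting y = intercept + slope·x by least squares, the intercept is
    decreased by the k-th smallest residual, k = ceil(q·n), so that at least
    a fraction 1 - q of the training points lie on or above the shifted line.
    This turns a population-average trend into an aspirational constraint
    that was met by (almost) every historical plan.

    Parameters
    ----------
    q : float, default 0.05
        Quantile of training points allowed to fall below the shifted line.
    apply_shift : bool, default True
        If False the estimator is plain OLS and ``shift_`` is 0.

    Attributes
    ----------
    slope_, intercept_ : float
        OLS coefficients (intercept before shifting).
    residuals_ : ndarray
        y - (intercept_ + slope_·x) on the training data.
    shift_ : float
        Signed intercept adjustment (<= 0 when applied).
    shifted_intercept_ : float
        intercept_ + shift_; what :meth:`predict` uses.
    """

    def __init__(self, q: float = 0.05, apply_shift: bool = True):
        self.q = q
        self.apply_shift = apply_shift

    def fit(self, X, y):
        if not 0 < self.q < 0.5:
            raise DomainError(f"q must lie in (0, 0.5), got {self.q}")
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise FitError(f"x and y lengths differ: {x.shape} vs {y.shape}")
        if x.size < 3:
            raise FitError(f"need at least 3 points, got {x.size}")
        if np.ptp(x) == 0:
            raise FitError("predictor is constant; line is unidentifiable")
        design = np.column_stack([np.ones_like(x), x])
        (intercept, slope), *_ = np.linalg.lstsq(design, y, rcond=None)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.coef_ = np.array([self.slope_])
        self.residuals_ = y - (self.intercept_ + self.slope_ * x)
        if self.apply_shift:
            self.shifted_intercept_ = coverage_shift(
                self.intercept_, self.residuals_, self.q
            )
            self.shift_ = self.shifted_intercept_ - self.intercept_
        else:
            self.shift_ = 0.0
            self.shifted_intercept_ = self.intercept_
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        return self.shifted_intercept_ + self.slope_ * _as_1d(X)


class MedianConstantModel(RegressorMixin, BaseEstimator):
    """Constant predictor: the population median (or mean) of the metric.

    Used for organs whose dose depends on where the target sits, not on how
    large it is, so no geometric trend is fitted.
    """

    def __init__(self, central: str = "median"):
        self.central = central

    def fit(self, X, y=None):
        # Accepts fit(values) or the sklearn fit(X, y) signature.
        values = np.asarray(X if y is None else y, dtype=float).ravel()
        if values.size == 0:
            raise FitError("cannot fit a constant to an empty sample")
        if self.central == "median":
            self.value_ = float(np.median(values))
        elif self.central == "mean":
            self.value_ = float(np.mean(values))
        else:
            raise DomainError(f"central must be 'median' or 'mean', got {self.central!r}")
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "value_")
        return np.full(_as_1d(X).shape, self.value_)


def fit_linear(x, y) -> tuple[float, float, np.ndarray]:
    """OLS fit y = intercept + slope·x; returns (slope, intercept, residuals)."""
    est = QuantileShiftedLinearRegression(apply_shift=False).fit(x, y)
    return est.slope_, est.intercept_, est.residuals_


def coverage_shift(intercept: float, residuals, q: float = 0.05) -> float:
    """Intercept after the downward coverage shift.

    The line is lowered by the k-th smallest residual, k = ceil(q·n), which
    guarantees that at least 1 - q of the training points lie on or above it
    for any finite sample.
    """
    if not 0 < q < 0.5:
        raise DomainError(f"q must lie in (0, 0.5), got {q}")
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    if n == 0:
        raise FitError("no residuals supplied")
    if n < 1.0 / q:
        warnings.warn(
            f"only {n} residuals for q={q}: the coverage quantile is poorly estimated",
            stacklevel=2,
        )
    k = math.ceil(q * n)
    # k-th smallest residual; for OLS residuals this is <= 0, so the line
    # moves down (or stays put when the fit is exact).
    return intercept + r[k - 1]


def fit_constant(values, central: str = "median") -> float:
    """Population median (default) or mean of a metric sample."""
    return MedianConstantModel(central=central).fit(values).value_


# ---------------------------------------------------------------------------
# Model structure


@dataclass(frozen=True)
class MetricSpec:
    """How one (organ, metric) is fitted from the cohort table."""

    organ: str
    metric_kind: str  # volume_at_dose | mean | max
    column: str
    unit: str  # '%' or 'cGy'
    model: str  # linear_shift | linear | constant
    priority: str  # high | low
    compromise: bool = True
    dose_gy: float | None = None


#: Default fitting configuration: the 11-organ protocol of the method.
DEFAULT_FITTING_SPEC: tuple[MetricSpec, ...] = (
    MetricSpec("liver_gtv", "volume_at_dose", "liver_gtv_v5_pct", "%", "linear_shift", "high", True, 5.0),
    MetricSpec("liver_gtv", "volume_at_dose", "liver_gtv_v10_pct", "%", "linear_shift", "high", True, 10.0),
    MetricSpec("liver_gtv", "volume_at_dose", "liver_gtv_v20_pct", "%", "linear_shift", "high", True, 20.0),
    MetricSpec("liver_gtv", "volume_at_dose", "liver_gtv_v30_pct", "%", "linear_shift", "high", True, 30.0),
    MetricSpec("left_kidney", "mean", "left_kidney_mean_cgy", "cGy", "linear", "high", True),
    MetricSpec("right_kidney", "mean", "right_kidney_mean_cgy", "cGy", "linear", "high", True),
    MetricSpec("spinal_cord_prv5", "max", "spinal_cord_prv5_max_cgy", "cGy", "linear", "low", True),
    MetricSpec("stomach", "volume_at_dose", "stomach_v20_pct", "%", "constant", "low", True, 20.0),
    MetricSpec("small_bowel", "volume_at_dose", "small_bowel_v15_pct", "%", "constant", "low", True, 15.0),
    MetricSpec("heart", "mean", "heart_mean_cgy", "cGy", "constant", "low", True),
    MetricSpec("esophagus", "max", "esophagus_max_cgy", "cGy", "constant", "low", True),
)


@dataclass(frozen=True)
class ConstraintRule:
    """Per-OAR mapping from RTL to a dose/volume bound plus optimizer metadata.

    ``slope``/``intercept``/``shift`` define a linear bound
    intercept + shift + slope·rtl; a constant rule stores ``value`` instead.
    """

    organ: str
    metric_kind: str
    unit: str
    priority: str
    compromise: bool
    model_type: str  # 'linear' or 'constant'
    dose_gy: float | None = None
    slope: float | None = None
    intercept: float | None = None
    shift: float = 0.0
    value: float | None = None

    def __post_init__(self) -> None:
        if self.metric_kind not in ("volume_at_dose", "mean", "max"):
            raise SchemaError(f"unknown metric kind {self.metric_kind!r}")
        if self.priority not in ("high", "low"):
            raise SchemaError(f"priority must be high|low, got {self.priority!r}")
        if self.model_type == "linear":
            if self.slope is None or self.intercept is None:
                raise SchemaError(f"linear rule for {self.organ} lacks slope/intercept")
            if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
                raise SchemaError(f"non-finite coefficients for {self.organ}")
        elif self.model_type == "constant":
            if self.value is None or not np.isfinite(self.value):
                raise SchemaError(f"constant rule for {self.organ} lacks a finite value")
        else:
            raise SchemaError(f"unknown model type {self.model_type!r}")
        if self.metric_kind == "volume_at_dose" and self.dose_gy is None:
            raise SchemaError(f"volume rule for {self.organ} lacks dose_gy")

    @property
    def key(self) -> tuple[str, str, float | None]:
        return (self.organ, self.metric_kind, self.dose_gy)

    @property
    def metric_label(self) -> str:
        if self.metric_kind == "volume_at_dose":
            return f"V{self.dose_gy:g}"
        return {"mean": "Mean dose", "max": "Maximum dose"}[self.metric_kind]

    def evaluate(self, rtl: float) -> float:
        """Unrounded bound at a given RTL."""
        if rtl <= 0:
            raise DomainError("rtl must be positive")
        if self.model_type == "constant":
            return float(self.value)
        return float(self.intercept + self.shift + self.slope * rtl)


@dataclass(frozen=True)
class GeneralSettings:
    """Optimizer-level settings shared by every patient protocol."""

    tuning_balance_pct: float = 7.0
    dose_falloff_margin_cm: float = 2.6
    hotspot_max_goal_pct: float = 106.0
    use_coldspot_rois: bool = True


@dataclass(frozen=True)
class KnowledgeModel:
    """Ordered constraint rules plus general settings and fit provenance."""

    rules: tuple[ConstraintRule, ...]
    general_settings: GeneralSettings = field(default_factory=GeneralSettings)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.rules]
        if len(keys) != len(set(keys)):
            raise SchemaError("duplicate (organ, metric) rule in model")
        object.__setattr__(self, "rules", tuple(self.rules))

    def rule(self, organ: str, metric_kind: str, dose_gy: float | None = None) -> ConstraintRule:
        for r in self.rules:
            if r.key == (organ, metric_kind, dose_gy):
                return r
        raise KeyError(f"no rule for ({organ}, {metric_kind}, {dose_gy})")


class KnowledgeModelBuilder(BaseEstimator):
    """Fit a :class:`KnowledgeModel` from a cohort table.

    The cohort table has one row per historical patient with columns
    ``patient_id``, ``rtl`` and one column per metric named in the fitting
    spec.  ``fit`` validates the table, dispatches each metric to its rule
    family and stores the result as ``model_``.

    Parameters
    ----------
    spec : sequence of MetricSpec, optional
        Which metrics to fit and how; defaults to the 11-organ protocol.
    q : float, default 0.05
        Coverage quantile for the shifted liver lines.
    central : {'median', 'mean'}, default 'median'
        Location statistic for RTL-independent organs.
    """

    def __init__(
        self,
        spec: Sequence[MetricSpec] | None = None,
        q: float = 0.05,
        central: str = "median",
    ):
        self.spec = spec
        self.q = q
        self.central = central

    def fit(self, cohort: pd.DataFrame, y=None):
        spec = tuple(self.spec) if self.spec is not None else DEFAULT_FITTING_SPEC
        _validate_cohort(cohort, spec)
        rtl = cohort["rtl"].to_numpy(dtype=float)
        rules = []
        for ms in spec:
            values = cohort[ms.column].to_numpy(dtype=float)
            common = dict(
                organ=ms.organ,
                metric_kind=ms.metric_kind,
                unit=ms.unit,
                priority=ms.priority,
                compromise=ms.compromise,
                dose_gy=ms.dose_gy,
            )
            if ms.model == "constant":
                rules.append(
                    ConstraintRule(
                        model_type="constant",
                        value=fit_constant(values, central=self.central),
                        **common,
                    )
                )
            else:
                est = QuantileShiftedLinearRegression(
                    q=self.q, apply_shift=(ms.model == "linear_shift")
                ).fit(rtl, values)
                rules.append(
                    ConstraintRule(
                        model_type="linear",
                        slope=est.slope_,
                        intercept=est.intercept_,
                        shift=est.shift_,
                        **common,
                    )
                )
        self.model_ = KnowledgeModel(
            rules=tuple(rules),
            provenance={
                "cohort_size": int(len(cohort)),
                "coverage_quantile": float(self.q),
                "central": self.central,
            },
        )
        self.n_features_in_ = cohort.shape[1]
        return self

    def predict(self, rtl):
        """Unrounded bounds for each rule at each RTL; shape (n_rtl, n_rules)."""
        check_is_fitted(self, "model_")
        rtl = _as_1d(rtl)
        return np.array([[r.evaluate(x) for r in self.model_.rules] for x in rtl])


def _validate_cohort(cohort: pd.DataFrame, spec: Sequence[MetricSpec]) -> None:
    if "rtl" not in cohort.columns:
        raise SchemaError("cohort table lacks the 'rtl' column")
    if "patient_id" in cohort.columns and cohort["patient_id"].duplicated().any():
        dupes = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise SchemaError(f"duplicated patient_id values: {dupes}")
    if (cohort["rtl"] <= 0).any():
        raise SchemaError("all rtl values must be positive")
    missing = [ms.column for ms in spec if ms.column not in cohort.columns]
    if missing:
        raise SchemaError(f"cohort table missing metric columns: {missing}")


def build_model(
    cohort: pd.DataFrame,
    spec: Sequence[MetricSpec] | None = None,
    q: float = 0.05,
    central: str = "median",
) -> KnowledgeModel:
    """Functional wrapper over :class:`KnowledgeModelBuilder`."""
    return KnowledgeModelBuilder(spec=spec, q=q, central=central).fit(cohort).model_


def load_reference_model() -> KnowledgeModel:
    """The shipped reference model with the published coefficients.

    Liver lines already include the 95% coverage shift (shift stored as 0);
    constants are the knowledge-cohort medians.
    """
    from .io import model_from_json_str

    text = resources.files("liverkbp.data").joinpath("reference_model.json").read_text()
    return model_from_json_str(text)
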