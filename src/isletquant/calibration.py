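"""Fitting and validating diameter -> cell-count models.

:class:`CellCountRegressor` is a scikit-learn-compatible polynomial
regressor (``fit``/``predict``/``score``) whose fitted state exports to
the immutable :class:`~isletquant.model.CellCountModel` used by the rest
of the package. Around it sit the validation statistics used to qualify
such a model: R^2, an extra-sum-of-squares ANCOVA comparing regression
curves across animal groups, Pearson correlation for inter-method
reliability, and CV% for repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import CellCountModel

__all__ = [
    "CalibrationPoint",
    "FitReport",
    "CellCountRegressor",
    "fit_cell_model",
    "r_squared",
    "ancova_compare",
    "AncovaResult",
    "pearson_r",
    "cv_percent",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One (diameter, counted cells) observation, optionally grouped/weighted."""

    diameter: float
    cells: float
    group: str | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.cells < 0:
            raise ValueError("cell count must be nonnegative")
        if self.weight is not None and self.weight <= 0:
            raise ValueError("weight must be positive")


@dataclass(frozen=True)
class FitReport:
    """A fitted model with its goodness-of-fit summary."""

    model: CellCountModel
    r_squared: float
    residual_sd: float
    n_points: int


class CellCountRegressor(RegressorMixin, BaseEstimator):
    """Least-squares polynomial regression of cell count on islet diameter.

    Parameters
    ----------
    degree : int, default 3
        Polynomial degree. A cubic is the standard choice for rat islets.

    Attributes
    ----------
    coef_ : ndarray of shape (degree + 1,)
        Fitted coefficients, highest degree first.
    r_squared_ : float
        Coefficient of determination on the training data,
        ``1 - SSE/SST`` (unweighted).
    residual_sd_ : float
        Residual standard deviation, ``sqrt(SSE / (n - degree - 1))``.
    valid_range_ : tuple of float
        ``(min, max)`` of the training diameters; the exported model
        refuses to extrapolate beyond it.
    n_points_ : int
        Number of training observations.
    """

    def __init__(self, degree: int = 3):
        self.degree = degree

    def fit(self, X, y, sample_weight=None) -> "CellCountRegressor":
        if self.degree < 1:
            raise ValueError("degree must be at least 1")
        d = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if d.shape != y.shape:
            raise ValueError("X and y have mismatched lengths")
        n = d.size
        if n < self.degree + 2:
            raise ValueError(
                f"need at least degree + 2 = {self.degree + 2} points, got {n}"
            )
        if np.unique(d).size < self.degree + 1:
            raise ValueError(
                f"need at least {self.degree + 1} distinct diameters to fit "
                f"a degree-{self.degree} polynomial"
            )
        V = np.vander(d, self.degree + 1)
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
            if w.shape != d.shape or np.any(w <= 0):
                raise ValueError("sample_weight must be positive, one per point")
            coef, *_ = np.linalg.lstsq(V * w[:, None], y * w, rcond=None)
        else:
            coef, *_ = np.linalg.lstsq(V, y, rcond=None)
        fitted = V @ coef
        self.coef_ = coef
        self.r_squared_ = r_squared(y, fitted)
        dof = max(n - (self.degree + 1), 1)
        self.residual_sd_ = float(np.sqrt(np.sum((y - fitted) ** 2) / dof))
        self.valid_range_ = (float(d.min()), float(d.max()))
        self.n_points_ = n
        return self

    def predict(self, X):
        check_is_fitted(self)
        d = np.asarray(X, dtype=float).reshape(-1)
        return np.polyval(self.coef_, d)

    def to_model(
        self, reference_cells_per_ie: float | None = None
    ) -> CellCountModel:
        """Export the fit as a :class:`CellCountModel` clamped to the data range."""
        check_is_fitted(self)
        kwargs = {}
        if reference_cells_per_ie is not None:
            kwargs["reference_cells_per_ie"] = reference_cells_per_ie
        return CellCountModel(
            coefficients=tuple(float(c) for c in self.coef_),
            valid_range=self.valid_range_,
            provenance=f"fitted degree-{self.degree} ({self.n_points_} points)",
            **kwargs,
        )


def fit_cell_model(
    points: Sequence[CalibrationPoint],
    degree: int = 3,
    weighted: bool = False,
) -> FitReport:
    """Fit a polynomial cell-count model to calibration points.

    With ``weighted=True`` each point's ``weight`` field (e.g. a category
    sample size when fitting published means) multiplies its squared
    residual in the loss.
    """
    d = np.array([p.diameter for p in points])
    y = np.array([p.cells for p in points])
    w = None
    if weighted:
        w = np.array([1.0 if p.weight is None else p.weight for p in points])
    reg = CellCountRegressor(degree=degree).fit(d, y, sample_weight=w)
    return FitReport(
        model=reg.to_model(),
        r_squared=reg.r_squared_,
        residual_sd=reg.residual_sd_,
        n_points=reg.n_points_,
    )


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, ``1 - SSE/SST``."""
    o = np.asarray(observed, dtype=float).reshape(-1)
    p = np.asarray(predicted, dtype=float).reshape(-1)
    if o.shape != p.shape or o.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant observed values")
    sse = float(np.sum((o - p) ** 2))
    return 1.0 - sse / sst


@dataclass(frozen=True)
class AncovaResult:
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    groups: tuple[str, ...]
    n_points: int
    max_diameter: float


def _group_sse(d: np.ndarray, y: np.ndarray, degree: int) -> float:
    V = np.vander(d, degree + 1)
    coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    return float(np.sum((y - V @ coef) ** 2))


def ancova_compare(
    groups: Mapping[str, Sequence[CalibrationPoint]],
    max_diameter: float = 250.0,
    degree: int = 3,
) -> AncovaResult:
    """Test whether diameter -> cell-count curves differ between groups.

    Extra-sum-of-squares F-test of one pooled degree-``degree`` curve
    against separate curves per group (all coefficients free), restricted
    to diameters up to ``max_diameter`` — the comparison is of whole
    regression curves, not slopes alone. Points above ``max_diameter``
    are excluded before fitting (large islets are absent in young
    animals, so the shared support ends there).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    per_group: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for label, pts in groups.items():
        d = np.array([p.diameter for p in pts if p.diameter <= max_diameter])
        y = np.array([p.cells for p in pts if p.diameter <= max_diameter])
        if d.size < degree + 2 or np.unique(d).size < degree + 1:
            raise ValueError(
                f"group {label!r} has too few points (<= {max_diameter} um) "
                f"for a degree-{degree} fit"
            )
        per_group[label] = (d, y)

    d_all = np.concatenate([d for d, _ in per_group.values()])
    y_all = np.concatenate([y for _, y in per_group.values()])
    sse_pooled = _group_sse(d_all, y_all, degree)
    sse_separate = sum(_group_sse(d, y, degree) for d, y in per_group.values())

    n, g, p = d_all.size, len(per_group), degree + 1
    df_num = (g - 1) * p
    df_den = n - g * p
    if df_den <= 0:
        raise ValueError("not enough points for per-group fits")
    # guard against tiny negative numerator from round-off
    f_stat = max(sse_pooled - sse_separate, 0.0) / df_num / (sse_separate / df_den)
    p_value = float(stats.f.sf(f_stat, df_num, df_den))
    return AncovaResult(
        f_statistic=float(f_stat),
        df_num=df_num,
        df_den=df_den,
        p_value=p_value,
        groups=tuple(per_group),
        n_points=n,
        max_diameter=max_diameter,
    )


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation between two measurement series."""
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


def cv_percent(replicates) -> float:
    """Coefficient of variation, ``100 * sample SD / mean`` (n-1 denominator)."""
    r = np.asarray(replicates, dtype=float).reshape(-1)
    if r.size < 2:
        raise ValueError("need at least two replicates")
    mean = float(r.mean())
    if mean <= 0:
        raise ValueError("CV%% undefined for nonpositive mean")
    return 100.0 * float(r.std(ddof=1)) / mean
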