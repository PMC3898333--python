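"""Diameter-to-cell-number conversion model and IE comparison curves.

The conversion model is a cubic polynomial fitted to computer-assisted
cytometer counts of dissociated rat islets,

    cells(d) = c3 d^3 + c2 d^2 + c1 d + c0,

valid for measured diameters between 20 and 350 um. Because the cell
count grows more slowly than the diameter cube, cells-per-IE falls with
islet size: sphere-based IE systematically overstates the tissue content
of large islets, and the comparison curves here quantify by how much.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from . import published
from .geometry import BinningScheme, IsletRecord, ie_exact

__all__ = [
    "CellCountModel",
    "kansas_rat_2012",
    "predict_cells",
    "total_cells",
    "cells_per_ie",
    "ie_implied_cells",
    "overestimation_ratio",
]

#: Below this diameter the published cubic dips (minimum near 36 um) and
#: predictions, while positive, are weakly supported by data.
LOW_DIAMETER_WARNING_UM = 40.0

EstimatorName = Literal["exact_sphere", "ricordi_binned", "density_expectation"]


@dataclass(frozen=True)
class CellCountModel:
    """Polynomial diameter (um) -> cell count model with a validity range.

    Coefficients are ordered highest degree first. Requests outside
    ``valid_range`` raise rather than extrapolate: a fitted cubic turns
    negative not far below its calibration range.
    """

    coefficients: tuple[float, ...]
    valid_range: tuple[float, float] = published.KANSAS_RAT_2012_RANGE
    reference_cells_per_ie: float = published.REFERENCE_CELLS_PER_IE
    provenance: str = "user"

    def __post_init__(self) -> None:
        lo, hi = self.valid_range
        if not (0 <= lo < hi):
            raise ValueError(f"invalid diameter range [{lo}, {hi}]")
        if len(self.coefficients) < 1:
            raise ValueError("model needs at least one coefficient")
        if self.reference_cells_per_ie <= 0:
            raise ValueError("reference_cells_per_ie must be positive")
        grid = np.linspace(lo, hi, 1024)
        if np.any(np.polyval(self.coefficients, grid) <= 0):
            raise ValueError(
                f"model predicts nonpositive cell counts inside [{lo}, {hi}]"
            )

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def with_range(self, lo: float, hi: float) -> "CellCountModel":
        return replace(self, valid_range=(float(lo), float(hi)))


def kansas_rat_2012() -> CellCountModel:
    """The built-in published rat conversion model (20–350 um)."""
    return CellCountModel(
        coefficients=published.KANSAS_RAT_2012_COEFFS,
        valid_range=published.KANSAS_RAT_2012_RANGE,
        reference_cells_per_ie=published.REFERENCE_CELLS_PER_IE,
        provenance="kansas-rat-2012",
    )


def _check_range(model: CellCountModel, d: np.ndarray | float) -> None:
    lo, hi = model.valid_range
    d = np.asarray(d, dtype=float)
    if np.any((d < lo) | (d > hi)):
        bad = np.atleast_1d(d)[(np.atleast_1d(d) < lo) | (np.atleast_1d(d) > hi)]
        raise ValueError(
            f"diameter(s) {bad.tolist()} um outside the model's valid range "
            f"[{lo}, {hi}] um; the model does not extrapolate"
        )
    if np.any(d < LOW_DIAMETER_WARNING_UM):
        warnings.warn(
            f"cell-count predictions below {LOW_DIAMETER_WARNING_UM:g} um lie "
            "below the model's non-monotone dip and are weakly constrained",
            stacklevel=3,
        )


def predict_cells(model: CellCountModel, d: float | np.ndarray) -> float | np.ndarray:
    """Predicted cell count of an islet of diameter ``d`` um."""
    _check_range(model, d)
    out = np.polyval(model.coefficients, np.asarray(d, dtype=float))
    return float(out) if np.isscalar(d) or np.ndim(d) == 0 else out


def total_cells(model: CellCountModel, islets: Sequence[IsletRecord]) -> float:
    """Summed predicted cell count over a preparation.

    Additive over concatenated lists; raises listing the offending islet
    ids if any diameter falls outside the model range.
    """
    lo, hi = model.valid_range
    bad = [
        islet.islet_id if islet.islet_id is not None else f"islet_{i}"
        for i, islet in enumerate(islets)
        if not (lo <= islet.diameter <= hi)
    ]
    if bad:
        raise ValueError(
            f"islet(s) {bad} outside the model's valid range [{lo}, {hi}] um"
        )
    if not islets:
        return 0.0
    diameters = np.array([islet.diameter for islet in islets])
    return float(np.sum(predict_cells(model, diameters)))


def cells_per_ie(model: CellCountModel, d: float) -> float:
    """Measured-model cell count per islet equivalent at diameter ``d``.

    A flat curve at the reference value would mean IE tracks cell mass
    exactly; the observed curve declines with diameter.
    """
    if d <= 0:
        raise ValueError("cells per IE undefined at zero diameter")
    return float(predict_cells(model, d)) / ie_exact(d)


def ie_implied_cells(
    d: float,
    reference_cells_per_ie: float = published.REFERENCE_CELLS_PER_IE,
    estimator: EstimatorName = "exact_sphere",
    scheme: BinningScheme | None = None,
) -> float:
    """Cell count the IE framework implies for an islet of diameter ``d``.

    Under the sphere assumption with uniform cell size, an islet of
    ``k`` IE holds ``k`` times the reference count. ``estimator``
    selects how the islet's IE is computed: individually from the sphere
    formula, or via a binned scheme's factor for the bin containing
    ``d`` (producing the characteristic step curves).
    """
    if estimator == "exact_sphere":
        return reference_cells_per_ie * ie_exact(d)
    if scheme is None:
        scheme = (
            BinningScheme.conventional()
            if estimator == "ricordi_binned"
            else BinningScheme.refined()
        )
    edges = np.asarray(scheme.bin_edges)
    if not (edges[0] <= d < edges[-1]):
        raise ValueError(
            f"diameter {d} um outside the binning scheme's range "
            f"[{edges[0]}, {edges[-1]}) um"
        )
    idx = int(np.searchsorted(edges, d, side="right")) - 1
    return reference_cells_per_ie * float(scheme.factors[idx])


def overestimation_ratio(
    model: CellCountModel,
    d: float,
    estimator: EstimatorName = "exact_sphere",
    scheme: BinningScheme | None = None,
    measured_cells: float | None = None,
) -> float:
    """IE-implied cell count over the measured (model) count at ``d``.

    Ratios above 1 mean the IE framework credits the islet with more
    tissue than its cells support; the ratio grows with diameter. Pass
    ``measured_cells`` to use a directly counted value in place of the
    model prediction (e.g. a published category mean).
    """
    implied = ie_implied_cells(
        d, model.reference_cells_per_ie, estimator=estimator, scheme=scheme
    )
    actual = (
        float(measured_cells)
        if measured_cells is not None
        else float(predict_cells(model, d))
    )
    if actual <= 0:
        raise ValueError("measured cell count must be positive")
    return implied / actual
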