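"""Islet volume math and islet-equivalent (IE) estimators.

One IE is the volume of a perfect sphere of 150 um diameter,
(pi/6)*150^3 ~= 1.77e6 um^3. Two families of estimators are provided:

* **exact** — each islet's diameter is converted to IE individually via
  the sphere formula, ``ie_exact``;
* **binned** — islets are tallied in diameter categories (conventionally
  50-um increments) and each category count is multiplied by a fixed
  conversion factor, ``ie_binned``. The conventional factors arise from
  averaging the edge cubes of each bin (``endpoint_mean_factor``); the
  refined variant replaces that average with the expected cube under an
  assumed within-bin diameter density (``density_expectation_factor``),
  which corrects the conventional factors downward for any decreasing
  density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "IE_REFERENCE_DIAMETER",
    "IE_REFERENCE_VOLUME",
    "IsletRecord",
    "BinningScheme",
    "IEResult",
    "sphere_volume",
    "ellipsoid_volume",
    "ie_exact",
    "endpoint_mean_factor",
    "midpoint_cube_factor",
    "density_expectation_factor",
    "ie_binned",
]

#: Diameter (um) of the reference islet defining 1 IE.
IE_REFERENCE_DIAMETER = 150.0

#: Volume (um^3) of 1 IE: (pi/6) * 150^3 ~= 1.77e6.
IE_REFERENCE_VOLUME = math.pi / 6.0 * IE_REFERENCE_DIAMETER**3

FactorRule = Literal[
    "endpoint_mean", "midpoint_cube", "density_expectation", "explicit_table"
]


@dataclass(frozen=True)
class IsletRecord:
    """A single measured islet.

    Irregular islets carry two to four diameter measurements taken at
    different locations; the working diameter is their arithmetic mean.
    """

    diameter_measurements: tuple[float, ...]
    islet_id: str | None = None
    counted_cells: float | None = None

    def __post_init__(self) -> None:
        if not self.diameter_measurements:
            raise ValueError("at least one diameter measurement is required")
        if any(d <= 0 for d in self.diameter_measurements):
            raise ValueError(
                f"islet {self.islet_id!r}: diameters must be strictly positive, "
                f"got {self.diameter_measurements}"
            )
        if self.counted_cells is not None and self.counted_cells < 0:
            raise ValueError("counted_cells must be nonnegative")

    @property
    def diameter(self) -> float:
        """Mean of the recorded diameter measurements (um)."""
        return float(np.mean(self.diameter_measurements))

    @classmethod
    def from_diameter(
        cls,
        diameter: float,
        islet_id: str | None = None,
        counted_cells: float | None = None,
    ) -> "IsletRecord":
        return cls((float(diameter),), islet_id=islet_id, counted_cells=counted_cells)


def _check_nonnegative(value: float, name: str) -> float:
    value = float(value)
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value}")
    return value


def sphere_volume(d: float) -> float:
    """Volume (um^3) of a sphere with diameter ``d`` um: (pi/6) d^3."""
    d = _check_nonnegative(d, "diameter")
    return math.pi / 6.0 * d**3


def ellipsoid_volume(a: float, b: float, c: float) -> float:
    """Volume (um^3) of an ellipsoid with full axis lengths ``a, b, c`` um.

    Equals ``sphere_volume(a)`` when the three axes coincide. Isolated
    islets are typically oblate, with mean axis ratios b/a = 0.82 and
    c/a = 0.60 rather than the sphere's 1:1:1.
    """
    a = _check_nonnegative(a, "axis a")
    b = _check_nonnegative(b, "axis b")
    c = _check_nonnegative(c, "axis c")
    return math.pi / 6.0 * a * b * c


def ie_exact(d: float) -> float:
    """Islet equivalents of a single islet of diameter ``d`` um.

    ``(d/150)^3``, i.e. its sphere volume over the 1-IE reference volume.
    """
    d = _check_nonnegative(d, "diameter")
    return (d / IE_REFERENCE_DIAMETER) ** 3


def endpoint_mean_factor(lo: float, hi: float) -> float:
    """Conventional IE conversion factor for the diameter bin [lo, hi].

    The mean of the edge cubes over the reference cube,
    ``(lo^3 + hi^3) / (2 * 150^3)``; applied to 50-um bins it reproduces
    the conventional published factor table. By convexity of d^3 this
    factor over-weights large diameters within the bin.
    """
    lo = _check_nonnegative(lo, "lo")
    hi = float(hi)
    if hi < lo:
        raise ValueError(f"bin edges out of order: lo={lo} > hi={hi}")
    return (lo**3 + hi**3) / (2.0 * IE_REFERENCE_DIAMETER**3)


def midpoint_cube_factor(lo: float, hi: float) -> float:
    """IE factor using the cube of the bin midpoint, ``((lo+hi)/2)^3 / 150^3``."""
    lo = _check_nonnegative(lo, "lo")
    if hi < lo:
        raise ValueError(f"bin edges out of order: lo={lo} > hi={hi}")
    return ((lo + hi) / 2.0) ** 3 / IE_REFERENCE_DIAMETER**3


def density_expectation_factor(
    lo: float,
    hi: float,
    density: Callable[[float], float] | float | None = None,
) -> float:
    """Refined IE factor: expected diameter cube under a within-bin density.

    ``E[d^3] / 150^3`` with the expectation taken over the density
    restricted to ``[lo, hi]`` and renormalized. ``density`` may be a
    callable (unnormalized density of diameter), ``None`` for the uniform
    density on the bin, or a number, interpreted as a point mass at that
    diameter (in which case the factor equals ``ie_exact`` there).

    For any strictly decreasing (or uniform) density on a nondegenerate
    bin the result lies below :func:`endpoint_mean_factor` — the
    "downward correction" of the refined method.
    """
    lo = _check_nonnegative(lo, "lo")
    hi = float(hi)
    if hi < lo:
        raise ValueError(f"bin edges out of order: lo={lo} > hi={hi}")

    if isinstance(density, (int, float)):
        point = float(density)
        if not (lo <= point <= hi):
            raise ValueError(f"point mass {point} outside bin [{lo}, {hi}]")
        return ie_exact(point)

    if lo == hi:
        return ie_exact(lo)

    if density is None:
        # closed form: E[d^3] = (hi^4 - lo^4) / (4 (hi - lo))
        expected_cube = (hi**4 - lo**4) / (4.0 * (hi - lo))
        return expected_cube / IE_REFERENCE_DIAMETER**3

    mass, _ = integrate.quad(density, lo, hi)
    if mass <= 0:
        raise ValueError(f"density has nonpositive mass {mass} on [{lo}, {hi}]")
    third_moment, _ = integrate.quad(lambda x: x**3 * density(x), lo, hi)
    return third_moment / mass / IE_REFERENCE_DIAMETER**3


def _derive_factors(
    edges: np.ndarray,
    rule: FactorRule,
    density: Callable[[float], float] | None,
) -> np.ndarray:
    pairs = zip(edges[:-1], edges[1:])
    if rule == "endpoint_mean":
        return np.array([endpoint_mean_factor(lo, hi) for lo, hi in pairs])
    if rule == "midpoint_cube":
        return np.array([midpoint_cube_factor(lo, hi) for lo, hi in pairs])
    if rule == "density_expectation":
        return np.array(
            [density_expectation_factor(lo, hi, density) for lo, hi in pairs]
        )
    raise ValueError(f"cannot derive factors for rule {rule!r}")


@dataclass(frozen=True)
class BinningScheme:
    """Ordered diameter bins with one IE conversion factor per bin.

    Bins are half-open ``[lo, hi)``: a 100-um islet falls in the 100–150
    bin. Islets below ``minimum_countable_diameter`` are excluded from
    binned totals (reported, never silently dropped).
    """

    bin_edges: tuple[float, ...]
    factors: tuple[float, ...]
    rule: FactorRule = "explicit_table"
    minimum_countable_diameter: float = 50.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        factors = np.asarray(self.factors, dtype=float)
        if edges.size < 2:
            raise ValueError("need at least two bin edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if factors.size != edges.size - 1:
            raise ValueError(
                f"{factors.size} factors for {edges.size - 1} bins"
            )
        if not np.all(factors > 0):
            raise ValueError("factors must be positive")
        if not np.all(np.diff(factors) > 0):
            raise ValueError("factors must be strictly increasing across bins")

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_labels(self) -> list[str]:
        return [
            f"{lo:g}-{hi:g}"
            for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
        ]

    @classmethod
    def conventional(
        cls,
        d_min: float = 50.0,
        d_max: float = 350.0,
        width: float = 50.0,
        minimum_countable_diameter: float | None = None,
    ) -> "BinningScheme":
        """Conventional scheme: ``width``-um bins, endpoint-mean factors."""
        edges = tuple(np.arange(d_min, d_max + width / 2, width, dtype=float))
        factors = tuple(_derive_factors(np.asarray(edges), "endpoint_mean", None))
        return cls(
            edges,
            factors,
            rule="endpoint_mean",
            minimum_countable_diameter=(
                d_min if minimum_countable_diameter is None
                else minimum_countable_diameter
            ),
        )

    @classmethod
    def refined(
        cls,
        d_min: float = 50.0,
        d_max: float = 350.0,
        width: float = 50.0,
        density: Callable[[float], float] | None = None,
        minimum_countable_diameter: float | None = None,
    ) -> "BinningScheme":
        """Refined scheme: factors from the within-bin density expectation.

        The default (``density=None``) assumes a uniform diameter density
        within each bin, which already corrects the conventional factors
        downward; pass a decreasing density for a stronger correction.
        """
        edges = np.arange(d_min, d_max + width / 2, width, dtype=float)
        factors = tuple(_derive_factors(edges, "density_expectation", density))
        return cls(
            tuple(edges),
            factors,
            rule="density_expectation",
            minimum_countable_diameter=(
                d_min if minimum_countable_diameter is None
                else minimum_countable_diameter
            ),
        )

    @classmethod
    def from_factor_table(
        cls,
        bin_edges: Sequence[float],
        factors: Sequence[float],
        minimum_countable_diameter: float = 50.0,
    ) -> "BinningScheme":
        """Scheme with explicitly transcribed factors (e.g. a published table)."""
        return cls(
            tuple(float(e) for e in bin_edges),
            tuple(float(f) for f in factors),
            rule="explicit_table",
            minimum_countable_diameter=minimum_countable_diameter,
        )


@dataclass(frozen=True)
class IEResult:
    """Outcome of an IE estimation over a preparation."""

    total_ie: float
    method: str
    per_bin_counts: dict[str, int] = field(default_factory=dict)
    per_islet_ie: tuple[float, ...] | None = None
    excluded_islets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.total_ie < 0:
            raise ValueError("total IE must be nonnegative")


def ie_total_exact(islets: Sequence[IsletRecord]) -> IEResult:
    """Exact-sphere IE total: each islet converted individually."""
    per_islet = tuple(ie_exact(islet.diameter) for islet in islets)
    return IEResult(
        total_ie=float(sum(per_islet)),
        method="exact_sphere",
        per_islet_ie=per_islet,
    )


def ie_binned(
    islets: Sequence[IsletRecord],
    scheme: BinningScheme,
    overflow: Literal["error", "extrapolate"] = "error",
) -> IEResult:
    """Binned IE total under a :class:`BinningScheme`.

    Each islet at or above the scheme's minimum countable diameter is
    assigned to exactly one half-open bin ``[lo, hi)`` and the total is
    ``sum(count_i * factor_i)``. Islets below the minimum are listed in
    ``excluded_islets``. Diameters at or above the last edge raise by
    default; with ``overflow="extrapolate"`` they are placed in extended
    bins of the same width whose factors follow the endpoint-mean rule.
    """
    edges = list(scheme.bin_edges)
    factors = list(scheme.factors)
    width = edges[-1] - edges[-2]
    labels = scheme.bin_labels()
    counts: dict[str, int] = dict.fromkeys(labels, 0)
    excluded: list[str] = []
    total = 0.0

    for idx, islet in enumerate(islets):
        d = islet.diameter
        name = islet.islet_id if islet.islet_id is not None else f"islet_{idx}"
        if d < scheme.minimum_countable_diameter:
            excluded.append(name)
            continue
        while d >= edges[-1]:
            if overflow == "error":
                raise ValueError(
                    f"islet {name!r} diameter {d} um is at or above the last "
                    f"bin edge {edges[-1]} um (set overflow='extrapolate' to "
                    f"extend the scheme)"
                )
            lo, hi = edges[-1], edges[-1] + width
            edges.append(hi)
            factors.append(endpoint_mean_factor(lo, hi))
            labels.append(f"{lo:g}-{hi:g}")
            counts[labels[-1]] = 0
        if d < edges[0]:
            # countable but below the first edge (minimum set under the scheme)
            excluded.append(name)
            continue
        bin_idx = int(np.searchsorted(edges, d, side="right")) - 1
        counts[labels[bin_idx]] += 1
        total += factors[bin_idx]

    return IEResult(
        total_ie=total,
        method=f"binned_{scheme.rule}",
        per_bin_counts=counts,
        excluded_islets=tuple(excluded),
    )
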