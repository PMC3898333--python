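"""Synthetic islet preparations, calibration data, and assay readouts.

The generator reproduces the statistical structure of the published rat
calibration study so every analysis routine can be exercised without
measured data:

* **calibration** — per-islet cell counts at the 12 published diameter
  categories, normal within category with SD reconstructed from the
  published SEMs (SD = SEM * sqrt(n)) and per-category sample sizes
  totalling 577 islets;
* **preparations** — diameters from the category allocation or a
  lognormal size distribution, true cell counts drawn around the
  published cubic (or the category means) with diameter-interpolated
  category SDs, from a mean-preserving positive (gamma) distribution,
  floored at one cell;
* **counting experiments** — paired noisy observations of category mean
  counts for two counting methods with given CV%;
* **assay groups** — small (<= 100 um) vs large (>= 200 um) islet
  experiments whose readouts are sums of true cells times a per-cell
  analyte content, optionally drifting with diameter (the content
  "size effect" that makes per-cell and per-IE comparisons disagree in
  sign).

All randomness flows through an explicit seed or ``numpy.random.Generator``;
identical configuration and seed give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import published
from .calibration import CalibrationPoint
from .geometry import IsletRecord
from .model import CellCountModel, kansas_rat_2012
from .normalization import AssayGroup, AssayReplicate

__all__ = [
    "SyntheticPrepConfig",
    "SyntheticPrep",
    "category_noise_sd",
    "simulate_calibration_points",
    "simulate_prep",
    "simulate_counting_experiment",
    "AssaySimConfig",
    "simulate_assay_groups",
]

_CATEGORY_DIAMETERS = np.array([c.diameter_um for c in published.CELL_COUNT_CATEGORIES])
_CATEGORY_MEANS = np.array([c.mean_cells for c in published.CELL_COUNT_CATEGORIES])
_CATEGORY_SDS = np.array([c.sd_cells for c in published.CELL_COUNT_CATEGORIES])
_CATEGORY_NS = np.array([c.n_islets for c in published.CELL_COUNT_CATEGORIES])


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def category_noise_sd(d: float | np.ndarray) -> np.ndarray:
    """Per-islet cell-count SD at diameter ``d`` um.

    Linear interpolation of the category SDs (SEM * sqrt(n)) between the
    published category diameters, held flat beyond the first and last
    category.
    """
    return np.interp(np.asarray(d, dtype=float), _CATEGORY_DIAMETERS, _CATEGORY_SDS)


def simulate_calibration_points(
    seed: int | np.random.Generator,
    category_scale: float = 1.0,
) -> list[CalibrationPoint]:
    """Per-islet calibration data replicating the published category table.

    For each of the 12 diameter categories, draws ``n_i`` cell counts
    from ``Normal(mean_i, SEM_i * sqrt(n_i))`` at the category diameter
    (577 points in total), truncated at one cell. ``category_scale``
    scales every category's sample size (rounded, min 1) for
    smaller/larger studies.
    """
    rng = _as_rng(seed)
    points: list[CalibrationPoint] = []
    for cat in published.CELL_COUNT_CATEGORIES:
        n = max(1, round(cat.n_islets * category_scale))
        counts = rng.normal(cat.mean_cells, cat.sd_cells, size=n)
        counts = np.maximum(counts, 1.0)
        points.extend(
            CalibrationPoint(diameter=cat.diameter_um, cells=float(c))
            for c in counts
        )
    return points


@dataclass(frozen=True)
class SyntheticPrepConfig:
    """Configuration of a simulated islet preparation.

    The default size distribution replays the published per-category
    allocation (577 islets across 50–325 um). The lognormal alternative
    (median 90 um, sigma_log 0.45, truncated to ``support``) is a
    generic small-islet-heavy preparation profile, not a published
    distribution. ``count_noise_scale`` multiplies the interpolated
    category SDs (0 disables count noise).
    """

    n_islets: int = published.TOTAL_CALIBRATION_ISLETS
    size_distribution: Literal["table_allocation", "lognormal"] = "table_allocation"
    count_center: Literal["model", "category_means"] = "model"
    lognormal_median_um: float = 90.0
    lognormal_sigma_log: float = 0.45
    support: tuple[float, float] = (50.0, 350.0)
    count_noise_scale: float = 1.0
    shape_axis_ratios: tuple[float, float] = published.ELLIPSOID_AXIS_RATIOS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_islets <= 0:
            raise ValueError("n_islets must be positive")
        if self.count_noise_scale < 0:
            raise ValueError("count_noise_scale must be nonnegative")
        lo, hi = self.support
        mlo, mhi = published.KANSAS_RAT_2012_RANGE
        if not (mlo <= lo < hi <= mhi):
            raise ValueError(
                f"size support [{lo}, {hi}] must lie within the model "
                f"range [{mlo}, {mhi}]"
            )


@dataclass(frozen=True)
class SyntheticPrep:
    """A simulated preparation: observed records plus hidden truth."""

    islets: tuple[IsletRecord, ...]
    true_cells: tuple[float, ...]
    config: SyntheticPrepConfig

    @property
    def diameters(self) -> np.ndarray:
        return np.array([islet.diameter for islet in self.islets])


def _draw_diameters(config: SyntheticPrepConfig, rng: np.random.Generator) -> np.ndarray:
    if config.size_distribution == "table_allocation":
        probs = _CATEGORY_NS / _CATEGORY_NS.sum()
        if config.n_islets == int(_CATEGORY_NS.sum()):
            counts = _CATEGORY_NS
        else:
            counts = rng.multinomial(config.n_islets, probs)
        return np.repeat(_CATEGORY_DIAMETERS, counts)
    lo, hi = config.support
    mu = np.log(config.lognormal_median_um)
    out = np.empty(config.n_islets)
    filled = 0
    while filled < config.n_islets:  # rejection-sample the truncation
        draw = rng.lognormal(mu, config.lognormal_sigma_log, size=config.n_islets)
        keep = draw[(draw >= lo) & (draw <= hi)][: config.n_islets - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _noisy_counts(
    expected: np.ndarray, sd: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Counts with mean ``expected`` and SD ``sd``, gamma-distributed.

    A gamma with shape ``(mean/sd)^2`` keeps counts positive while
    preserving the target mean exactly, so readouts proportional to true
    cells stay unbiased per modeled cell; a clamped normal would inflate
    the mean wherever SD is comparable to the mean (the 50-um category).
    """
    cells = expected.astype(float).copy()
    noisy = sd > 0
    if np.any(noisy):
        shape = (expected[noisy] / sd[noisy]) ** 2
        scale = sd[noisy] ** 2 / expected[noisy]
        cells[noisy] = rng.gamma(shape, scale)
    return np.maximum(cells, 1.0)


def simulate_prep(
    config: SyntheticPrepConfig,
    model: CellCountModel | None = None,
) -> SyntheticPrep:
    """Simulate one preparation under ``config``.

    True cell counts are drawn around the ``model`` (default: the
    published cubic) evaluated at each diameter — or, with
    ``count_center="category_means"``, around the diameter-interpolated
    published category means — with the diameter-interpolated category
    SD, from a mean-preserving gamma, floored at one cell.
    """
    if model is None:
        model = kansas_rat_2012()
    rng = np.random.default_rng(config.seed)
    diameters = _draw_diameters(config, rng)
    if config.count_center == "category_means":
        expected = np.interp(diameters, _CATEGORY_DIAMETERS, _CATEGORY_MEANS)
    else:
        expected = np.polyval(model.coefficients, diameters)
    sd = config.count_noise_scale * category_noise_sd(diameters)
    cells = _noisy_counts(expected, np.broadcast_to(sd, expected.shape), rng)
    islets = tuple(
        IsletRecord.from_diameter(d, islet_id=f"sim_{i}", counted_cells=float(c))
        for i, (d, c) in enumerate(zip(diameters, cells))
    )
    return SyntheticPrep(islets=islets, true_cells=tuple(map(float, cells)), config=config)


def simulate_counting_experiment(
    prep: SyntheticPrep,
    cv_percent_a: float,
    cv_percent_b: float,
    seed: int | np.random.Generator,
    category_edges: Sequence[float] = (50.0, 100.0, 150.0, 200.0, 250.0, 300.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired noisy category-mean counts from two counting methods.

    Islets are grouped into half-open diameter categories ``[e_i, e_{i+1})``
    and each method observes every category's true mean cell count with
    multiplicative normal noise of the given CV%. Returns
    ``(category_diameters, counts_a, counts_b)`` for the non-empty
    categories, suitable for a Pearson inter-method correlation.
    """
    if cv_percent_a < 0 or cv_percent_b < 0:
        raise ValueError("CV% must be nonnegative")
    rng = _as_rng(seed)
    edges = np.asarray(category_edges, dtype=float)
    d = prep.diameters
    cells = np.asarray(prep.true_cells)
    idx = np.searchsorted(edges, d, side="right") - 1
    valid = (idx >= 0) & (d < edges[-1])
    mids, truths = [], []
    for i in range(edges.size - 1):
        mask = valid & (idx == i)
        if mask.any():
            mids.append(float(edges[i]))
            truths.append(cells[mask].mean())
    truths = np.asarray(truths)
    obs_a = truths * (1.0 + cv_percent_a / 100.0 * rng.normal(size=truths.size))
    obs_b = truths * (1.0 + cv_percent_b / 100.0 * rng.normal(size=truths.size))
    return np.asarray(mids), obs_a, obs_b


@dataclass(frozen=True)
class AssaySimConfig:
    """Small-vs-large assay simulation settings.

    Defaults mirror the published experiment structure: 20 replicate
    experiments per size class, at least 50 small islets (50–100 um) and
    20 large islets (200–300 um) per experiment, per-cell DNA content
    6.05 pg with experiment-level SD 0.69. ``size_effect`` tilts the
    per-cell content linearly with diameter (fractional change per
    150 um, zero for size-independent analytes such as DNA).
    """

    analyte: str = "dna_pg"
    content_mean: float = published.DNA_PG_PER_CELL[0]
    content_sd: float = published.DNA_PG_PER_CELL[1]
    n_experiments: int = 20
    islets_per_small_experiment: int = 50
    islets_per_large_experiment: int = 20
    small_range: tuple[float, float] = (50.0, published.SMALL_ISLET_MAX_DIAMETER)
    large_range: tuple[float, float] = (published.LARGE_ISLET_MIN_DIAMETER, 300.0)
    size_effect: float = 0.0
    count_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.small_range[1] > self.large_range[0]:
            raise ValueError("small and large size ranges must be disjoint")
        if self.content_sd < 0 or self.content_mean <= 0:
            raise ValueError("content mean must be positive, SD nonnegative")
        mlo, mhi = published.KANSAS_RAT_2012_RANGE
        for lo, hi in (self.small_range, self.large_range):
            if not (mlo <= lo < hi <= mhi):
                raise ValueError("size ranges must lie within the model range")


def _content_at(config: AssaySimConfig, base: float, d: np.ndarray) -> np.ndarray:
    profile = 1.0 + config.size_effect * (d - 150.0) / 150.0
    return np.maximum(base * profile, 0.0)


def simulate_assay_groups(
    config: AssaySimConfig,
    model: CellCountModel | None = None,
) -> tuple[AssayGroup, AssayGroup]:
    """Simulate paired small- and large-islet assay group readouts.

    Each experiment draws its islet diameters uniformly within the size
    class range, its true cell counts from the model plus category
    noise, and a per-experiment per-cell content from
    ``Normal(content_mean, content_sd)`` (truncated positive). The
    replicate readout is the sum over islets of true cells times the
    (possibly diameter-tilted) content; DNA totals from true cells are
    attached for per-DNA normalization.
    """
    if model is None:
        model = kansas_rat_2012()
    rng = np.random.default_rng(config.seed)
    groups = []
    for label, (lo, hi), n_islets in (
        ("small", config.small_range, config.islets_per_small_experiment),
        ("large", config.large_range, config.islets_per_large_experiment),
    ):
        reps = []
        for _ in range(config.n_experiments):
            d = rng.uniform(lo, hi, size=n_islets)
            expected = np.polyval(model.coefficients, d)
            sd = config.count_noise_scale * category_noise_sd(d)
            cells = _noisy_counts(expected, sd, rng)
            base = rng.normal(config.content_mean, config.content_sd)
            while base <= 0:
                base = rng.normal(config.content_mean, config.content_sd)
            readout = float(np.sum(cells * _content_at(config, base, d)))
            dna_total = float(np.sum(cells * published.DNA_PG_PER_CELL[0]))
            reps.append(
                AssayReplicate(
                    readout_total=readout,
                    islets=tuple(
                        IsletRecord.from_diameter(di, counted_cells=float(ci))
                        for di, ci in zip(d, cells)
                    ),
                    dna_total=dna_total,
                )
            )
        groups.append(
            AssayGroup(
                label=label,
                replicates=tuple(reps),
                readout_units=config.analyte,
                size_range=(lo, hi),
            )
        )
    return groups[0], groups[1]
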