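"""Assay normalization per IE, per cell, or per DNA.

Whether "analyte per islet material" differs between small and large
islets depends on the denominator. Because cells-per-IE declines with
islet diameter, dividing a readout by IE inflates the apparent content
of small islets relative to large ones even when the per-cell content is
identical; dividing by modeled cell number (or measured DNA) does not.
These helpers normalize replicate-level readouts on a chosen basis and
compare two size groups with a Student's t test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .geometry import BinningScheme, IsletRecord, ie_binned, ie_total_exact
from .model import CellCountModel, total_cells

__all__ = [
    "AssayReplicate",
    "AssayGroup",
    "NormalizedReadout",
    "ComparisonResult",
    "normalize_group",
    "compare_groups",
    "denominator_for_protein_mass",
]

Basis = Literal["ie", "cell", "dna"]


@dataclass(frozen=True)
class AssayReplicate:
    """One experiment: a pooled islet group and its total readout."""

    readout_total: float
    islets: tuple[IsletRecord, ...]
    dna_total: float | None = None

    def __post_init__(self) -> None:
        if self.readout_total < 0:
            raise ValueError("readout_total must be nonnegative")
        if self.dna_total is not None and self.dna_total < 0:
            raise ValueError("dna_total must be nonnegative")


@dataclass(frozen=True)
class AssayGroup:
    """Replicated assay experiments on one islet size class.

    ``size_range``, when given, is enforced on every islet (e.g.
    small: diameter <= 100 um; large: diameter >= 200 um).
    """

    label: str
    replicates: tuple[AssayReplicate, ...]
    readout_units: str = "arbitrary"
    size_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.size_range is not None:
            lo, hi = self.size_range
            for rep in self.replicates:
                for islet in rep.islets:
                    if not (lo <= islet.diameter <= hi):
                        raise ValueError(
                            f"group {self.label!r}: islet diameter "
                            f"{islet.diameter} um outside size class [{lo}, {hi}]"
                        )


@dataclass(frozen=True)
class NormalizedReadout:
    """Per-replicate normalized values and their summary."""

    label: str
    basis: Basis
    per_replicate: tuple[float, ...]
    mean: float
    sem: float
    units: str


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group comparison of normalized readouts."""

    label_a: str
    label_b: str
    basis: Basis
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int
    welch: bool = False


def _replicate_denominator(
    rep: AssayReplicate,
    basis: Basis,
    model: CellCountModel | None,
    estimator: str,
    scheme: BinningScheme | None,
) -> float:
    if basis == "dna":
        if rep.dna_total is None:
            raise ValueError("basis='dna' requires dna_total on every replicate")
        return rep.dna_total
    if basis == "cell":
        if model is None:
            raise ValueError("basis='cell' requires a cell-count model")
        return total_cells(model, rep.islets)
    if basis == "ie":
        if estimator == "exact_sphere":
            return ie_total_exact(rep.islets).total_ie
        if scheme is None:
            scheme = (
                BinningScheme.refined()
                if estimator == "density_expectation"
                else BinningScheme.conventional()
            )
        return ie_binned(rep.islets, scheme, overflow="extrapolate").total_ie
    raise ValueError(f"unknown basis {basis!r}")


def normalize_group(
    group: AssayGroup,
    basis: Basis,
    model: CellCountModel | None = None,
    estimator: str = "ricordi_binned",
    scheme: BinningScheme | None = None,
) -> NormalizedReadout:
    """Readout per IE, per modeled cell, or per unit DNA, replicate-wise.

    The group denominator for ``basis="ie"`` defaults to the conventional
    binned estimator — what a wet lab records — with ``"exact_sphere"``
    and ``"density_expectation"`` as alternatives. Mean and SEM are taken
    across replicates (experiments), not across islets.
    """
    if not group.replicates:
        raise ValueError(f"group {group.label!r} has no replicates")
    values = []
    for rep in group.replicates:
        denom = _replicate_denominator(rep, basis, model, estimator, scheme)
        if denom <= 0:
            raise ValueError(
                f"group {group.label!r}: zero denominator on basis {basis!r}"
            )
        values.append(rep.readout_total / denom)
    arr = np.asarray(values)
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return NormalizedReadout(
        label=group.label,
        basis=basis,
        per_replicate=tuple(values),
        mean=float(arr.mean()),
        sem=sem,
        units=f"{group.readout_units}/{basis}",
    )


def compare_groups(
    a: AssayGroup,
    b: AssayGroup,
    basis: Basis,
    model: CellCountModel | None = None,
    estimator: str = "ricordi_binned",
    scheme: BinningScheme | None = None,
    welch: bool = False,
) -> ComparisonResult:
    """Student's t test between two groups' normalized readouts.

    Pooled-variance two-sample t test on the per-replicate normalized
    values (Welch's correction available via ``welch=True``).
    """
    norm_a = normalize_group(a, basis, model=model, estimator=estimator, scheme=scheme)
    norm_b = normalize_group(b, basis, model=model, estimator=estimator, scheme=scheme)
    if len(norm_a.per_replicate) < 2 or len(norm_b.per_replicate) < 2:
        raise ValueError("need at least two replicates per group")
    t_stat, p_value = stats.ttest_ind(
        norm_a.per_replicate, norm_b.per_replicate, equal_var=not welch
    )
    return ComparisonResult(
        label_a=a.label,
        label_b=b.label,
        basis=basis,
        mean_a=norm_a.mean,
        sem_a=norm_a.sem,
        mean_b=norm_b.mean,
        sem_b=norm_b.sem,
        t_statistic=float(t_stat),
        p_value=float(p_value),
        n_a=len(norm_a.per_replicate),
        n_b=len(norm_b.per_replicate),
        welch=welch,
    )


def denominator_for_protein_mass(
    protein_per_unit: float | AssayGroup,
    target_mass_ug: float,
    basis: Basis = "ie",
    model: CellCountModel | None = None,
    estimator: str = "ricordi_binned",
) -> float:
    """Islet material (IE or cells) needed to supply ``target_mass_ug`` protein.

    ``protein_per_unit`` is the protein content in ug per IE or per cell
    (convert ng/cell to ug/cell first), or an :class:`AssayGroup` whose
    replicate readouts are protein masses in ug, in which case the
    group's mean per-unit content is used.
    """
    if isinstance(protein_per_unit, AssayGroup):
        per_unit = normalize_group(
            protein_per_unit, basis, model=model, estimator=estimator
        ).mean
    else:
        per_unit = float(protein_per_unit)
    if target_mass_ug < 0:
        raise ValueError("target mass must be nonnegative")
    if per_unit <= 0:
        raise ValueError("protein content per unit must be positive")
    return target_mass_ug / per_unit
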