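"""Published rat-islet reference data.

Category summaries of computer-assisted cytometer cell counts per islet
(12 diameter categories, 8 animals), the fitted cubic conversion
coefficients, and per-cell analyte contents. These constants parameterize
the built-in ``kansas-rat-2012`` conversion model and the synthetic-data
generator.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

#: Cubic coefficients (highest degree first) of the published rat
#: diameter (um) -> cells-per-islet regression, at full printed precision.
KANSAS_RAT_2012_COEFFS: tuple[float, float, float, float] = (
    -0.0001,
    0.0912,
    -6.2162,
    182.1125,
)

#: Valid diameter range (um) of the published conversion model.
KANSAS_RAT_2012_RANGE: tuple[float, float] = (20.0, 350.0)

#: Measured mean cell count of a 150-um (1 IE) islet.
REFERENCE_CELLS_PER_IE: float = 943.0


class CategorySummary(NamedTuple):
    """Mean cell count per islet in one 25-um diameter category."""

    diameter_um: float
    n_islets: int
    mean_cells: float
    sem_cells: float

    @property
    def sd_cells(self) -> float:
        """Per-islet SD reconstructed as SEM * sqrt(n)."""
        return self.sem_cells * np.sqrt(self.n_islets)


#: Cell number per islet by diameter category (mean +/- SEM, n), 577 islets.
CELL_COUNT_CATEGORIES: tuple[CategorySummary, ...] = (
    CategorySummary(50.0, 259, 92.0, 11.0),
    CategorySummary(75.0, 48, 188.0, 15.0),
    CategorySummary(100.0, 40, 322.0, 24.0),
    CategorySummary(125.0, 36, 642.0, 48.0),
    CategorySummary(150.0, 33, 943.0, 60.0),
    CategorySummary(175.0, 46, 1308.0, 68.0),
    CategorySummary(200.0, 42, 1674.0, 91.0),
    CategorySummary(225.0, 31, 2099.0, 94.0),
    CategorySummary(250.0, 21, 2731.0, 137.0),
    CategorySummary(275.0, 7, 2831.0, 216.0),
    CategorySummary(300.0, 5, 3586.0, 689.0),
    CategorySummary(325.0, 9, 4003.0, 506.0),
)

#: Total islets across the categories above.
TOTAL_CALIBRATION_ISLETS: int = sum(c.n_islets for c in CELL_COUNT_CATEGORIES)

#: Mean measured ellipsoid axis ratios of isolated islets (b/a, c/a).
ELLIPSOID_AXIS_RATIOS: tuple[float, float] = (0.82, 0.60)

#: Total DNA per islet cell, pg (mean, SD across experiments).
DNA_PG_PER_CELL: tuple[float, float] = (6.05, 0.69)

#: Total protein per islet cell, ng (mean, SEM across experiments).
PROTEIN_NG_PER_CELL: tuple[float, float] = (0.58, 0.06)

#: Size-class boundaries used for the small/large assay comparisons (um).
SMALL_ISLET_MAX_DIAMETER: float = 100.0
LARGE_ISLET_MIN_DIAMETER: float = 200.0
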