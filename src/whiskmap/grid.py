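"""Stimulation-grid geometry in Bregma-aligned stereotaxic coordinates.

The photostimulation grid is 6 columns x 8 rows covering 3.9 x 5.0 mm of the
left hemisphere. Columns span the mediolateral (ML) axis from the midline
(0 mm) to 3.9 mm lateral; rows span the anteroposterior (AP) axis from
+2.5 mm (anterior to Bregma, row 0) to -2.5 mm (posterior, row 7). Anterior
and lateral are positive. The exact origin is configurable; these defaults
place every reported hotspot inside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

__all__ = ["StimGrid"]


@dataclass(frozen=True)
class StimGrid:
    """Geometry of the cortical photostimulation grid."""

    n_rows: int = 8
    n_cols: int = 6
    ml_extent_mm: float = 3.9
    ap_extent_mm: float = 5.0
    #: AP coordinate (mm, anterior positive) of row 0.
    ap_origin_mm: float = 2.5

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid needs at least 2 rows and 2 columns")
        if self.ml_extent_mm <= 0 or self.ap_extent_mm <= 0:
            raise ValueError("grid extents must be positive")

    @property
    def n_sites(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def ml_coords(self) -> np.ndarray:
        """ML coordinate (mm) of each column, medial to lateral."""
        return np.linspace(0.0, self.ml_extent_mm, self.n_cols)

    @property
    def ap_coords(self) -> np.ndarray:
        """AP coordinate (mm) of each row, anterior to posterior."""
        return np.linspace(
            self.ap_origin_mm, self.ap_origin_mm - self.ap_extent_mm, self.n_rows
        )

    def site_coord(self, row: int, col: int) -> tuple[float, float]:
        """(ml_mm, ap_mm) of a grid site."""
        return float(self.ml_coords[col]), float(self.ap_coords[row])

    def nearest_site(self, ml_mm: float, ap_mm: float) -> tuple[int, int]:
        """Grid site whose center is closest to a stereotaxic coordinate."""
        col = int(np.argmin(np.abs(self.ml_coords - ml_mm)))
        row = int(np.argmin(np.abs(self.ap_coords - ap_mm)))
        return row, col

    def sites(self) -> Iterator[tuple[int, int]]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield row, col

    def coord_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(ml, ap) coordinate arrays, each of shape (n_rows, n_cols)."""
        ml = np.broadcast_to(self.ml_coords, (self.n_rows, self.n_cols)).copy()
        ap = np.broadcast_to(self.ap_coords[:, None], (self.n_rows, self.n_cols)).copy()
        return ml, ap

    def anterior_mask(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) mask of sites strictly anterior to Bregma."""
        _, ap = self.coord_grids()
        return ap > 0.0

    def posterior_mask(self) -> np.ndarray:
        """Sites at or posterior to Bregma (AP <= 0 is assigned posterior)."""
        return ~self.anterior_mask()
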