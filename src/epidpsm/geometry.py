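"""Panel geometry and the central-axis convention shared across the package.

Coordinates are physical millimetres at the isocenter plane with the origin at
the panel centre.  Crossplane is +x along increasing column index; inplane is
+y along increasing row index (beam's-eye view).  For panels with an even
number of pixels along an axis there is no pixel exactly on the axis; the
"central-axis value" of an array is then the mean over the central 2x2 block
(2x1/1x2 for mixed parity), which every normalization in the package uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PanelGeometry", "central_axis_value"]


@dataclass(frozen=True)
class PanelGeometry:
    """Active-area geometry of a flat-panel imager.

    Parameters
    ----------
    n_rows, n_cols
        Pixel counts (rows = inplane, columns = crossplane).
    active_width_mm
        Crossplane active width at the isocenter plane.  The pixel pitch is
        ``active_width_mm / n_cols`` and is shared by both axes.

    Notes
    -----
    The full-scale dosimetry panel is 1190 x 1190 pixels over 400 mm
    (pitch ~0.336 mm); the package's desk-scale default is 238 x 238 over the
    same 400 mm (1/5 linear scale).
    """

    n_rows: int
    n_cols: int
    active_width_mm: float = 400.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("pixel counts must be positive")
        if not self.active_width_mm > 0:
            raise ValueError("active_width_mm must be positive")

    @property
    def pixel_pitch_mm(self) -> float:
        return self.active_width_mm / self.n_cols

    @property
    def active_height_mm(self) -> float:
        return self.pixel_pitch_mm * self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def x_mm(self) -> np.ndarray:
        """Crossplane pixel-centre coordinates, one per column."""
        return (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.pixel_pitch_mm

    def y_mm(self) -> np.ndarray:
        """Inplane pixel-centre coordinates, one per row."""
        return (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.pixel_pitch_mm

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) pixel-centre coordinate arrays of shape ``(n_rows, n_cols)``."""
        return np.meshgrid(self.x_mm(), self.y_mm())

    def central_block(self) -> tuple[slice, slice]:
        """Row/column slices of the central-axis block.

        2 pixels wide on an even-sized axis, 1 on an odd-sized axis.
        """
        return (_axis_block(self.n_rows), _axis_block(self.n_cols))

    def central_roi(self, halfwidth_px: int) -> tuple[slice, slice]:
        """ROI: the central-axis block expanded by ``halfwidth_px`` per side.

        ``2*halfwidth_px + 1`` pixels on an odd-sized axis, ``+ 2`` on an
        even-sized one — in both cases symmetric about the physical panel
        centre, which matters because an off-centre averaging ROI would
        masquerade as beam tilt in grid samples.
        """
        if halfwidth_px < 0:
            raise ValueError("halfwidth_px must be >= 0")
        rs, cs = self.central_block()
        rows = slice(rs.start - halfwidth_px, rs.stop + halfwidth_px)
        cols = slice(cs.start - halfwidth_px, cs.stop + halfwidth_px)
        if rows.start < 0 or cols.start < 0 or rows.stop > self.n_rows or cols.stop > self.n_cols:
            raise ValueError("ROI exceeds panel")
        return rows, cols

    def scaled(self, factor: int) -> "PanelGeometry":
        """Same physical panel at 1/factor linear pixel resolution."""
        return PanelGeometry(self.n_rows // factor, self.n_cols // factor, self.active_width_mm)


def _axis_block(n: int) -> slice:
    return slice(n // 2 - 1, n // 2 + 1) if n % 2 == 0 else slice(n // 2, n // 2 + 1)


def central_axis_value(values: np.ndarray, geometry: PanelGeometry, exclude: np.ndarray | None = None) -> float:
    """Central-axis value of a 2D array: mean over the central block.

    ``exclude`` marks pixels (e.g. dead ones) that must not enter the mean;
    all-excluded blocks are an error because every normalization anchors here.
    """
    rs, cs = geometry.central_block()
    block = np.asarray(values, dtype=float)[rs, cs]
    if exclude is not None:
        keep = ~np.asarray(exclude, dtype=bool)[rs, cs]
        if not keep.any():
            raise ValueError("central-axis block is entirely excluded")
        return float(block[keep].mean())
    return float(block.mean())
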