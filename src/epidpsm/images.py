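"""In-memory containers: portal images, pixel-sensitivity maps, beam responses.

The multiplicative image model underlying the whole package is

    raw = B * S

where ``B`` is the beam-response (what a perfectly uniform panel would record
of the beam) and ``S`` is the pixel-sensitivity map (per-pixel relative gain).
Both are dimensionless, normalized to 1 on the central axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import PanelGeometry, central_axis_value

__all__ = ["EpidImage", "Psm", "BeamResponse", "IMAGE_KINDS"]

IMAGE_KINDS = ("raw", "corrected", "flood")

#: tolerance for the "central-axis value equals 1" container invariant
_CAX_TOL = 1e-9


@dataclass
class EpidImage:
    """A 2D portal image with panel geometry and acquisition metadata.

    ``kind`` distinguishes raw images (flood correction removed, so the beam
    profile is present), vendor-style flood-corrected images, and flood
    fields themselves.  ``meta`` carries acquisition provenance (beam label,
    field, panel offset, dose rate, noise, seed) as plain JSON-able values.
    """

    values: np.ndarray
    geometry: PanelGeometry
    kind: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError(
                f"image shape {self.values.shape} does not match geometry {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if np.any(self.values < 0):
            raise ValueError("image values must be non-negative")
        if self.kind not in IMAGE_KINDS:
            raise ValueError(f"unknown image kind {self.kind!r}")

    def central_axis_value(self) -> float:
        return central_axis_value(self.values, self.geometry)


@dataclass
class Psm:
    """Pixel-sensitivity map ``S``: per-pixel relative gain, central axis = 1.

    Dead pixels hold value 0 and are flagged in ``dead_mask``; they are
    excluded from every statistic downstream.  ``normalization`` is
    ``"central_axis"`` (the default contract) or ``"none"`` for
    intermediate, unnormalized maps used by the dose-rate analysis.
    """

    values: np.ndarray
    geometry: PanelGeometry
    dead_mask: np.ndarray | None = None
    normalization: str = "central_axis"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError("PSM shape does not match geometry")
        if self.dead_mask is None:
            self.dead_mask = np.zeros(self.geometry.shape, dtype=bool)
        else:
            self.dead_mask = np.asarray(self.dead_mask, dtype=bool)
            if self.dead_mask.shape != self.geometry.shape:
                raise ValueError("dead mask shape does not match geometry")
        live = self.values[~self.dead_mask]
        if not (np.all(np.isfinite(live)) and np.all(live > 0)):
            raise ValueError("non-dead PSM values must be finite and strictly positive")
        if self.normalization not in ("central_axis", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "central_axis":
            cax = central_axis_value(self.values, self.geometry, exclude=self.dead_mask)
            if abs(cax - 1.0) > _CAX_TOL:
                raise ValueError(f"central-axis value {cax} != 1 for a central_axis-normalized PSM")

    def central_axis_value(self) -> float:
        return central_axis_value(self.values, self.geometry, exclude=self.dead_mask)


@dataclass
class BeamResponse:
    """Beam-response ``B``: the beam's image on an ideal uniform panel.

    ``source`` records provenance: ``direct_fit`` (surface fit to directly
    measured grid samples), ``derived_from_psm`` (raw image divided by a
    PSM) or ``external`` (supplied from outside, e.g. a radiation-transport
    calculation).  ``interpolated_mask`` flags pixels filled from neighbours
    (dead-pixel repair) when derived from a PSM.
    """

    values: np.ndarray
    geometry: PanelGeometry
    source: str = "external"
    interpolated_mask: np.ndarray | None = None
    normalization: str = "central_axis"
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.shape:
            raise ValueError("beam-response shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beam-response values must be finite")
        if self.source not in ("direct_fit", "derived_from_psm", "external"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.interpolated_mask is not None:
            self.interpolated_mask = np.asarray(self.interpolated_mask, dtype=bool)
            if self.interpolated_mask.shape != self.geometry.shape:
                raise ValueError("interpolated mask shape does not match geometry")
        if self.normalization not in ("central_axis", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "central_axis":
            cax = central_axis_value(self.values, self.geometry)
            if abs(cax - 1.0) > _CAX_TOL:
                raise ValueError(f"central-axis value {cax} != 1 for a normalized beam-response")

    def central_axis_value(self) -> float:
        return central_axis_value(self.values, self.geometry)
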