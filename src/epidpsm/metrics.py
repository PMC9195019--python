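"""Comparison metrics: deviation maps/statistics/histograms, profiles,
IEC-976 point-ratio symmetry and flatness.

The headline comparison statistic throughout the package is the *median*
percent deviation over a named region of interest: mean and standard
deviation are reported too but are sensitive to the extreme values that
dead pixels, field edges and the collimator shadow produce, so every
statistics record names its ROI and mask explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PanelGeometry
from .images import BeamResponse, EpidImage, Psm

__all__ = [
    "DeviationMap",
    "DeviationStats",
    "Histogram",
    "Profile",
    "SymmetryResult",
    "percent_deviation",
    "deviation_stats",
    "deviation_histogram",
    "crossplane_profile",
    "inplane_profile",
    "symmetry_point_ratio",
    "flatness",
    "symmetry_of",
]


@dataclass
class DeviationMap:
    """2D percent deviation of a target field from a reference field."""

    values: np.ndarray  # percent
    valid_mask: np.ndarray
    geometry: PanelGeometry
    reference_label: str = "reference"
    target_label: str = "target"


@dataclass(frozen=True)
class DeviationStats:
    """Mean/median/SD percent deviation over a named ROI."""

    mean_pct: float
    median_pct: float
    sd_pct: float
    roi: str
    n_pixels: int
    n_excluded: int


@dataclass(frozen=True)
class Histogram:
    """Fixed-bin histogram of a deviation map with explicit overflow counts."""

    bin_edges: np.ndarray  # percent, strictly increasing
    counts: np.ndarray  # int, len = len(bin_edges) - 1
    underflow: int
    overflow: int

    @property
    def total(self) -> int:
        return int(self.counts.sum()) + self.underflow + self.overflow


@dataclass(frozen=True)
class Profile:
    """A 1D profile with physical positions attached."""

    positions_mm: np.ndarray
    values: np.ndarray
    axis: str = "crossplane"

    def __post_init__(self) -> None:
        if len(self.positions_mm) != len(self.values):
            raise ValueError("positions and values must be aligned")


@dataclass(frozen=True)
class SymmetryResult:
    """IEC-976 point-ratio symmetry per plane (>= 100 by convention)."""

    inplane_pct: float
    crossplane_pct: float
    region_halfwidth_mm: float
    label: str = ""


def _unpack(obj):
    """(values, invalid_mask, geometry, label) from any field-like object."""
    if isinstance(obj, Psm):
        return obj.values, obj.dead_mask.copy(), obj.geometry, obj.label or "psm"
    if isinstance(obj, BeamResponse):
        mask = np.zeros(obj.geometry.shape, bool)
        return obj.values, mask, obj.geometry, obj.label or obj.source
    if isinstance(obj, EpidImage):
        return obj.values, np.zeros(obj.geometry.shape, bool), obj.geometry, obj.kind
    raise TypeError(f"cannot compare object of type {type(obj).__name__}")


def percent_deviation(target, reference, *, target_label: str | None = None,
                      reference_label: str | None = None) -> DeviationMap:
    """Per-pixel percent deviation ``100 * (target - reference) / reference``.

    Pixels that are dead/invalid in either input, or where the reference is
    non-positive, are flagged invalid (value 0) and excluded downstream.
    """
    t, t_bad, t_geo, t_lab = _unpack(target)
    r, r_bad, r_geo, r_lab = _unpack(reference)
    if t_geo != r_geo:
        raise ValueError("target and reference have different panel geometries")
    valid = ~(t_bad | r_bad) & (r > 0) & np.isfinite(t) & np.isfinite(r)
    values = np.zeros_like(t)
    values[valid] = 100.0 * (t[valid] - r[valid]) / r[valid]
    return DeviationMap(
        values, valid, t_geo,
        reference_label=reference_label or r_lab,
        target_label=target_label or t_lab,
    )


def roi_mask(geometry: PanelGeometry, roi: str | np.ndarray, roi_halfwidth_mm: float = 150.0):
    """(mask, descriptor) for a named or explicit region of interest."""
    if isinstance(roi, np.ndarray):
        if roi.shape != geometry.shape:
            raise ValueError("ROI mask shape does not match geometry")
        return roi.astype(bool), "custom"
    if roi == "full":
        return np.ones(geometry.shape, bool), "full-panel"
    if roi == "central":
        X, Y = geometry.grid_mm()
        mask = (np.abs(X) <= roi_halfwidth_mm) & (np.abs(Y) <= roi_halfwidth_mm)
        return mask, f"central±{roi_halfwidth_mm:g}mm"
    raise ValueError(f"unknown ROI {roi!r}")


def deviation_stats(dmap: DeviationMap, roi: str | np.ndarray = "central",
                    roi_halfwidth_mm: float = 150.0) -> DeviationStats:
    """Mean/median/sample-SD of a deviation map over valid ROI pixels.

    The default ROI is the central 300 x 300 mm square, which stays inside
    the directly measured extent of the grid method; ``roi='full'`` pools the
    whole panel (extrapolated corners included) and is reported separately,
    never silently.
    """
    mask, desc = roi_mask(dmap.geometry, roi, roi_halfwidth_mm)
    sel = mask & dmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("empty ROI: no valid pixels")
    v = dmap.values[sel]
    sd = float(np.std(v, ddof=1)) if n > 1 else 0.0
    return DeviationStats(
        mean_pct=float(np.mean(v)),
        median_pct=float(np.median(v)),
        sd_pct=sd,
        roi=desc,
        n_pixels=n,
        n_excluded=int(mask.sum()) - n,
    )


def deviation_histogram(dmap: DeviationMap, bin_width_pct: float = 0.1,
                        range_pct: tuple[float, float] = (-5.0, 5.0)) -> Histogram:
    """Histogram of valid deviation values with explicit under/overflow bins."""
    if bin_width_pct <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = range_pct
    if not hi > lo:
        raise ValueError("empty histogram range")
    n_bins = int(round((hi - lo) / bin_width_pct))
    edges = lo + np.arange(n_bins + 1) * bin_width_pct
    edges[-1] = hi  # guard against accumulation error at the top edge
    v = dmap.values[dmap.valid_mask]
    counts, _ = np.histogram(v, bins=edges)
    underflow = int(np.sum(v < edges[0]))
    overflow = int(np.sum(v > edges[-1]))
    return Histogram(edges, counts, underflow, overflow)


def crossplane_profile(field, averaging_halfwidth_px: int = 1) -> Profile:
    """Central-axis crossplane profile: mean over the central rows.

    The central rows are the central-axis block (two rows on even-sized
    panels, one on odd) expanded by ``averaging_halfwidth_px`` on each side.
    """
    values, bad, geometry, _ = _unpack(field)
    return _axis_profile(values, bad, geometry, averaging_halfwidth_px, axis="crossplane")


def inplane_profile(field, averaging_halfwidth_px: int = 1) -> Profile:
    """Central-axis inplane profile (column direction analogue)."""
    values, bad, geometry, _ = _unpack(field)
    return _axis_profile(values, bad, geometry, averaging_halfwidth_px, axis="inplane")


def _axis_profile(values, bad, geometry, halfwidth, axis):
    rs, _ = geometry.central_block()
    if axis == "inplane":
        values = values.T
        bad = bad.T
        _, cs = geometry.central_block()
        rs = cs
        positions = geometry.y_mm()
        n_rows = geometry.n_cols
    else:
        positions = geometry.x_mm()
        n_rows = geometry.n_rows
    start = rs.start - halfwidth
    stop = rs.stop + halfwidth
    if start < 0 or stop > n_rows:
        raise ValueError("averaging halfwidth exceeds the panel")
    band = values[start:stop]
    band_bad = bad[start:stop]
    if band_bad.any():
        weights = (~band_bad).astype(float)
        denom = weights.sum(axis=0)
        if np.any(denom == 0):
            raise ValueError("profile band has columns with no valid pixels")
        prof = (band * weights).sum(axis=0) / denom
    else:
        prof = band.mean(axis=0)
    return Profile(positions, prof, axis=axis)


def _region_halfwidth(profile: Profile, region_halfwidth_mm, field_width_mm, region_fraction):
    if region_halfwidth_mm is not None:
        return float(region_halfwidth_mm)
    if field_width_mm is not None:
        return region_fraction * field_width_mm / 2.0
    extent = min(-profile.positions_mm.min(), profile.positions_mm.max())
    return region_fraction * extent


def symmetry_point_ratio(
    profile: Profile,
    region_halfwidth_mm: float | None = None,
    *,
    field_width_mm: float | None = None,
    region_fraction: float = 0.8,
    step_mm: float = 1.0,
) -> float:
    """IEC-976 point-ratio symmetry over mirrored position pairs, in percent.

    ``100 * max over x in [0, R] of max(P(x)/P(-x), P(-x)/P(x))`` with the
    profile linearly interpolated at ``step_mm`` steps.  Always >= 100;
    exactly 100 for a mirror-symmetric profile.  The evaluation region R is
    either given directly, or as a fraction of the field width, or as a
    fraction of the profile extent.
    """
    if not 0 < region_fraction <= 1:
        raise ValueError("region_fraction must lie in (0, 1]")
    region = _region_halfwidth(profile, region_halfwidth_mm, field_width_mm, region_fraction)
    xs = np.arange(0.0, region + 1e-9, step_mm)
    p_pos = np.interp(xs, profile.positions_mm, profile.values)
    p_neg = np.interp(-xs, profile.positions_mm, profile.values)
    if np.any(p_pos <= 0) or np.any(p_neg <= 0):
        raise ValueError("profile has non-positive values inside the symmetry region")
    ratios = np.maximum(p_pos / p_neg, p_neg / p_pos)
    return float(100.0 * np.max(ratios))


def flatness(
    profile: Profile,
    region_halfwidth_mm: float | None = None,
    *,
    field_width_mm: float | None = None,
    region_fraction: float = 0.8,
) -> float:
    """Profile flatness ``100 * (max - min) / (max + min)`` over the region.

    Provided for completeness: an aSi panel over-responds to the low-energy
    part of the spectrum and exaggerates flattened-beam horns, so this
    number is not comparable to a dose-to-water flatness without conversion.
    """
    region = _region_halfwidth(profile, region_halfwidth_mm, field_width_mm, region_fraction)
    sel = np.abs(profile.positions_mm) <= region + 1e-9
    v = profile.values[sel]
    if v.size == 0:
        raise ValueError("empty flatness region")
    if np.any(v <= 0):
        raise ValueError("profile has non-positive values inside the flatness region")
    return float(100.0 * (v.max() - v.min()) / (v.max() + v.min()))


def symmetry_of(field, region_halfwidth_mm: float, *, averaging_halfwidth_px: int = 1,
                label: str = "") -> SymmetryResult:
    """Point-ratio symmetry of a 2D field in both planes."""
    cross = symmetry_point_ratio(
        crossplane_profile(field, averaging_halfwidth_px), region_halfwidth_mm
    )
    inpl = symmetry_point_ratio(
        inplane_profile(field, averaging_halfwidth_px), region_halfwidth_mm
    )
    return SymmetryResult(inplane_pct=inpl, crossplane_pct=cross,
                          region_halfwidth_mm=region_halfwidth_mm, label=label)
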