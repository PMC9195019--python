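"""Flood-field handling, PSM/beam-response decomposition and the grid method.

The decomposition model is multiplicative: a raw portal image (flood
correction removed) factorizes as ``raw = B * S``.  Dividing out either
factor recovers the other; both are renormalized to the central axis.  The
grid method measures ``B`` directly: a small field is stepped over a grid of
off-axis nodes and each node is imaged twice, panel centred and panel
shifted, so that the same physical pixels read the beam at the node and at
the origin.  The per-pixel ratio cancels pixel sensitivity exactly; a smooth
surface fitted to the node samples yields ``B`` on every pixel, and the PSM
follows by division.  Outside the sampled extent the surface is an
extrapolation and is flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import RectBivariateSpline

from .geometry import PanelGeometry, central_axis_value
from .images import BeamResponse, EpidImage, Psm
from .simulator import GridPlan

__all__ = [
    "DIVISION_FLOOR",
    "GridSamples",
    "SurfaceFit",
    "remove_flood",
    "apply_flood",
    "psm_from_beam_response",
    "beam_response_from_psm",
    "grid_sample_beam_response",
    "fit_beam_response_surface",
    "grid_calibrate",
    "radial_average",
]

#: relative floor below which divisor pixels are flagged invalid instead of divided
DIVISION_FLOOR = 0.05


def _check_geometry(a, b) -> None:
    if a.geometry != b.geometry:
        raise ValueError("operands have different panel geometries")


# ---------------------------------------------------------------------------
# flood-field operators


def remove_flood(image: EpidImage, flood: EpidImage, dead_mask: np.ndarray | None = None) -> EpidImage:
    """Undo the vendor flood-field correction, leaving the raw image.

    ``raw = corrected * flood / CAX(flood)`` — the exact inverse of
    :func:`apply_flood`.  Non-positive flood pixels outside the dead mask are
    an error (they cannot have produced a corrected image).
    """
    _check_geometry(image, flood)
    if image.kind != "corrected" or flood.kind != "flood":
        raise ValueError("remove_flood expects a corrected image and a flood image")
    _check_flood_positive(flood, dead_mask)
    cax = flood.central_axis_value()
    values = image.values * flood.values / cax
    return EpidImage(values, image.geometry, kind="raw", meta=dict(image.meta))


def apply_flood(raw: EpidImage, flood: EpidImage, dead_mask: np.ndarray | None = None) -> EpidImage:
    """Vendor-style flood-field correction: ``corrected = raw / flood * CAX(flood)``.

    Removes the beam profile together with the panel non-uniformity — the
    behaviour the PSM decomposition exists to avoid.  Dead pixels (mask or
    zero flood signal) propagate as zeros.
    """
    _check_geometry(raw, flood)
    if raw.kind != "raw" or flood.kind != "flood":
        raise ValueError("apply_flood expects a raw image and a flood image")
    _check_flood_positive(flood, dead_mask)
    cax = flood.central_axis_value()
    dead = np.zeros(raw.geometry.shape, bool) if dead_mask is None else np.asarray(dead_mask, bool)
    values = np.zeros_like(raw.values)
    live = ~dead
    values[live] = raw.values[live] / flood.values[live] * cax
    return EpidImage(values, raw.geometry, kind="corrected", meta=dict(raw.meta))


def _check_flood_positive(flood: EpidImage, dead_mask: np.ndarray | None) -> None:
    live = np.ones(flood.geometry.shape, bool) if dead_mask is None else ~np.asarray(dead_mask, bool)
    if np.any(flood.values[live] <= 0):
        raise ValueError("flood image has non-positive pixels outside the dead mask")


# ---------------------------------------------------------------------------
# decomposition operators


def psm_from_beam_response(
    raw: EpidImage,
    beam_resp: BeamResponse,
    *,
    floor: float = DIVISION_FLOOR,
    normalize: bool = True,
) -> Psm:
    """Divide the beam-response out of a wide-field raw image: ``S = raw / B``.

    Pixels where ``B`` is below ``floor`` (relative to its central axis) or
    where the raw signal is below ``floor`` of its own central axis — out of
    field, collimator shadow, dead — are flagged in the dead mask instead of
    divided, so they cannot explode downstream percent-deviation statistics.
    """
    _check_geometry(raw, beam_resp)
    if raw.kind != "raw":
        raise ValueError("psm_from_beam_response expects a raw image")
    b = beam_resp.values
    b_cax = central_axis_value(b, beam_resp.geometry)
    raw_cax = raw.central_axis_value()
    if raw_cax <= 0:
        raise ValueError("raw image has no central-axis signal")
    invalid = (b < floor * b_cax) | (raw.values < floor * raw_cax)
    values = np.zeros_like(raw.values)
    values[~invalid] = raw.values[~invalid] / b[~invalid]
    if normalize:
        values /= central_axis_value(values, raw.geometry, exclude=invalid)
        values[invalid] = 0.0
    return Psm(values, raw.geometry, dead_mask=invalid,
               normalization="central_axis" if normalize else "none")


def beam_response_from_psm(
    raw: EpidImage,
    psm: Psm,
    *,
    floor: float = DIVISION_FLOOR,
    normalize: bool = True,
) -> BeamResponse:
    """Divide the PSM out of a raw image: ``B = raw / S``.

    Dead/invalid pixels are filled by the mean of their valid 4-neighbours
    (single pass; unresolved pixels stay 0) and flagged in
    ``interpolated_mask``.
    """
    _check_geometry(raw, psm)
    if raw.kind != "raw":
        raise ValueError("beam_response_from_psm expects a raw image")
    invalid = psm.dead_mask | (psm.values < floor)
    values = np.zeros_like(raw.values)
    values[~invalid] = raw.values[~invalid] / psm.values[~invalid]
    values = _fill_from_neighbours(values, invalid)
    if normalize:
        values = values / central_axis_value(values, raw.geometry)
    return BeamResponse(
        values,
        raw.geometry,
        source="derived_from_psm",
        interpolated_mask=invalid,
        normalization="central_axis" if normalize else "none",
    )


def _fill_from_neighbours(values: np.ndarray, invalid: np.ndarray) -> np.ndarray:
    """Replace invalid pixels by the mean of their valid 4-neighbours."""
    if not invalid.any():
        return values
    out = values.copy()
    valid = (~invalid).astype(float)
    vals = np.where(invalid, 0.0, values)
    num = np.zeros_like(values)
    den = np.zeros_like(values)
    for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
        num += _shift_zero(vals, shift, axis)
        den += _shift_zero(valid, shift, axis)
    fixable = invalid & (den > 0)
    out[fixable] = num[fixable] / den[fixable]
    return out


def _shift_zero(a: np.ndarray, shift: int, axis: int) -> np.ndarray:
    out = np.zeros_like(a)
    src = [slice(None), slice(None)]
    dst = [slice(None), slice(None)]
    if shift > 0:
        src[axis], dst[axis] = slice(0, -shift), slice(shift, None)
    else:
        src[axis], dst[axis] = slice(-shift, None), slice(0, shift)
    out[tuple(dst)] = a[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# grid method: direct beam-response sampling, surface fit, calibration chain


@dataclass(frozen=True)
class GridSamples:
    """Directly measured relative beam-response samples at grid nodes.

    ``values[i]`` is the beam-response at ``node_positions_mm[i]`` relative
    to the reference (origin) acquisition; with the default in-plan
    reference the origin node is exactly 1.
    """

    node_positions_mm: np.ndarray  # (n, 2) crossplane, inplane
    values: np.ndarray  # (n,)
    roi_halfwidth_mm: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.node_positions_mm, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or len(val) != len(pos):
            raise ValueError("node positions must be (n, 2) aligned with values")
        if np.any(val <= 0) or not np.all(np.isfinite(val)):
            raise ValueError("grid samples must be positive and finite")
        object.__setattr__(self, "node_positions_mm", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class SurfaceFit:
    """Metadata of a fitted beam-response surface.

    ``coefficients`` are tensor-polynomial coefficients over coordinates
    scaled by ``domain_mm`` (empty for the spline basis);
    ``extrapolated_mask`` is True exactly where |x| or |y| exceeds the
    directly sampled extent.
    """

    basis: str
    degree: int
    coefficients: np.ndarray
    domain_mm: float
    extrapolated_mask: np.ndarray
    node_residuals: np.ndarray
    rms_residual: float


def grid_sample_beam_response(
    images: list[EpidImage],
    plan: GridPlan,
    *,
    roi_halfwidth_px: int = 5,
    reference_image: EpidImage | None = None,
) -> GridSamples:
    """Extract relative beam-response samples from grid-plan acquisitions.

    ``images`` is the flat acquisition list in plan order (centred, shifted
    per node).  For each node the panel-shifted image reads the beam at the
    node with the *central* pixels; dividing it pixel-by-pixel by the
    reference image (the origin node's acquisition, unless an explicit
    ``reference_image`` anchors the chain elsewhere, e.g. at another dose
    rate) cancels the pixel sensitivity exactly.  The sample is the mean of
    those per-pixel ratios over the central ROI (default 11x11 pixels).
    """
    if len(images) != 2 * plan.n_nodes:
        raise ValueError(
            f"expected {2 * plan.n_nodes} acquisitions (two per node), got {len(images)}"
        )
    geometry = images[0].geometry
    roi = geometry.central_roi(roi_halfwidth_px)
    if reference_image is None:
        reference_image = images[2 * plan.origin_index() + 1]
    _check_geometry(images[0], reference_image)
    ref_roi = reference_image.values[roi]
    valid = ref_roi > 0
    if not valid.any():
        raise ValueError("reference ROI has no usable signal")
    samples = np.empty(plan.n_nodes)
    for i in range(plan.n_nodes):
        shifted = images[2 * i + 1]
        _check_geometry(shifted, reference_image)
        num = shifted.values[roi]
        ok = valid & (num > 0)
        if not ok.any():
            raise ValueError(f"node {plan.nodes_mm[i]} ROI has no usable signal")
        samples[i] = float(np.mean(num[ok] / ref_roi[ok]))
    return GridSamples(
        np.asarray(plan.nodes_mm, dtype=float),
        samples,
        roi_halfwidth_mm=roi_halfwidth_px * geometry.pixel_pitch_mm,
    )


def fit_beam_response_surface(
    samples: GridSamples,
    geometry: PanelGeometry,
    degree: int = 4,
    *,
    basis: str = "tensor_polynomial",
    smoothing: float = 0.0,
    normalize: bool = True,
) -> tuple[BeamResponse, SurfaceFit]:
    """Fit a smooth surface to grid samples and evaluate it on every pixel.

    The default basis is a least-squares tensor-product polynomial of the
    given per-axis degree over coordinates scaled to the sampled extent; a
    smoothing bivariate spline is available behind the same interface
    (``basis='spline'``, requires samples on a full regular grid).  The
    surface is renormalized to central axis = 1 unless ``normalize=False``
    (used when the calibration chain is anchored to an external reference).
    Pixels beyond the sampled extent are flagged as extrapolated.
    """
    pos = samples.node_positions_mm
    vals = samples.values
    extent = float(np.max(np.abs(pos)))
    if extent == 0:
        extent = 1.0
    sx, sy = pos[:, 0] / extent, pos[:, 1] / extent
    X, Y = geometry.grid_mm()

    if basis == "tensor_polynomial":
        n_coef = (degree + 1) ** 2
        if len(vals) < n_coef:
            raise ValueError(
                f"degree {degree} needs at least {n_coef} samples, got {len(vals)}"
            )
        design = npoly.polyvander2d(sx, sy, [degree, degree])
        coef, _, rank, _ = np.linalg.lstsq(design, vals, rcond=None)
        if rank < n_coef:
            raise ValueError(f"rank-deficient design (rank {rank} < {n_coef}); lower the degree")
        fitted_nodes = design @ coef
        surface = npoly.polyval2d(X / extent, Y / extent, coef.reshape(degree + 1, degree + 1))
    elif basis == "spline":
        ux = np.unique(pos[:, 0])
        uy = np.unique(pos[:, 1])
        if len(ux) * len(uy) != len(vals):
            raise ValueError("spline basis requires samples on a full regular grid")
        grid_vals = np.full((len(uy), len(ux)), np.nan)
        ix = np.searchsorted(ux, pos[:, 0])
        iy = np.searchsorted(uy, pos[:, 1])
        grid_vals[iy, ix] = vals
        if np.isnan(grid_vals).any():
            raise ValueError("spline basis requires samples on a full regular grid")
        k = min(3, len(ux) - 1, len(uy) - 1)
        spl = RectBivariateSpline(uy, ux, grid_vals, kx=k, ky=k, s=smoothing)
        coef = np.empty(0)
        fitted_nodes = spl.ev(pos[:, 1], pos[:, 0])
        surface = spl(geometry.y_mm(), geometry.x_mm())
        degree = k
    else:
        raise ValueError(f"unknown basis {basis!r}")

    residuals = vals - fitted_nodes
    extrapolated = (np.abs(X) > extent + 1e-9) | (np.abs(Y) > extent + 1e-9)
    if normalize:
        cax = central_axis_value(surface, geometry)
        surface = surface / cax
        if coef.size:
            coef = coef / cax
    fit = SurfaceFit(
        basis=basis,
        degree=degree,
        coefficients=coef,
        domain_mm=extent,
        extrapolated_mask=extrapolated,
        node_residuals=residuals,
        rms_residual=float(np.sqrt(np.mean(residuals**2))),
    )
    br = BeamResponse(
        surface,
        geometry,
        source="direct_fit",
        normalization="central_axis" if normalize else "none",
    )
    return br, fit


def grid_calibrate(
    images: list[EpidImage],
    plan: GridPlan,
    wide_field_raw: EpidImage,
    *,
    degree: int = 4,
    roi_halfwidth_px: int = 5,
    basis: str = "tensor_polynomial",
    reference_image: EpidImage | None = None,
    normalize: bool = True,
) -> tuple[BeamResponse, Psm, SurfaceFit]:
    """Full grid calibration: sample, fit, then divide out of the wide field.

    The fitted surface is smooth, so all pixel-level (high-frequency) gain
    structure in the wide-field raw image lands in the PSM, which is the
    point of the method.
    """
    samples = grid_sample_beam_response(
        images, plan, roi_halfwidth_px=roi_halfwidth_px, reference_image=reference_image
    )
    beam_resp, fit = fit_beam_response_surface(
        samples, wide_field_raw.geometry, degree, basis=basis, normalize=normalize
    )
    psm = psm_from_beam_response(wide_field_raw, beam_resp, normalize=normalize)
    return beam_resp, psm, fit


# ---------------------------------------------------------------------------
# radial averaging


def radial_average(field: BeamResponse, bin_width_mm: float | None = None) -> BeamResponse:
    """Replace each pixel by the mean of its annular (equal-radius) bin.

    The post-processing applied to radiation-transport beam-response data:
    pixels are binned by ``floor(r / bin_width)`` and every pixel takes its
    bin mean, then the result is renormalized to the central axis.  Ring
    artifacts in downstream deviation maps are the expected signature of
    this operation, not a bug.
    """
    geometry = field.geometry
    pitch = geometry.pixel_pitch_mm
    if bin_width_mm is None:
        bin_width_mm = pitch
    if bin_width_mm < pitch / 2:
        raise ValueError("bin width below half the pixel pitch")
    X, Y = geometry.grid_mm()
    r = np.hypot(X, Y)
    idx = np.floor(r / bin_width_mm).astype(int)
    counts = np.bincount(idx.ravel())
    sums = np.bincount(idx.ravel(), weights=field.values.ravel())
    means = sums / counts
    out = means[idx]
    out = out / central_axis_value(out, geometry)
    return BeamResponse(out, geometry, source=field.source, label=field.label)
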