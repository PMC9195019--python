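"""Virtual linac/EPID: ground-truth sensitivity maps, beams and acquisitions.

The simulator provides every input the calibration pipeline needs, with known
ground truth and seeded reproducibility:

* :func:`make_truth_psm` — a pixel-sensitivity map with a smooth low-frequency
  gain component, per-pixel lognormal-like gain noise and dead pixels;
* :func:`make_beam_response` — parametric flattened (horned) or
  flattening-filter-free (FFF, forward-peaked) beam shapes with optional
  linear tilt and primary-collimator corner roll-off;
* :func:`acquire` / :func:`make_flood` — portal images composed as
  ``B(shifted) * aperture * S * dose-rate gain * noise``;
* :func:`make_grid_plan` — the acquisition schedule for the direct
  grid-sampled beam-response measurement (a small field stepped over a grid
  of off-axis nodes, imaged with the panel centred and panel shifted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import PanelGeometry, central_axis_value
from .images import BeamResponse, EpidImage, Psm
from .seeding import derive_seed

__all__ = [
    "PsmTruthModel",
    "BeamModel",
    "AcquisitionSpec",
    "GridPlan",
    "make_truth_psm",
    "make_beam_response",
    "acquire",
    "make_flood",
    "make_grid_plan",
    "wide_open_spec",
    "beam_library",
    "DEFAULT_PENUMBRA_MM",
]

#: fixed linear penumbra width of simulated field edges, mm
DEFAULT_PENUMBRA_MM = 3.0

#: floor applied to the radial profile before collimator attenuation
_PROFILE_FLOOR = 0.1


@dataclass(frozen=True)
class PsmTruthModel:
    """Parameters of the ground-truth pixel-sensitivity map.

    ``lowfreq_amplitude`` is the peak fractional deviation of the smooth gain
    component from 1 (the smooth field spans exactly [1-A, 1+A]);
    ``lowfreq_scale_mm`` its correlation scale.  ``pixel_sigma`` is the s.d.
    of per-pixel multiplicative (lognormal-like) gain noise.  Dead pixels are
    drawn uniformly outside the central-axis block.
    """

    lowfreq_amplitude: float = 0.02
    lowfreq_scale_mm: float = 120.0
    pixel_sigma: float = 0.005
    dead_pixel_fraction: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lowfreq_amplitude < 0 or self.pixel_sigma < 0:
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.dead_pixel_fraction < 0.01:
            raise ValueError("dead_pixel_fraction must lie in [0, 0.01)")
        if self.lowfreq_scale_mm <= 0:
            raise ValueError("lowfreq_scale_mm must be positive")


@dataclass(frozen=True)
class BeamModel:
    """Parametric beam-response shape.

    Radial profile (r in mm, u = r/100):

    * flattened: ``1 + horn_coeff*u**2 - rolloff_coeff*u**4`` — off-axis
      maxima ("horns") followed by a quartic decline;
    * fff: ``1 - rolloff_coeff*u**2`` — monotone forward-peaked shape.

    The profile is floored at 0.1, multiplied by a linear tilt
    ``(1 + tilt*x/100)(1 + tilt_inplane*y/100)`` (asymmetry, in fraction per
    100 mm) and by ``collimator_transmission`` beyond
    ``collimator_radius_mm`` (primary-collimator corner roll-off).

    ``dose_rate_sensitivity`` is the fractional panel gain change per unit
    fractional reduction of the nominal dose rate below
    ``reference_dose_rate``; e.g. 0.0036 gives a +0.30% gain at 400 MU/min
    against a 2400 MU/min reference.
    """

    label: str
    profile_kind: str
    horn_coeff: float = 0.0
    rolloff_coeff: float = 0.0
    collimator_radius_mm: float = 240.0
    collimator_transmission: float = 0.25
    tilt: float = 0.0
    tilt_inplane: float = 0.0
    dose_rate_sensitivity: float = 0.0
    reference_dose_rate: float = 2400.0

    def __post_init__(self) -> None:
        if self.profile_kind not in ("flattened", "fff"):
            raise ValueError("profile_kind must be 'flattened' or 'fff'")
        if not 0 <= self.collimator_transmission < 1:
            raise ValueError("collimator_transmission must lie in [0, 1)")
        if self.rolloff_coeff < 0:
            raise ValueError("rolloff_coeff must be non-negative")
        if self.profile_kind == "flattened":
            if self.horn_coeff < 0:
                raise ValueError("horn_coeff must be non-negative")
            if self.horn_coeff > 0 and self.rolloff_coeff <= 0:
                raise ValueError("flattened beams with horns need rolloff_coeff > 0")
        if self.reference_dose_rate <= 0:
            raise ValueError("reference_dose_rate must be positive")

    def profile(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        """Evaluate the (unnormalized) beam-response at beam-frame coordinates."""
        x = np.asarray(x_mm, dtype=float)
        y = np.asarray(y_mm, dtype=float)
        r2 = x * x + y * y
        u2 = r2 / 1e4
        if self.profile_kind == "flattened":
            base = 1.0 + self.horn_coeff * u2 - self.rolloff_coeff * u2 * u2
        else:
            base = 1.0 - self.rolloff_coeff * u2
        base = np.maximum(base, _PROFILE_FLOOR)
        base = base * (1.0 + self.tilt * x / 100.0) * (1.0 + self.tilt_inplane * y / 100.0)
        shadow = r2 > self.collimator_radius_mm**2
        return np.where(shadow, base * self.collimator_transmission, base)

    def dose_rate_gain(self, dose_rate_mu_min: float) -> float:
        """Global panel gain factor at a nominal dose rate."""
        frac = (self.reference_dose_rate - dose_rate_mu_min) / self.reference_dose_rate
        return 1.0 + self.dose_rate_sensitivity * frac


def beam_library() -> dict[str, BeamModel]:
    """Default desk-scale beam models for the four clinical photon beams.

    Horn/roll-off coefficients are chosen so flattened beams show a few
    percent of horns peaking ~90 mm off-axis and FFF beams fall by 20–30% at
    200 mm, with the higher energy flatter (flattened) or more forward-peaked
    (FFF) — the qualitative shapes an aSi panel records.
    """
    return {
        "6MV": BeamModel("6MV", "flattened", horn_coeff=0.055, rolloff_coeff=0.032),
        "10MV": BeamModel("10MV", "flattened", horn_coeff=0.035, rolloff_coeff=0.022),
        "6FFF": BeamModel("6FFF", "fff", rolloff_coeff=0.045),
        "10FFF": BeamModel("10FFF", "fff", rolloff_coeff=0.065),
    }


@dataclass(frozen=True)
class AcquisitionSpec:
    """One simulated exposure.

    ``field_center_mm``/``field_size_mm`` describe the rectangular aperture in
    the beam frame (crossplane, inplane).  ``panel_offset_mm`` is the lateral
    panel shift: a pixel at panel position p sees the beam at beam-frame
    position ``p - panel_offset_mm``.  ``noise_sigma`` is the s.d. of i.i.d.
    per-pixel multiplicative Gaussian acquisition noise.
    """

    field_center_mm: tuple[float, float] = (0.0, 0.0)
    field_size_mm: tuple[float, float] = (450.0, 450.0)
    panel_offset_mm: tuple[float, float] = (0.0, 0.0)
    dose_rate_mu_min: float = 2400.0
    noise_sigma: float = 0.0
    seed: int = 0
    penumbra_mm: float = DEFAULT_PENUMBRA_MM

    def __post_init__(self) -> None:
        if min(self.field_size_mm) <= 0:
            raise ValueError("field_size_mm components must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.penumbra_mm <= 0:
            raise ValueError("penumbra_mm must be positive")
        if self.dose_rate_mu_min <= 0:
            raise ValueError("dose_rate_mu_min must be positive")


def wide_open_spec(geometry: PanelGeometry, **kwargs) -> AcquisitionSpec:
    """An aperture comfortably covering the whole panel (flat transmission 1)."""
    size = max(geometry.active_width_mm, geometry.active_height_mm) + 50.0
    return AcquisitionSpec(field_size_mm=(size, size), **kwargs)


def make_truth_psm(model: PsmTruthModel, geometry: PanelGeometry) -> Psm:
    """Generate a ground-truth pixel-sensitivity map.

    The map is the product of a smooth low-frequency gain field spanning
    exactly ``[1-A, 1+A]`` (Gaussian-filtered white noise, rescaled) and
    per-pixel lognormal gains ``exp(pixel_sigma * N(0,1))``; dead pixels are
    then zeroed and flagged, and the map is renormalized so the central-axis
    block mean is exactly 1.  Bit-reproducible for a fixed seed.
    """
    n_rows, n_cols = geometry.shape
    if min(n_rows, n_cols) < 11:
        raise ValueError("panel too small for grid sampling; need at least 11x11 pixels")
    rng = np.random.default_rng(model.seed)

    white = rng.standard_normal((n_rows, n_cols))
    sigma_px = model.lowfreq_scale_mm / geometry.pixel_pitch_mm
    smooth = gaussian_filter(white, sigma_px, mode="reflect")
    smooth -= smooth.mean()
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth /= peak
    low = 1.0 + model.lowfreq_amplitude * smooth

    gains = np.exp(model.pixel_sigma * rng.standard_normal((n_rows, n_cols)))
    values = low * gains

    dead = np.zeros(geometry.shape, dtype=bool)
    n_dead = int(round(model.dead_pixel_fraction * n_rows * n_cols))
    if n_dead:
        # the central reference region anchors every normalization and every
        # grid-sample denominator; keep it defect-free
        rs, cs = geometry.central_roi(min(5, min(n_rows, n_cols) // 4))
        eligible = np.ones(geometry.shape, dtype=bool)
        eligible[rs, cs] = False
        flat = np.flatnonzero(eligible)
        chosen = rng.choice(flat, size=n_dead, replace=False)
        dead.flat[chosen] = True
        values[dead] = 0.0

    values /= central_axis_value(values, geometry, exclude=dead)
    values[dead] = 0.0
    return Psm(values, geometry, dead_mask=dead, label="truth")


def make_beam_response(beam: BeamModel, geometry: PanelGeometry) -> BeamResponse:
    """Evaluate a beam model on the pixel grid, normalized to the central axis."""
    X, Y = geometry.grid_mm()
    values = beam.profile(X, Y)
    values = values / central_axis_value(values, geometry)
    return BeamResponse(values, geometry, source="external", label=beam.label)


def _aperture(xb: np.ndarray, yb: np.ndarray, spec: AcquisitionSpec) -> np.ndarray:
    """Rectangular field transmission with a linear penumbra ramp per axis."""
    out = np.ones(np.broadcast(xb, yb).shape, dtype=float)
    for coord, center, size in (
        (xb, spec.field_center_mm[0], spec.field_size_mm[0]),
        (yb, spec.field_center_mm[1], spec.field_size_mm[1]),
    ):
        half, w = size / 2.0, spec.penumbra_mm
        t = np.clip((half + w / 2.0 - np.abs(coord - center)) / w, 0.0, 1.0)
        out = out * t
    return out


def acquire(psm: Psm, beam: BeamModel, spec: AcquisitionSpec, kind: str = "raw") -> EpidImage:
    """Simulate one raw portal image.

    Pixel value = beam-response at the pixel's beam-frame position
    (panel position minus panel offset) x field-aperture transmission
    x pixel sensitivity x dose-rate gain x multiplicative acquisition noise.
    Deterministic for a fixed ``spec.seed``.
    """
    geometry = psm.geometry
    # a field entirely off the panel is a planning error, not data
    for axis, (half_extent, c, o, size) in enumerate(
        [
            (geometry.active_width_mm / 2, spec.field_center_mm[0], spec.panel_offset_mm[0], spec.field_size_mm[0]),
            (geometry.active_height_mm / 2, spec.field_center_mm[1], spec.panel_offset_mm[1], spec.field_size_mm[1]),
        ]
    ):
        if abs(c + o) - size / 2.0 > half_extent:
            raise ValueError(f"field lies entirely off-panel along axis {axis}")

    X, Y = geometry.grid_mm()
    xb = X - spec.panel_offset_mm[0]
    yb = Y - spec.panel_offset_mm[1]
    # acquisitions use the unnormalized physical profile; beam.profile is 1
    # on the beam axis by construction
    b = beam.profile(xb, yb)
    values = b * _aperture(xb, yb, spec) * psm.values * beam.dose_rate_gain(spec.dose_rate_mu_min)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        values = values * (1.0 + spec.noise_sigma * rng.standard_normal(geometry.shape))
    values = np.maximum(values, 0.0)
    meta = {
        "beam": beam.label,
        "field_center_mm": list(spec.field_center_mm),
        "field_size_mm": list(spec.field_size_mm),
        "panel_offset_mm": list(spec.panel_offset_mm),
        "dose_rate_mu_min": spec.dose_rate_mu_min,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }
    return EpidImage(values, geometry, kind=kind, meta=meta)


def make_flood(psm: Psm, beam: BeamModel, spec: AcquisitionSpec | None = None) -> EpidImage:
    """A wide-open-field acquisition tagged ``kind='flood'``.

    Same composition law as :func:`acquire`; this is the image the vendor
    flood-field calibration divides by, which is why that calibration removes
    the beam profile along with the panel non-uniformity.
    """
    if spec is None:
        spec = wide_open_spec(psm.geometry)
    return acquire(psm, beam, spec, kind="flood")


@dataclass(frozen=True)
class GridPlan:
    """Acquisition schedule for direct grid sampling of the beam-response.

    Per node p: one acquisition with the field at p and the panel centred,
    and one with the field at p and the panel shifted by -p so the central
    pixels sit under the field.  The origin node contributes two identical
    specs, kept for uniformity.
    """

    nodes_mm: tuple[tuple[float, float], ...]
    pairs: tuple[tuple[AcquisitionSpec, AcquisitionSpec], ...]
    extent_mm: float
    spacing_mm: float
    field_mm: float

    @property
    def n_nodes(self) -> int:
        return len(self.nodes_mm)

    @property
    def acquisitions(self) -> list[AcquisitionSpec]:
        """Flat list: centred then shifted spec for each node, in node order."""
        return [s for pair in self.pairs for s in pair]

    def origin_index(self) -> int:
        for i, (x, y) in enumerate(self.nodes_mm):
            if x == 0.0 and y == 0.0:
                return i
        raise ValueError("plan has no origin node")


def make_grid_plan(
    geometry: PanelGeometry,
    extent_mm: float = 150.0,
    spacing_mm: float = 50.0,
    field_mm: float = 50.0,
    *,
    noise_sigma: float = 0.0,
    dose_rate_mu_min: float = 2400.0,
    base_seed: int = 0,
) -> GridPlan:
    """Build the grid-measurement plan on ``[-extent, +extent]^2`` nodes.

    The default 150/50/50 mm plan has 7x7 = 49 nodes and 98 acquisitions.
    The field must fit the panel at the outermost node, otherwise the plan is
    rejected (the measurement would clip at the panel edge).
    """
    if extent_mm < 0 or spacing_mm <= 0 or field_mm <= 0:
        raise ValueError("extent, spacing and field size must be positive")
    n_steps = extent_mm / spacing_mm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("extent_mm must be an integer multiple of spacing_mm")
    half_panel = min(geometry.active_width_mm, geometry.active_height_mm) / 2.0
    if extent_mm + field_mm / 2.0 > half_panel + 1e-9:
        raise ValueError(
            f"field edge at {extent_mm + field_mm / 2.0:.1f} mm exceeds the "
            f"panel half-width {half_panel:.1f} mm"
        )
    coords = np.arange(-round(n_steps), round(n_steps) + 1) * spacing_mm
    nodes: list[tuple[float, float]] = []
    pairs: list[tuple[AcquisitionSpec, AcquisitionSpec]] = []
    i = 0
    for y in coords:
        for x in coords:
            common = dict(
                field_center_mm=(float(x), float(y)),
                field_size_mm=(field_mm, field_mm),
                dose_rate_mu_min=dose_rate_mu_min,
                noise_sigma=noise_sigma,
            )
            centered = AcquisitionSpec(panel_offset_mm=(0.0, 0.0), seed=derive_seed(base_seed, i), **common)
            shifted = AcquisitionSpec(
                panel_offset_mm=(float(-x), float(-y)), seed=derive_seed(base_seed, i + 1), **common
            )
            nodes.append((float(x), float(y)))
            pairs.append((centered, shifted))
            i += 2
    return GridPlan(tuple(nodes), tuple(pairs), float(extent_mm), float(spacing_mm), float(field_mm))


def with_seed(spec: AcquisitionSpec, seed: int) -> AcquisitionSpec:
    """Copy of an acquisition spec with a replaced noise seed."""
    return replace(spec, seed=seed)
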