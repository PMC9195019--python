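"""End-to-end experiment drivers.

Four scripted studies run the full simulate → calibrate → compare pipeline on
a shared ground-truth sensitivity map:

* :func:`run_beam_dependence` — does the recovered PSM depend on the beam it
  was measured with?  Each beam's recovered PSM is compared to the
  first-listed (reference) beam's PSM and to the truth.
* :func:`run_inter_method` — recovered PSMs per beam against an externally
  supplied reference PSM (e.g. a radiation-transport result); the median is
  the headline because mean/SD are skewed by edges, corners and dead pixels.
* :func:`run_dose_rate` — the grid pipeline at two nominal dose rates with
  the calibration chain anchored at the reference rate; a dose-rate gain
  splits into a beam-response deviation and its near-inverse in the PSM.
* :func:`run_symmetry_benchmark` — beams with injected tilt; point-ratio
  symmetry of the recovered beam-response against the analytic truth (the
  stand-in for an independent profiler measurement).

Every driver is a pure function of its configuration and seeds: re-running
with the same inputs produces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .calibration import grid_calibrate
from .geometry import PanelGeometry
from .images import BeamResponse, EpidImage, Psm
from .metrics import (
    DeviationMap,
    Histogram,
    deviation_histogram,
    deviation_stats,
    percent_deviation,
    symmetry_of,
)
from .seeding import derive_seed
from .simulator import (
    BeamModel,
    GridPlan,
    PsmTruthModel,
    acquire,
    beam_library,
    make_beam_response,
    make_grid_plan,
    make_truth_psm,
    wide_open_spec,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "config_from_dict",
    "simulate_beam_dataset",
    "calibrate_dataset",
    "run_beam_dependence",
    "run_inter_method",
    "run_dose_rate",
    "run_symmetry_benchmark",
]

_CSV_FLOAT = "%.10g"


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration shared by all experiment drivers."""

    geometry: PanelGeometry = field(default_factory=lambda: PanelGeometry(238, 238, 400.0))
    psm_truth: PsmTruthModel = field(default_factory=PsmTruthModel)
    beams: tuple[BeamModel, ...] = field(
        default_factory=lambda: tuple(beam_library().values())
    )
    noise_sigma: float = 0.001
    dose_rate_mu_min: float = 2400.0
    dose_rates: tuple[float, float] = (2400.0, 400.0)
    grid_extent_mm: float = 150.0
    grid_spacing_mm: float = 50.0
    grid_field_mm: float = 50.0
    roi_halfwidth_px: int = 5
    fit_degree: int = 4
    fit_basis: str = "tensor_polynomial"
    roi_halfwidth_mm: float = 150.0
    symmetry_region_mm: float = 140.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beams) < 1:
            raise ValueError("at least one beam is required")
        if len(set(b.label for b in self.beams)) != len(self.beams):
            raise ValueError("beam labels must be unique")
        if len(self.dose_rates) != 2:
            raise ValueError("exactly two dose rates are required")


_GEOMETRY_KEYS = {"n_rows", "n_cols", "n_pixels", "active_width_mm"}
_TRUTH_KEYS = {"lowfreq_amplitude", "lowfreq_scale_mm", "pixel_sigma", "dead_pixel_fraction", "seed"}
_BEAM_KEYS = {
    "label", "profile_kind", "horn_coeff", "rolloff_coeff", "collimator_radius_mm",
    "collimator_transmission", "tilt", "tilt_inplane", "dose_rate_sensitivity",
    "reference_dose_rate",
}
_TOP_KEYS = {
    "geometry", "psm_truth", "beams", "noise_sigma", "dose_rate_mu_min", "dose_rates",
    "grid", "roi_halfwidth_mm", "symmetry_region_mm", "seed",
}
_GRID_KEYS = {"extent_mm", "spacing_mm", "field_mm", "roi_halfwidth_px", "fit_degree", "fit_basis"}


def _reject_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def config_from_dict(doc: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a plain (YAML/JSON) mapping.

    Unknown keys anywhere are errors, so typos never silently fall back to
    defaults.
    """
    _reject_unknown(doc, _TOP_KEYS, "configuration")
    kwargs: dict = {}
    if "geometry" in doc:
        g = dict(doc["geometry"])
        _reject_unknown(g, _GEOMETRY_KEYS, "geometry")
        n = g.get("n_pixels")
        kwargs["geometry"] = PanelGeometry(
            g.get("n_rows", n), g.get("n_cols", n), g.get("active_width_mm", 400.0)
        )
    if "psm_truth" in doc:
        t = dict(doc["psm_truth"])
        _reject_unknown(t, _TRUTH_KEYS, "psm_truth")
        kwargs["psm_truth"] = PsmTruthModel(**t)
    if "beams" in doc:
        beams = []
        for b in doc["beams"]:
            b = dict(b)
            _reject_unknown(b, _BEAM_KEYS, f"beam {b.get('label', '?')}")
            beams.append(BeamModel(**b))
        kwargs["beams"] = tuple(beams)
    if "grid" in doc:
        g = dict(doc["grid"])
        _reject_unknown(g, _GRID_KEYS, "grid")
        for src, dst in (
            ("extent_mm", "grid_extent_mm"), ("spacing_mm", "grid_spacing_mm"),
            ("field_mm", "grid_field_mm"), ("roi_halfwidth_px", "roi_halfwidth_px"),
            ("fit_degree", "fit_degree"), ("fit_basis", "fit_basis"),
        ):
            if src in g:
                kwargs[dst] = g[src]
    for key in ("noise_sigma", "dose_rate_mu_min", "roi_halfwidth_mm", "symmetry_region_mm", "seed"):
        if key in doc:
            kwargs[key] = doc[key]
    if "dose_rates" in doc:
        kwargs["dose_rates"] = tuple(float(r) for r in doc["dose_rates"])
    return ExperimentConfig(**kwargs)


def config_to_dict(cfg: ExperimentConfig) -> dict:
    """All defaults materialized, JSON-able; echoed into run manifests."""
    return {
        "geometry": {
            "n_rows": cfg.geometry.n_rows,
            "n_cols": cfg.geometry.n_cols,
            "active_width_mm": cfg.geometry.active_width_mm,
        },
        "psm_truth": {f.name: getattr(cfg.psm_truth, f.name) for f in fields(cfg.psm_truth)},
        "beams": [{f.name: getattr(b, f.name) for f in fields(b)} for b in cfg.beams],
        "noise_sigma": cfg.noise_sigma,
        "dose_rate_mu_min": cfg.dose_rate_mu_min,
        "dose_rates": list(cfg.dose_rates),
        "grid": {
            "extent_mm": cfg.grid_extent_mm,
            "spacing_mm": cfg.grid_spacing_mm,
            "field_mm": cfg.grid_field_mm,
            "roi_halfwidth_px": cfg.roi_halfwidth_px,
            "fit_degree": cfg.fit_degree,
            "fit_basis": cfg.fit_basis,
        },
        "roi_halfwidth_mm": cfg.roi_halfwidth_mm,
        "symmetry_region_mm": cfg.symmetry_region_mm,
        "seed": cfg.seed,
    }


# ---------------------------------------------------------------------------
# shared simulation / calibration building blocks (also used by the CLI)


def truth_psm_for(cfg: ExperimentConfig) -> Psm:
    """The shared ground-truth PSM of a run (seed derived from cfg.seed)."""
    model = replace(cfg.psm_truth, seed=derive_seed(cfg.seed, 999))
    return make_truth_psm(model, cfg.geometry)


@dataclass
class BeamDataset:
    """All simulated acquisitions the grid method needs for one beam."""

    beam: BeamModel
    plan: GridPlan
    grid_images: list[EpidImage]
    wide_raw: EpidImage


def simulate_beam_dataset(
    truth: Psm,
    beam: BeamModel,
    cfg: ExperimentConfig,
    beam_index: int,
    *,
    dose_rate: float | None = None,
    wide_dose_rate: float | None = None,
    rate_index: int = 0,
) -> BeamDataset:
    """Simulate grid acquisitions plus the wide-field raw image for one beam."""
    rate = cfg.dose_rate_mu_min if dose_rate is None else dose_rate
    plan = make_grid_plan(
        cfg.geometry,
        cfg.grid_extent_mm,
        cfg.grid_spacing_mm,
        cfg.grid_field_mm,
        noise_sigma=cfg.noise_sigma,
        dose_rate_mu_min=rate,
        base_seed=derive_seed(cfg.seed, beam_index, rate_index),
    )
    grid_images = [acquire(truth, beam, spec) for spec in plan.acquisitions]
    wide_spec = wide_open_spec(
        cfg.geometry,
        noise_sigma=cfg.noise_sigma,
        dose_rate_mu_min=rate if wide_dose_rate is None else wide_dose_rate,
        seed=derive_seed(cfg.seed, beam_index, rate_index, 1_000_000),
    )
    wide_raw = acquire(truth, beam, wide_spec)
    return BeamDataset(beam, plan, grid_images, wide_raw)


def calibrate_dataset(
    ds: BeamDataset,
    cfg: ExperimentConfig,
    *,
    reference_image: EpidImage | None = None,
    wide_raw: EpidImage | None = None,
    normalize: bool = True,
):
    """Run the grid calibration over a simulated dataset."""
    beam_resp, psm, fit = grid_calibrate(
        ds.grid_images,
        ds.plan,
        ds.wide_raw if wide_raw is None else wide_raw,
        degree=cfg.fit_degree,
        roi_halfwidth_px=cfg.roi_halfwidth_px,
        basis=cfg.fit_basis,
        reference_image=reference_image,
        normalize=normalize,
    )
    beam_resp.label = ds.beam.label
    psm.label = ds.beam.label
    return beam_resp, psm, fit


# ---------------------------------------------------------------------------
# report container


@dataclass
class ExperimentReport:
    """Structured results of one experiment run.

    ``stats`` is the table-style summary (one row per comparison x ROI);
    ``maps``/``histograms`` hold the figure-style arrays keyed by comparison
    name; ``extras`` keeps recovered objects for reuse; ``manifest`` echoes
    the fully materialized configuration and seeds.
    """

    name: str
    stats: pd.DataFrame
    maps: dict[str, DeviationMap] = field(default_factory=dict)
    histograms: dict[str, Histogram] = field(default_factory=dict)
    profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    symmetry: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def write(self, out_dir) -> None:
        """Write CSV tables, native-container maps and the JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.stats.to_csv(out / "stats.csv", index=False, float_format=_CSV_FLOAT)
        if self.symmetry is not None:
            self.symmetry.to_csv(out / "symmetry.csv", index=False, float_format=_CSV_FLOAT)
        if self.maps:
            (out / "maps").mkdir(exist_ok=True)
            for name, dmap in self.maps.items():
                eio._write_container(
                    out / "maps" / f"{name}.npy",
                    dmap.values,
                    {
                        "type": "deviation_map",
                        "geometry": eio._geometry_sidecar(dmap.geometry),
                        "reference_label": dmap.reference_label,
                        "target_label": dmap.target_label,
                        "invalid_mask_rle": eio.rle_encode(~dmap.valid_mask),
                    },
                )
        if self.histograms:
            (out / "histograms").mkdir(exist_ok=True)
            for name, h in self.histograms.items():
                df = pd.DataFrame(
                    {
                        "bin_lo": np.concatenate([[-np.inf], h.bin_edges[:-1], [h.bin_edges[-1]]]),
                        "bin_hi": np.concatenate([[h.bin_edges[0]], h.bin_edges[1:], [np.inf]]),
                        "count": np.concatenate([[h.underflow], h.counts, [h.overflow]]),
                    }
                )
                df.to_csv(out / "histograms" / f"{name}.csv", index=False, float_format=_CSV_FLOAT)
        if self.profiles:
            (out / "profiles").mkdir(exist_ok=True)
            for name, df in self.profiles.items():
                df.to_csv(out / "profiles" / f"{name}.csv", index=False, float_format=_CSV_FLOAT)
        for label, psm in self.extras.get("psms", {}).items():
            eio.write_psm(psm, out / f"psm_{label}.npy")
        for label, br in self.extras.get("beam_responses", {}).items():
            eio.write_beam_response(br, out / f"beam_response_{label}.npy")
        import json

        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, sort_keys=True, indent=1)
            fh.write("\n")


def _stats_rows(dmap: DeviationMap, cfg: ExperimentConfig, comparison: str) -> list[dict]:
    rows = []
    for roi in ("central", "full"):
        s = deviation_stats(dmap, roi, roi_halfwidth_mm=cfg.roi_halfwidth_mm)
        rows.append(
            {
                "comparison": comparison,
                "target": dmap.target_label,
                "reference": dmap.reference_label,
                "roi": s.roi,
                "n_pixels": s.n_pixels,
                "n_excluded": s.n_excluded,
                "mean_pct": s.mean_pct,
                "median_pct": s.median_pct,
                "sd_pct": s.sd_pct,
            }
        )
    return rows


def _manifest(cfg: ExperimentConfig, name: str) -> dict:
    from . import __version__

    return {"experiment": name, "config": config_to_dict(cfg), "version": __version__}


# ---------------------------------------------------------------------------
# drivers


def run_beam_dependence(cfg: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Intra-method beam dependence of the recovered PSM.

    All beams share one truth PSM.  Each beam's recovered PSM is compared to
    the first-listed beam's recovered PSM (deviation map, histogram, profile
    deviation, stats) and — simulation-only extra — to the truth PSM.
    """
    if len(cfg.beams) < 2:
        raise ValueError("beam-dependence needs at least two beams")
    truth = truth_psm_for(cfg)
    recovered: dict[str, Psm] = {}
    responses: dict[str, BeamResponse] = {}
    for i, beam in enumerate(cfg.beams):
        ds = simulate_beam_dataset(truth, beam, cfg, i)
        br, psm, _ = calibrate_dataset(ds, cfg)
        recovered[beam.label] = psm
        responses[beam.label] = br

    ref_label = cfg.beams[0].label
    rows: list[dict] = []
    maps: dict[str, DeviationMap] = {}
    hists: dict[str, Histogram] = {}
    profiles: dict[str, pd.DataFrame] = {}
    from .metrics import crossplane_profile

    ref_profile = crossplane_profile(recovered[ref_label])
    for beam in cfg.beams:
        label = beam.label
        if label != ref_label:
            dmap = percent_deviation(recovered[label], recovered[ref_label])
            key = f"psm_{label}_vs_{ref_label}"
            maps[key] = dmap
            hists[key] = deviation_histogram(dmap)
            rows += _stats_rows(dmap, cfg, "inter-beam")
            prof = crossplane_profile(recovered[label])
            profiles[key] = pd.DataFrame(
                {
                    "x_mm": prof.positions_mm,
                    "psm": prof.values,
                    "deviation_pct": 100.0 * (prof.values - ref_profile.values) / ref_profile.values,
                }
            )
        tmap = percent_deviation(recovered[label], truth, reference_label="truth")
        rows += _stats_rows(tmap, cfg, "truth-recovery")

    report = ExperimentReport(
        name="beam-dependence",
        stats=pd.DataFrame(rows),
        maps=maps,
        histograms=hists,
        profiles=profiles,
        manifest=_manifest(cfg, "beam-dependence"),
        extras={"psms": recovered, "beam_responses": responses, "truth_psm": truth},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_inter_method(cfg: ExperimentConfig, reference_psm: Psm | None = None, out_dir=None) -> ExperimentReport:
    """Recovered PSM per beam against an externally supplied reference PSM.

    The reference stands in for an independent method (e.g. a
    radiation-transport calculation); by default it is the truth PSM itself.
    The median is the headline statistic; means/SDs are reported with the
    full-panel ROI so their skew is visible rather than hidden.
    """
    truth = truth_psm_for(cfg)
    if reference_psm is None:
        reference_psm = Psm(
            truth.values.copy(), truth.geometry, dead_mask=truth.dead_mask.copy(), label="reference"
        )
    if reference_psm.geometry != cfg.geometry:
        raise ValueError("reference PSM geometry does not match the configuration")
    rows: list[dict] = []
    maps: dict[str, DeviationMap] = {}
    hists: dict[str, Histogram] = {}
    recovered: dict[str, Psm] = {}
    for i, beam in enumerate(cfg.beams):
        ds = simulate_beam_dataset(truth, beam, cfg, i)
        _, psm, _ = calibrate_dataset(ds, cfg)
        recovered[beam.label] = psm
        dmap = percent_deviation(psm, reference_psm)
        key = f"psm_{beam.label}_vs_reference"
        maps[key] = dmap
        hists[key] = deviation_histogram(dmap)
        rows += _stats_rows(dmap, cfg, "inter-method")
    report = ExperimentReport(
        name="inter-method",
        stats=pd.DataFrame(rows),
        maps=maps,
        histograms=hists,
        manifest=_manifest(cfg, "inter-method"),
        extras={"psms": recovered, "truth_psm": truth, "reference_psm": reference_psm},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_dose_rate(cfg: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Dose-rate dependence of the measured beam-response and PSM.

    The grid pipeline runs at both configured dose rates using the first
    beam.  The calibration chain is anchored at the reference (higher) rate
    — the machine only permits the flood/reference acquisition there — so
    the grid-sample denominator and the wide-field raw image come from the
    reference-rate session and the fit/PSM extraction skip central-axis
    renormalization.  A dose-rate gain then appears in the measured
    beam-response, and (because S = raw / B) as its near-exact inverse in
    the PSM.
    """
    beam = cfg.beams[0]
    ref_rate, low_rate = max(cfg.dose_rates), min(cfg.dose_rates)
    truth = truth_psm_for(cfg)

    ds_ref = simulate_beam_dataset(truth, beam, cfg, 0, dose_rate=ref_rate, rate_index=0)
    ds_low = simulate_beam_dataset(
        truth, beam, cfg, 0, dose_rate=low_rate, wide_dose_rate=ref_rate, rate_index=1
    )
    # anchor: the origin-node acquisition and the wide-field raw of the
    # reference-rate session
    anchor = ds_ref.grid_images[2 * ds_ref.plan.origin_index() + 1]
    br_ref, psm_ref, _ = calibrate_dataset(ds_ref, cfg, normalize=False)
    br_low, psm_low, _ = calibrate_dataset(
        ds_low, cfg, reference_image=anchor, wide_raw=ds_ref.wide_raw, normalize=False
    )
    br_ref.label = psm_ref.label = f"{beam.label}@{ref_rate:g}MU/min"
    br_low.label = psm_low.label = f"{beam.label}@{low_rate:g}MU/min"

    dmap_b = percent_deviation(br_low, br_ref)
    dmap_s = percent_deviation(psm_low, psm_ref)
    rows = _stats_rows(dmap_b, cfg, "beam-response dose-rate") + _stats_rows(
        dmap_s, cfg, "psm dose-rate"
    )
    maps = {"beam_response_low_vs_ref": dmap_b, "psm_low_vs_ref": dmap_s}
    hists = {k: deviation_histogram(v) for k, v in maps.items()}
    report = ExperimentReport(
        name="dose-rate",
        stats=pd.DataFrame(rows),
        maps=maps,
        histograms=hists,
        manifest=_manifest(cfg, "dose-rate"),
        extras={
            "truth_psm": truth,
            "beam_responses": {f"rate{ref_rate:g}": br_ref, f"rate{low_rate:g}": br_low},
            "psms": {f"rate{ref_rate:g}": psm_ref, f"rate{low_rate:g}": psm_low},
        },
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def run_symmetry_benchmark(cfg: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Point-ratio symmetry of recovered beam-responses vs analytic truth.

    The analytic evaluation of the tilted beam model plays the role of a
    perfect external profiler.  An unsmoothed noisy external beam-response
    (truth x 0.5% pixel noise) is scored alongside, demonstrating how
    pixel-level noise left in a beam-response degrades the symmetry metric.
    """
    truth = truth_psm_for(cfg)
    region = cfg.symmetry_region_mm
    rows = []
    recovered: dict[str, BeamResponse] = {}
    rng = np.random.default_rng(derive_seed(cfg.seed, 777))
    for i, beam in enumerate(cfg.beams):
        truth_br = make_beam_response(beam, cfg.geometry)
        ds = simulate_beam_dataset(truth, beam, cfg, i)
        br, _, _ = calibrate_dataset(ds, cfg)
        recovered[beam.label] = br
        noisy_values = truth_br.values * (1.0 + 0.005 * rng.standard_normal(cfg.geometry.shape))
        noisy = BeamResponse(
            noisy_values / np.mean(noisy_values[cfg.geometry.central_block()]),
            cfg.geometry,
            source="external",
            label=f"{beam.label}-noisy",
        )
        s_truth = symmetry_of(truth_br, region, label=beam.label)
        s_grid = symmetry_of(br, region, label=beam.label)
        s_noisy = symmetry_of(noisy, region, label=noisy.label)
        for plane in ("crossplane", "inplane"):
            truth_v = getattr(s_truth, f"{plane}_pct")
            grid_v = getattr(s_grid, f"{plane}_pct")
            noisy_v = getattr(s_noisy, f"{plane}_pct")
            rows.append(
                {
                    "beam": beam.label,
                    "plane": plane,
                    "region_halfwidth_mm": region,
                    "truth_pct": truth_v,
                    "grid_pct": grid_v,
                    "external_noisy_pct": noisy_v,
                    "grid_abs_err_pp": abs(grid_v - truth_v),
                    "external_noisy_abs_err_pp": abs(noisy_v - truth_v),
                }
            )
    table = pd.DataFrame(rows)
    report = ExperimentReport(
        name="symmetry",
        stats=table,
        symmetry=table,
        manifest=_manifest(cfg, "symmetry"),
        extras={"beam_responses": recovered, "truth_psm": truth},
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
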