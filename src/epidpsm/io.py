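"""File formats: the native matrix container, text-matrix fixtures,
optional DICOM RT-image reading, and experiment configuration files.

The native container is a `.npy` float payload plus a JSON sidecar at
``<path>.json`` carrying geometry, kind/normalization, acquisition metadata,
a run-length-encoded dead mask and a format version.  Round trips are
bit-exact for the payload and lossless for the sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .geometry import PanelGeometry
from .images import BeamResponse, EpidImage, Psm

__all__ = [
    "FORMAT_VERSION",
    "write_image",
    "read_image",
    "write_psm",
    "read_psm",
    "write_beam_response",
    "read_beam_response",
    "read_any",
    "read_text_matrix",
    "read_rtimage",
    "load_config_file",
    "rle_encode",
    "rle_decode",
]

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# dead-mask run-length encoding (flattened row-major [start, length] pairs)


def rle_encode(mask: np.ndarray) -> list[list[int]]:
    flat = np.asarray(mask, bool).ravel()
    if not flat.any():
        return []
    padded = np.concatenate([[False], flat, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[0::2], changes[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        mask[start : start + length] = True
    return mask.reshape(shape)


# ---------------------------------------------------------------------------
# native container


def _write_container(path, values: np.ndarray, sidecar: dict) -> None:
    path = Path(path)
    with open(path, "wb") as fh:
        np.save(fh, np.ascontiguousarray(values))
    sidecar = dict(sidecar, format_version=FORMAT_VERSION, shape=list(values.shape))
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
        fh.write("\n")


def _read_container(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    with open(path, "rb") as fh:
        values = np.load(fh)
    with open(str(path) + ".json") as fh:
        sidecar = json.load(fh)
    version = sidecar.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported container format version {version!r}")
    if list(values.shape) != sidecar.get("shape"):
        raise ValueError("payload shape does not match sidecar")
    return values, sidecar


def _geometry_sidecar(geometry: PanelGeometry) -> dict:
    return {
        "n_rows": geometry.n_rows,
        "n_cols": geometry.n_cols,
        "active_width_mm": geometry.active_width_mm,
    }


def _geometry_from(sidecar: dict) -> PanelGeometry:
    g = sidecar["geometry"]
    geometry = PanelGeometry(g["n_rows"], g["n_cols"], g["active_width_mm"])
    if list(geometry.shape) != sidecar["shape"]:
        raise ValueError("sidecar geometry does not match payload shape")
    return geometry


def write_image(image: EpidImage, path) -> None:
    _write_container(
        path,
        image.values,
        {
            "type": "image",
            "geometry": _geometry_sidecar(image.geometry),
            "kind": image.kind,
            "meta": image.meta,
        },
    )


def read_image(path) -> EpidImage:
    path = Path(path)
    if path.name.endswith((".txt", ".txt.gz")):
        return read_text_matrix(path)
    values, sidecar = _read_container(path)
    if sidecar.get("type") != "image":
        raise ValueError(f"container at {path} is not an image")
    return EpidImage(values, _geometry_from(sidecar), kind=sidecar["kind"], meta=sidecar.get("meta", {}))


def write_psm(psm: Psm, path) -> None:
    _write_container(
        path,
        psm.values,
        {
            "type": "psm",
            "geometry": _geometry_sidecar(psm.geometry),
            "normalization": psm.normalization,
            "label": psm.label,
            "dead_mask_rle": rle_encode(psm.dead_mask),
        },
    )


def read_psm(path) -> Psm:
    values, sidecar = _read_container(path)
    if sidecar.get("type") != "psm":
        raise ValueError(f"container at {path} is not a PSM")
    geometry = _geometry_from(sidecar)
    dead = rle_decode(sidecar.get("dead_mask_rle", []), geometry.shape)
    return Psm(values, geometry, dead_mask=dead,
               normalization=sidecar.get("normalization", "central_axis"),
               label=sidecar.get("label", ""))


def write_beam_response(br: BeamResponse, path) -> None:
    sidecar = {
        "type": "beam_response",
        "geometry": _geometry_sidecar(br.geometry),
        "source": br.source,
        "normalization": br.normalization,
        "label": br.label,
    }
    if br.interpolated_mask is not None:
        sidecar["interpolated_mask_rle"] = rle_encode(br.interpolated_mask)
    _write_container(path, br.values, sidecar)


def read_beam_response(path) -> BeamResponse:
    values, sidecar = _read_container(path)
    if sidecar.get("type") != "beam_response":
        raise ValueError(f"container at {path} is not a beam-response")
    geometry = _geometry_from(sidecar)
    interp = sidecar.get("interpolated_mask_rle")
    return BeamResponse(
        values, geometry, source=sidecar.get("source", "external"),
        interpolated_mask=None if interp is None else rle_decode(interp, geometry.shape),
        normalization=sidecar.get("normalization", "central_axis"),
        label=sidecar.get("label", ""),
    )


def read_any(path):
    """Read a container regardless of payload type (image, PSM, beam-response)."""
    _, sidecar = _read_container(path)
    kind = sidecar.get("type")
    if kind == "image":
        return read_image(path)
    if kind == "psm":
        return read_psm(path)
    if kind == "beam_response":
        return read_beam_response(path)
    raise ValueError(f"unknown container type {kind!r}")


def read_text_matrix(path, geometry: PanelGeometry | None = None, kind: str = "raw") -> EpidImage:
    """Read a (optionally gzipped) whitespace-separated text matrix fixture.

    If no geometry is given, a JSON sidecar is used when present; otherwise
    the panel defaults to 400 mm active width.
    """
    values = np.atleast_2d(np.loadtxt(path))
    sidecar_path = Path(str(path) + ".json")
    if geometry is None:
        if sidecar_path.exists():
            with open(sidecar_path) as fh:
                sidecar = json.load(fh)
            g = sidecar.get("geometry", {})
            geometry = PanelGeometry(
                g.get("n_rows", values.shape[0]),
                g.get("n_cols", values.shape[1]),
                g.get("active_width_mm", 400.0),
            )
            kind = sidecar.get("kind", kind)
        else:
            geometry = PanelGeometry(values.shape[0], values.shape[1], 400.0)
    return EpidImage(values, geometry, kind=kind)


# ---------------------------------------------------------------------------
# DICOM RT image (read-only, optional)

_RTIMAGE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.1"


def read_rtimage(path) -> EpidImage:
    """Read a DICOM RT Image file into an :class:`EpidImage` (kind=corrected).

    Applies rescale slope/intercept and maps the pixel spacing to the
    isocenter plane using SAD/SID magnification when both are present.
    Real-world portal images come flood-corrected, hence ``kind='corrected'``.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    sop = str(getattr(ds, "SOPClassUID", ""))
    modality = str(getattr(ds, "Modality", ""))
    if sop != _RTIMAGE_SOP_CLASS and modality != "RTIMAGE":
        raise ValueError(f"{path} is not a DICOM RT Image (modality {modality or 'unknown'})")
    spacing = getattr(ds, "ImagePlanePixelSpacing", None) or getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise ValueError("RT image lacks ImagePlanePixelSpacing / PixelSpacing")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = ds.pixel_array.astype(np.float64) * slope + intercept
    pitch = float(spacing[1])
    sid = getattr(ds, "RTImageSID", None)
    sad = getattr(ds, "RadiationMachineSAD", None)
    if sid and sad:
        pitch *= float(sad) / float(sid)
    n_rows, n_cols = values.shape
    geometry = PanelGeometry(n_rows, n_cols, pitch * n_cols)
    meta = {"source": str(path), "modality": "RTIMAGE"}
    return EpidImage(np.maximum(values, 0.0), geometry, kind="corrected", meta=meta)


# ---------------------------------------------------------------------------
# configuration files


def load_config_file(path) -> dict:
    """Load a YAML/JSON experiment configuration into a plain dict.

    Validation (including unknown-key rejection) happens in
    :func:`epidpsm.experiments.config_from_dict`.
    """
    with open(path) as fh:
        if str(path).endswith(".json"):
            doc = json.load(fh)
        else:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError("configuration file must contain a mapping")
    return doc
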