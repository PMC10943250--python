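"""File formats: TIFF interferograms with JSON sidecars, npz field containers,
CSV marker tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from polholo.phantom import ComplexField, DEFAULT_PIXEL_PITCH
from polholo.holography import Interferogram

__all__ = [
    "save_field",
    "load_field",
    "save_interferogram",
    "load_interferogram",
    "save_marker_table",
    "load_marker_table",
    "save_json",
    "load_json",
]


def save_field(path, field: ComplexField) -> None:
    """Lossless float round-trip container for a complex field."""
    np.savez(path, ux=field.ux, uy=field.uy, pixel_pitch=field.pixel_pitch)


def load_field(path) -> ComplexField:
    with np.load(path) as z:
        return ComplexField(ux=z["ux"], uy=z["uy"], pixel_pitch=float(z["pixel_pitch"]))


def save_interferogram(path, ig: Interferogram, bits: int = 16) -> None:
    """Write an interferogram as 8- or 16-bit grayscale TIFF + JSON sidecar."""
    path = Path(path)
    if bits not in (8, 16):
        raise ValueError("bits must be 8 or 16")
    levels = 2**bits - 1
    top = float(ig.intensity.max())
    scaled = np.zeros_like(ig.intensity) if top == 0 else ig.intensity / top
    raster = np.round(scaled * levels).astype(np.uint8 if bits == 8 else np.uint16)
    tifffile.imwrite(path, raster)
    sidecar = {
        "analyzer_omega": ig.analyzer_omega,
        "carrier": list(ig.carrier),
        "ref_amplitude": ig.ref_amplitude,
        "intensity_max": top,
        "bits": bits,
        "quantize_bits": ig.quantize_bits,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_interferogram(path) -> Interferogram:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    raster = tifffile.imread(path).astype(float)
    levels = 2 ** meta["bits"] - 1
    intensity = raster / levels * meta["intensity_max"]
    return Interferogram(
        intensity=intensity,
        analyzer_omega=meta["analyzer_omega"],
        carrier=tuple(meta["carrier"]),
        ref_amplitude=meta["ref_amplitude"],
        quantize_bits=meta.get("quantize_bits"),
    )


def save_marker_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_marker_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce))


def load_json(path):
    return json.loads(Path(path).read_text())


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
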