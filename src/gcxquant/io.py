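"""Reading and writing the package's file formats.

Two-channel images travel as multi-page TIFF with the physical pixel size in
the resolution tags; surface polylines as CSV point lists (x_um, y_um);
profiles and measurement tables as tidy CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_two_channel_tiff",
    "read_two_channel_tiff",
    "read_polyline_csv",
    "write_polyline_csv",
    "measurements_to_frame",
    "write_json",
]


def write_two_channel_tiff(path, image: np.ndarray, pixel_size: float) -> None:
    """Write a (C, H, W) stack as multi-page TIFF with pixel size metadata."""
    arr = np.asarray(image, dtype=np.float32)
    if arr.ndim != 3:
        raise ValueError("expected a (channels, rows, cols) stack")
    tifffile.imwrite(
        path,
        arr,
        resolution=(1.0 / pixel_size, 1.0 / pixel_size),
        resolutionunit="MICROMETER",
        metadata={"axes": "CYX", "pixel_size_um": pixel_size},
    )


def read_two_channel_tiff(path, pixel_size: float | None = None):
    """Read a multi-page TIFF; returns (stack (C,H,W), pixel_size µm).

    The pixel size comes from the resolution tags unless overridden.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray().astype(float)
        if pixel_size is None:
            page = tif.pages[0]
            try:
                num, den = page.tags["XResolution"].value
                pixel_size = den / num
            except (KeyError, ZeroDivisionError, TypeError):
                raise ValueError(
                    "pixel size missing from TIFF metadata; pass pixel_size explicitly"
                )
    if arr.ndim == 2:
        arr = arr[None]
    return arr, float(pixel_size)


def read_polyline_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def write_polyline_csv(path, polyline: np.ndarray) -> None:
    pd.DataFrame(np.asarray(polyline, dtype=float), columns=["x_um", "y_um"]).to_csv(
        path, index=False
    )


def measurements_to_frame(measurements) -> pd.DataFrame:
    """Tidy table of ThicknessMeasurement records."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "site_id": m.site_id,
                "animal_id": m.animal_id,
                "x_lectin_um": m.x_inflection_lectin,
                "x_marker_um": m.x_inflection_marker,
                "T_um": m.thickness,
                "method": m.method,
                "qc_flags": ";".join(m.qc_flags),
                "ok": m.ok,
            }
        )
    return pd.DataFrame(rows)


class _Encoder(json.JSONEncoder):
    def default(self, o):
        if is_dataclass(o) and not isinstance(o, type):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_Encoder)
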