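"""Intensity profiles and region-level intensity / area metrics.

A measurement line is drawn perpendicular to the ependymal surface, from the
ventricular lumen toward the brain parenchyma; the fluorescence intensity of
each channel sampled along that line is the :class:`IntensityProfile` that the
curve-fitting stage consumes.  This module also covers region metrics used for
inflammation readouts: mean intensity over a mask, band masks hugging the
surface (e.g. the 17-µm periventricular band), per-cell positivity rates, and
connected-component areas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from skimage.measure import label as cc_label

from .geometry import check_simple, polyline_point_and_normal, signed_distance_field

__all__ = [
    "IntensityProfile",
    "RegionMetric",
    "extract_line_profile",
    "subtract_background",
    "region_mean_intensity",
    "band_mask_along_surface",
    "positivity_rate",
    "labeled_region_areas",
]

MIN_SAMPLES = 16


@dataclass(frozen=True)
class IntensityProfile:
    """1-D fluorescence intensity vs position (µm) for one channel.

    Positions are strictly increasing and uniformly spaced; by convention the
    origin (position 0) sits at the luminal end of the measurement line and
    positions grow toward the parenchyma.  Intensities are clamped at 0.
    """

    positions: np.ndarray
    intensities: np.ndarray
    channel_label: str = ""
    origin_convention: str = "lumen->parenchyma"

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        inten = np.clip(np.asarray(self.intensities, dtype=float), 0.0, None)
        if pos.ndim != 1 or pos.shape != inten.shape:
            raise ValueError("positions and intensities must be matching 1-D arrays")
        if len(pos) < MIN_SAMPLES:
            raise ValueError(f"profile needs at least {MIN_SAMPLES} samples, got {len(pos)}")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("positions must be uniformly spaced")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position_um": self.positions,
                "intensity": self.intensities,
                "channel": self.channel_label,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, channel: str | None = None) -> "IntensityProfile":
        df = pd.read_csv(path)
        if channel is not None:
            df = df[df["channel"] == channel]
        return cls(
            positions=df["position_um"].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            channel_label=channel or (str(df["channel"].iloc[0]) if "channel" in df else ""),
        )


@dataclass(frozen=True)
class RegionMetric:
    """Mean intensity (a.u./pixel) over a labeled region of interest."""

    mean_intensity: float
    pixel_count: int
    region_label: str = ""

    def __post_init__(self):
        if self.pixel_count <= 0:
            raise ValueError("region must contain at least one pixel")


def _as_channel_stack(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("image must be (H, W) or (C, H, W)")
    return arr


def extract_line_profile(
    image: np.ndarray,
    pixel_size: float,
    p0: tuple[float, float],
    p1: tuple[float, float],
    averaging_width: int = 3,
    channel_labels: tuple[str, ...] | None = None,
) -> list[IntensityProfile]:
    """Sample a measurement line perpendicular to the surface.

    ``p0`` (luminal end) and ``p1`` are physical (x, y) coordinates in µm.
    The line is sampled at pixel-size steps with bilinear interpolation; each
    sample is averaged over ``averaging_width`` parallel samples spaced one
    pixel apart perpendicular to the line.  Returns one profile per channel,
    positions starting at 0 at ``p0``.
    """
    stack = _as_channel_stack(image)
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if averaging_width < 1:
        raise ValueError("averaging_width must be >= 1")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    n = int(np.floor(length / pixel_size)) + 1
    if n < MIN_SAMPLES:
        raise ValueError(
            f"measurement line of {length:.3g} µm yields {n} samples; need >= {MIN_SAMPLES}"
        )
    t_hat = (p1 - p0) / length
    n_hat = np.array([-t_hat[1], t_hat[0]])
    s = np.arange(n) * pixel_size
    centers = p0[None, :] + s[:, None] * t_hat[None, :]
    offsets = (np.arange(averaging_width) - (averaging_width - 1) / 2.0) * pixel_size
    pts = centers[:, None, :] + offsets[None, :, None] * n_hat[None, None, :]

    H, W = stack.shape[1:]
    for end, name in ((p0, "p0"), (p1, "p1")):
        if not (0 <= end[0] <= (W - 1) * pixel_size and 0 <= end[1] <= (H - 1) * pixel_size):
            raise ValueError(f"{name} lies outside the image")

    # map_coordinates expects (row, col) = (y/px, x/px)
    rows = pts[..., 1].ravel() / pixel_size
    cols = pts[..., 0].ravel() / pixel_size
    out = []
    for c, chan in enumerate(stack):
        vals = map_coordinates(chan, [rows, cols], order=1, mode="nearest")
        prof = vals.reshape(n, averaging_width).mean(axis=1)
        lab = channel_labels[c] if channel_labels else f"ch{c}"
        out.append(IntensityProfile(positions=s, intensities=prof, channel_label=lab))
    return out


def subtract_background(
    profile: IntensityProfile,
    method: str = "percentile",
    value_or_q: float = 5.0,
) -> IntensityProfile:
    """Subtract a background estimate from a profile, clamping at zero.

    ``method="constant"`` subtracts ``value_or_q`` directly;
    ``method="percentile"`` subtracts the q-th percentile of the profile's
    own intensities (q in (0, 50]).
    """
    if method == "constant":
        if value_or_q < 0:
            raise ValueError("constant background must be >= 0")
        bg = float(value_or_q)
    elif method == "percentile":
        if not 0 < value_or_q <= 50:
            raise ValueError("percentile q must be in (0, 50]")
        bg = float(np.percentile(profile.intensities, value_or_q))
    else:
        raise ValueError(f"unknown background method {method!r}")
    new = np.clip(profile.intensities - bg, 0.0, None)
    if np.all(new == 0) and np.any(profile.intensities > 0):
        warnings.warn(
            "background estimate exceeds every intensity; profile is all zero",
            stacklevel=2,
        )
    return replace(profile, intensities=new)


def region_mean_intensity(
    channel: np.ndarray, mask: np.ndarray, region_label: str = ""
) -> RegionMetric:
    """Mean intensity of one channel over a binary region."""
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    count = int(mask.sum())
    if count == 0:
        raise ValueError("empty region mask")
    return RegionMetric(
        mean_intensity=float(channel[mask].mean()),
        pixel_count=count,
        region_label=region_label,
    )


def band_mask_along_surface(
    surface_polyline: np.ndarray,
    shape: tuple[int, int],
    pixel_size: float,
    band_width: float,
    side: str = "parenchymal",
) -> np.ndarray:
    """Binary mask of all pixels within ``band_width`` µm of the surface.

    ``side`` selects the parenchymal (signed distance > 0) or luminal
    (< 0) side.  A zero band width yields an empty mask (documented
    contract); the band never crosses to the other side of the surface.
    """
    check_simple(surface_polyline)
    if band_width < 0:
        raise ValueError("band_width must be >= 0")
    if band_width == 0:
        return np.zeros(shape, dtype=bool)
    d, _ = signed_distance_field(surface_polyline, shape, pixel_size)
    if side == "parenchymal":
        return (d > 0) & (d <= band_width)
    if side == "luminal":
        return (d < 0) & (d >= -band_width)
    raise ValueError("side must be 'parenchymal' or 'luminal'")


def positivity_rate(per_cell_values, threshold: float) -> float:
    """Percent of cells with intensity strictly above ``threshold``.

    Ties at the threshold count as negative (fixed rule for
    reproducibility).
    """
    vals = np.asarray(per_cell_values, dtype=float)
    if vals.size == 0:
        raise ValueError("positivity_rate needs at least one cell")
    return 100.0 * float(np.count_nonzero(vals > threshold)) / vals.size


def labeled_region_areas(
    mask: np.ndarray, pixel_size: float, min_area_px: int = 4
) -> list[float]:
    """Areas (µm²) of 8-connected components of a binary mask.

    Components below ``min_area_px`` pixels are dropped as noise.
    """
    if pixel_size <= 0:
        raise ValueError("pixel size must be known and positive")
    lbl = cc_label(np.asarray(mask, dtype=bool), connectivity=2)
    counts = np.bincount(lbl.ravel())[1:]  # skip background
    keep = counts[counts >= min_area_px]
    return [float(c) * pixel_size**2 for c in keep]
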