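"""Thickness measurements and surface coverage with denudation exclusion.

Glycocalyx thickness at one site is the distance between the lectin
rising-edge inflection (outer glycocalyx boundary) and the cell-marker
rising-edge inflection (apical membrane) along a measurement line cast
perpendicular to the surface.  Surface coverage is the percent of the
ANALYZABLE ventricular lining — total arc length minus marker-negative
(denuded) gaps — that is positive for the glycan stain.  Denuded stretches
never enter the coverage numerator or denominator, so the reported
percentages reflect glycocalyx changes only on morphologically intact
ependyma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.filters import threshold_otsu

from .fitting import FitError, locate_rising_inflection
from .geometry import arc_length, check_simple, polyline_point_and_normal
from .profiles import IntensityProfile, extract_line_profile

__all__ = [
    "ThicknessMeasurement",
    "CoverageResult",
    "thickness_at_site",
    "thickness_survey",
    "coverage",
    "detect_denuded_intervals",
]


@dataclass(frozen=True)
class ThicknessMeasurement:
    """Paired inflection positions and their distance T at one site.

    Negative T is flagged, never clamped or dropped: clamping would bias
    group means.  ``ok`` is False when either channel's fit failed; failed
    sites are excluded from summaries but counted in QC reports.
    """

    site_id: int | str
    x_inflection_lectin: float | None
    x_inflection_marker: float | None
    thickness: float | None
    method: str
    animal_id: str = ""
    qc_flags: tuple[str, ...] = ()
    ok: bool = True

    @property
    def failed(self) -> bool:
        return not self.ok


@dataclass(frozen=True)
class CoverageResult:
    """Coverage of the analyzable (non-denuded) surface by the glycan stain."""

    total_surface_length: float
    denuded_length_excluded: float
    positive_length: float
    denuded_intervals: tuple[tuple[float, float], ...] = ()

    @property
    def analyzable_length(self) -> float:
        return self.total_surface_length - self.denuded_length_excluded

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.positive_length / self.analyzable_length

    def __post_init__(self):
        if self.analyzable_length <= 0:
            raise ValueError("no analyzable ependyma (analyzable length = 0)")
        if self.positive_length > self.analyzable_length + 1e-9:
            raise ValueError("positive length exceeds analyzable length")


def thickness_at_site(
    lectin: IntensityProfile,
    marker: IntensityProfile,
    method: str = "polynomial8",
    site_id: int | str = 0,
    animal_id: str = "",
    rmse_frac_max: float = 0.25,
    edge_margin_um: float = 0.05,
) -> ThicknessMeasurement:
    """Measure glycocalyx thickness from one lectin/marker profile pair.

    Both profiles must share the position grid (same measurement line).  Each
    channel's rising-phase inflection is localized independently;
    T = marker − lectin.  QC flags: ``negative_thickness``, per-channel
    ``*_edge_at_window_bound`` (inflection within ``edge_margin_um`` of the
    search window edge) and ``*_rmse_high`` (fit RMSE above ``rmse_frac_max``
    of the profile's intensity range).  A failed fit in either channel marks
    the site failed rather than raising.
    """
    if len(lectin.positions) != len(marker.positions) or not np.allclose(
        lectin.positions, marker.positions
    ):
        raise ValueError("lectin and marker profiles must share the position grid")

    flags: list[str] = []
    results = {}
    for name, prof in (("lectin", lectin), ("marker", marker)):
        try:
            est, fit = locate_rising_inflection(prof, method=method)
        except FitError as err:
            return ThicknessMeasurement(
                site_id=site_id,
                animal_id=animal_id,
                x_inflection_lectin=None,
                x_inflection_marker=None,
                thickness=None,
                method=method,
                qc_flags=(f"{name}_fit_failed: {err}",),
                ok=False,
            )
        results[name] = est
        lo, hi = est.search_window
        if min(est.position - lo, hi - est.position) < edge_margin_um:
            flags.append(f"{name}_edge_at_window_bound")
        rng_y = float(np.ptp(prof.intensities))
        if rng_y > 0 and fit.rmse > rmse_frac_max * rng_y:
            flags.append(f"{name}_rmse_high")

    T = results["marker"].position - results["lectin"].position
    if T < 0:
        flags.append("negative_thickness")
    return ThicknessMeasurement(
        site_id=site_id,
        animal_id=animal_id,
        x_inflection_lectin=results["lectin"].position,
        x_inflection_marker=results["marker"].position,
        thickness=float(T),
        method=method,
        qc_flags=tuple(flags),
        ok=True,
    )


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------


def _auto_threshold(channel: np.ndarray, band_samples: np.ndarray, method: str) -> float:
    """Positivity threshold for surface-band intensities.

    ``"background"`` (default): background (5th percentile of the whole
    channel) plus 30% of the span up to the 95th percentile of the band
    samples — robust when the band is unimodal (fully covered or fully
    denuded surfaces).  ``"otsu"``: Otsu's threshold over the band samples.
    """
    if method == "otsu":
        return float(threshold_otsu(band_samples))
    if method == "background":
        bg = float(np.percentile(channel, 5))
        hi = float(np.percentile(band_samples, 95))
        # the epsilon makes a signal-free band read as fully negative even
        # when the channel is exactly constant (no noise)
        return bg + 0.3 * max(hi - bg, 0.0) + 1e-9 + 1e-6 * abs(hi)
    raise ValueError(f"unknown threshold method {method!r}")


def _band_means(channel, pts, normals, offsets, pixel_size):
    """Mean channel intensity at pts + offset·normal for each arc sample."""
    samples = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    rows = samples[..., 1].ravel() / pixel_size
    cols = samples[..., 0].ravel() / pixel_size
    vals = map_coordinates(channel, [rows, cols], order=1, mode="nearest")
    return vals.reshape(len(pts), len(offsets)).mean(axis=1)


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs."""
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))[0]
    return list(zip(idx[0::2], idx[1::2]))


def detect_denuded_intervals(
    marker_band: np.ndarray,
    arc_positions: np.ndarray,
    marker_threshold: float,
    min_gap_um: float = 5.0,
) -> list[tuple[float, float]]:
    """Marker-negative contiguous runs of at least ``min_gap_um`` (arc µm)."""
    step = float(arc_positions[1] - arc_positions[0]) if len(arc_positions) > 1 else 0.0
    out = []
    for i0, i1 in _runs(marker_band < marker_threshold):
        length = (i1 - i0) * step
        if length >= min_gap_um:
            out.append((float(arc_positions[i0]), float(arc_positions[i0]) + length))
    return out


def coverage(
    image: np.ndarray,
    pixel_size: float,
    surface_polyline: np.ndarray,
    lectin_channel: int = 0,
    marker_channel: int = 1,
    thresholds: tuple[float, float] | None = None,
    threshold_method: str = "background",
    min_gap_um: float = 5.0,
    lectin_offsets_um: tuple[float, float] = (-0.2, 0.5),
    marker_offsets_um: tuple[float, float] = (0.3, 1.2),
) -> CoverageResult:
    """Glycan coverage of the analyzable surface, excluding denudation.

    The surface is sampled at pixel-size arc steps.  At each step the marker
    and lectin channels are averaged over short stretches of the surface
    normal (offsets in µm, parenchymal positive).  A step belongs to a
    DENUDED gap when the marker band intensity stays below its threshold over
    a contiguous run of at least ``min_gap_um``; among the remaining intact
    steps, a step is POSITIVE when the lectin band intensity reaches its
    threshold.  ``thresholds=(lectin, marker)`` overrides the automatic rule.
    """
    check_simple(surface_polyline)
    if thresholds is not None and any(t < 0 for t in thresholds):
        raise ValueError("thresholds must be >= 0")
    img = np.asarray(image, dtype=float)
    total = float(arc_length(surface_polyline)[-1])
    u = np.arange(0.0, total, pixel_size)
    pts, normals = polyline_point_and_normal(surface_polyline, u)

    def offsets(rng):
        lo, hi = rng
        n = max(2, int(round((hi - lo) / pixel_size)) + 1)
        return np.linspace(lo, hi, n)

    lec = _band_means(img[lectin_channel], pts, normals, offsets(lectin_offsets_um), pixel_size)
    mar = _band_means(img[marker_channel], pts, normals, offsets(marker_offsets_um), pixel_size)

    if thresholds is not None:
        thr_l, thr_m = thresholds
    else:
        thr_l = _auto_threshold(img[lectin_channel], lec, threshold_method)
        thr_m = _auto_threshold(img[marker_channel], mar, threshold_method)

    denuded_iv = detect_denuded_intervals(mar, u, thr_m, min_gap_um=min_gap_um)
    denuded_mask = np.zeros(len(u), dtype=bool)
    for a, b in denuded_iv:
        denuded_mask |= (u >= a) & (u < b)
    intact = ~denuded_mask
    positive = intact & (lec >= thr_l)

    step = pixel_size
    return CoverageResult(
        total_surface_length=len(u) * step,
        denuded_length_excluded=float(denuded_mask.sum()) * step,
        positive_length=float(positive.sum()) * step,
        denuded_intervals=tuple(denuded_iv),
    )


def thickness_survey(
    image: np.ndarray,
    pixel_size: float,
    surface_polyline: np.ndarray,
    n_sites: int = 16,
    seed: int = 0,
    method: str = "polynomial8",
    line_half_length_um: float = 2.5,
    min_spacing_um: float = 1.0,
    averaging_width: int = 3,
    marker_channel: int = 1,
    threshold_method: str = "background",
    min_gap_um: float = 5.0,
    animal_id: str = "",
) -> list[ThicknessMeasurement]:
    """Measure thickness at ``n_sites`` random intact surface points.

    Site positions are drawn uniformly (seeded) along the surface arc,
    excluding detected denuded stretches; at each site a normal measurement
    line (luminal → parenchymal, length 2·``line_half_length_um``) is cast and
    :func:`thickness_at_site` applied.  Raises when the surface is shorter
    than ``n_sites · min_spacing_um`` or offers no intact stretch.
    """
    check_simple(surface_polyline)
    img = np.asarray(image, dtype=float)
    total = float(arc_length(surface_polyline)[-1])
    if total <= n_sites * min_spacing_um:
        raise ValueError("surface too short for the requested number of sites")

    u_grid = np.arange(0.0, total, pixel_size)
    pts_g, normals_g = polyline_point_and_normal(surface_polyline, u_grid)
    mar_off = np.linspace(0.3, 1.2, max(2, int(round(0.9 / pixel_size)) + 1))
    mar = _band_means(img[marker_channel], pts_g, normals_g, mar_off, pixel_size)
    thr_m = _auto_threshold(img[marker_channel], mar, threshold_method)
    denuded_iv = detect_denuded_intervals(mar, u_grid, thr_m, min_gap_um=min_gap_um)

    intact_mask = np.ones(len(u_grid), dtype=bool)
    for a, b in denuded_iv:
        intact_mask &= ~((u_grid >= a) & (u_grid < b))
    # keep sites whose measurement window stays clear of the image border
    H, W = img.shape[-2:]
    ok_pos = []
    for i in np.nonzero(intact_mask)[0]:
        p = pts_g[i]
        n = normals_g[i]
        p0 = p - line_half_length_um * n
        p1 = p + line_half_length_um * n
        if all(
            0 <= q[0] <= (W - 1) * pixel_size and 0 <= q[1] <= (H - 1) * pixel_size
            for q in (p0, p1)
        ):
            ok_pos.append(i)
    if not ok_pos:
        raise ValueError("no intact, fully-contained surface stretch to sample")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(ok_pos), size=n_sites, replace=len(ok_pos) < n_sites)
    out = []
    for k, i in enumerate(chosen):
        p = pts_g[i]
        n = normals_g[i]
        p0 = p - line_half_length_um * n  # luminal end
        p1 = p + line_half_length_um * n
        lec_prof, mar_prof = extract_line_profile(
            img, pixel_size, p0, p1, averaging_width=averaging_width,
            channel_labels=("lectin", "marker"),
        )
        out.append(
            thickness_at_site(
                lec_prof, mar_prof, method=method, site_id=k, animal_id=animal_id
            )
        )
    return out
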