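"""Synthetic profiles, two-channel surface images, and cohorts with ground truth.

The generator model mirrors the measurement geometry: a measurement line runs
from the ventricular lumen (position 0) toward the brain parenchyma.  The
lectin (glycan) channel forms a thin band whose rising edge marks the outer
glycocalyx boundary; the cell-body marker (S100β) channel rises at the apical
membrane.  The separation between the two rising-edge midpoints is the true
glycocalyx thickness T.

With σ the standard logistic function, the noise-free single-site model is::

    lectin(x) = baseline + A_L · [σ((x − x_L)/s) − σ((x − x_L − band)/s)]
    marker(x) = baseline + A_M · σ((x − x_L − T)/s)

followed by Gaussian blur (optical point-spread) and additive Gaussian noise,
sampled every ``pixel_size``.  Because the logistic derivative is symmetric
about its midpoint, Gaussian blur leaves the rising-phase inflection of each
channel exactly at the recorded ground-truth edge, which is what makes these
generators usable as oracles for the analysis stack.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import expit

from .geometry import arc_length, check_simple, signed_distance_field
from .profiles import IntensityProfile

__all__ = [
    "ProfileSpec",
    "SurfaceImageSpec",
    "CohortPreset",
    "SyntheticGroundTruth",
    "generate_profile_pair",
    "generate_surface_image",
    "generate_cohort",
    "AGING_THICKNESS_LEL",
    "AGING_THICKNESS_PNA",
    "AGING_THICKNESS_RCA1",
    "AGING_COVERAGE",
    "IVH_COVERAGE_PNA",
    "CYTOPLASMIC_PNA_RATE",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Parameters of one simulated two-channel line profile.

    Distances in µm, intensities in arbitrary units.  ``x_lectin_edge`` is the
    midpoint of the lectin rising edge (outer glycocalyx boundary);
    ``thickness_true`` separates it from the marker rising edge (apical
    membrane).  ``lectin_band_width`` makes the lectin channel a band (rise
    then decay) rather than a step — the glycocalyx is a thin layer, so only
    its RISING edge carries the boundary.  ``edge_width`` is the logistic
    slope scale s.
    """

    x_lectin_edge: float = 1.5
    thickness_true: float = 0.5
    amplitude_lectin: float = 100.0
    amplitude_marker: float = 100.0
    baseline: float = 10.0
    edge_width: float = 0.1
    lectin_band_width: float = 1.5
    psf_sigma: float = 0.15
    noise_sd: float = 0.0
    pixel_size: float = 0.1
    window_length: float = 5.0

    def validate(self) -> None:
        if self.thickness_true < 0:
            raise ValueError("thickness_true must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_lectin <= 0 or self.amplitude_marker <= 0:
            raise ValueError("amplitudes must be > 0")
        if self.edge_width <= 0:
            raise ValueError("edge_width must be > 0")
        margin = 3.0 * self.edge_width
        if self.x_lectin_edge - margin < 0 or (
            self.x_lectin_edge + self.thickness_true + margin > self.window_length
        ):
            raise ValueError(
                "window too short: it must contain both edges plus a margin of "
                f"3·edge_width = {margin:.3g} µm on each side"
            )


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Truth attached to every synthetic sample.

    ``lectin_edge_um``/``marker_edge_um`` are the analytic rising-phase
    inflection positions of the noise-free model.  For surface scenes the
    coverage annotation (positive / denuded arc intervals) is exact by
    construction.  Regenerating with the same spec and seed reproduces the
    sample bit-for-bit.
    """

    lectin_edge_um: float | None = None
    marker_edge_um: float | None = None
    thickness_true: float | np.ndarray | None = None
    coverage_fraction_true: float | None = None
    denudation_intervals: tuple[tuple[float, float], ...] = ()
    positive_intervals: tuple[tuple[float, float], ...] = ()
    surface_length_um: float | None = None
    seed: int | None = None
    spec: dict = field(default_factory=dict)


def _logistic_band(x, x_rise, x_fall, s):
    return expit((x - x_rise) / s) - expit((x - x_fall) / s)


def generate_profile_pair(
    spec: ProfileSpec, seed: int
) -> tuple[IntensityProfile, IntensityProfile, SyntheticGroundTruth]:
    """Simulate one lectin/marker profile pair on a shared position grid."""
    spec.validate()
    rng = np.random.default_rng(seed)
    n = int(round(spec.window_length / spec.pixel_size)) + 1
    x = np.arange(n) * spec.pixel_size

    xl = spec.x_lectin_edge
    xm = xl + spec.thickness_true
    lectin = spec.baseline + spec.amplitude_lectin * _logistic_band(
        x, xl, xl + spec.lectin_band_width, spec.edge_width
    )
    marker = spec.baseline + spec.amplitude_marker * expit((x - xm) / spec.edge_width)

    if spec.psf_sigma > 0:
        sig = spec.psf_sigma / spec.pixel_size
        lectin = gaussian_filter1d(lectin, sig, mode="nearest")
        marker = gaussian_filter1d(marker, sig, mode="nearest")
    if spec.noise_sd > 0:
        lectin = lectin + rng.normal(0.0, spec.noise_sd, size=n)
        marker = marker + rng.normal(0.0, spec.noise_sd, size=n)

    truth = SyntheticGroundTruth(
        lectin_edge_um=xl,
        marker_edge_um=xm,
        thickness_true=spec.thickness_true,
        seed=seed,
        spec=asdict(spec),
    )
    return (
        IntensityProfile(x, lectin, channel_label="lectin"),
        IntensityProfile(x, marker, channel_label="marker"),
        truth,
    )


# ---------------------------------------------------------------------------
# surface scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurfaceImageSpec:
    """A curved epithelial surface scene for coverage / survey measurements.

    The surface is a sinusoidal polyline (or an explicit user polyline) drawn
    left-to-right with the lumen above it; ``coverage_fraction_true`` is the
    proportion of the ANALYZABLE surface (total minus denudation) bearing
    glycocalyx, realized as exact arc-length intervals.  Within denudation
    intervals the marker channel stays at baseline (cell layer lost), and the
    glycan band is absent.  ``segment_um`` sets the spatial scale of the
    positive/negative patchwork.
    """

    shape: tuple[int, int] = (160, 1024)  # rows, cols
    pixel_size: float = 0.25
    surface_amplitude: float = 2.0
    surface_period: float = 60.0
    surface_depth_frac: float = 0.4
    surface_polyline: tuple | None = None
    coverage_fraction_true: float = 1.0
    denudation_intervals: tuple[tuple[float, float], ...] = ()
    thickness_mean: float = 0.5
    segment_um: float = 20.0
    amplitude_lectin: float = 100.0
    amplitude_marker: float = 100.0
    baseline: float = 10.0
    edge_width: float = 0.1
    lectin_band_width: float = 1.5
    psf_sigma: float = 0.15
    noise_sd: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.coverage_fraction_true <= 1.0:
            raise ValueError("coverage_fraction_true must be in [0, 1]")
        if self.pixel_size <= 0 or self.thickness_mean < 0:
            raise ValueError("pixel_size must be > 0 and thickness_mean >= 0")
        ivals = sorted(self.denudation_intervals)
        for a, b in ivals:
            if not 0 <= a < b:
                raise ValueError("denudation intervals must be non-empty and within the arc")
        for (a0, b0), (a1, b1) in zip(ivals, ivals[1:]):
            if a1 < b0:
                raise ValueError("denudation intervals must be disjoint")

    def build_polyline(self) -> np.ndarray:
        if self.surface_polyline is not None:
            pts = np.asarray(self.surface_polyline, dtype=float)
        else:
            rows, cols = self.shape
            xs = np.arange(cols) * self.pixel_size
            y0 = rows * self.pixel_size * self.surface_depth_frac
            ys = y0 + self.surface_amplitude * np.sin(2 * np.pi * xs / self.surface_period)
            pts = np.column_stack([xs, ys])
        check_simple(pts)
        return pts


def _interval_length(intervals) -> float:
    return float(sum(b - a for a, b in intervals))


def _complement(intervals, total: float):
    """Complement of sorted disjoint intervals within [0, total]."""
    out, cursor = [], 0.0
    for a, b in sorted(intervals):
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < total:
        out.append((cursor, total))
    return out


def _membership(u: np.ndarray, intervals) -> np.ndarray:
    # right-inclusive so the final arc sample belongs to a closing interval
    m = np.zeros(u.shape, dtype=bool)
    for a, b in intervals:
        m |= (u >= a) & (u <= b)
    return m


def _draw_positive_intervals(analyzable, fraction, segment_um, rng):
    """Choose glycan-positive arc intervals totalling exactly fraction·analyzable."""
    target = fraction * _interval_length(analyzable)
    if target <= 0:
        return ()
    chunks = []
    for a, b in analyzable:
        edges = np.arange(a, b, segment_um)
        for lo in edges:
            chunks.append((float(lo), float(min(lo + segment_um, b))))
    order = rng.permutation(len(chunks))
    chosen, acc = [], 0.0
    for i in order:
        lo, hi = chunks[i]
        w = hi - lo
        if acc + w <= target + 1e-12:
            chosen.append((lo, hi))
            acc += w
        elif target - acc > 1e-9:
            chosen.append((lo, lo + (target - acc)))
            acc = target
        if acc >= target - 1e-12:
            break
    return tuple(sorted(chosen))


def generate_surface_image(
    spec: SurfaceImageSpec, seed: int
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a two-channel (lectin, marker) image of a curved surface.

    Along any normal through a covered, non-denuded surface point the two
    channels follow the line-profile model with the local thickness; within
    denudation intervals the marker stays at baseline.  Returns an array of
    shape (2, rows, cols) and the exact annotation.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    poly = spec.build_polyline()
    total = float(arc_length(poly)[-1])
    for a, b in spec.denudation_intervals:
        if b > total:
            raise ValueError("denudation interval extends beyond the surface arc length")

    analyzable = _complement(spec.denudation_intervals, total)
    positive = _draw_positive_intervals(
        analyzable, spec.coverage_fraction_true, spec.segment_um, rng
    )

    d, u = signed_distance_field(poly, spec.shape, spec.pixel_size)
    covered = _membership(u, positive)
    denuded = _membership(u, spec.denudation_intervals)
    intact = ~denuded

    s = spec.edge_width
    T = spec.thickness_mean
    lectin = np.full(spec.shape, spec.baseline, dtype=float)
    band = spec.amplitude_lectin * _logistic_band(d, -T, spec.lectin_band_width - T, s)
    lectin[covered] += band[covered]
    marker = np.full(spec.shape, spec.baseline, dtype=float)
    rise = spec.amplitude_marker * expit(d / s)
    marker[intact] += rise[intact]

    img = np.stack([lectin, marker])
    if spec.psf_sigma > 0:
        sig = spec.psf_sigma / spec.pixel_size
        img = np.stack([gaussian_filter(c, sig, mode="nearest") for c in img])
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    analyzable_len = _interval_length(analyzable)
    truth = SyntheticGroundTruth(
        thickness_true=T,
        coverage_fraction_true=(
            _interval_length(positive) / analyzable_len if analyzable_len > 0 else None
        ),
        denudation_intervals=tuple(spec.denudation_intervals),
        positive_intervals=positive,
        surface_length_um=total,
        seed=seed,
        spec=asdict(spec),
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortPreset:
    """Group-level targets for a hierarchical (animal / site) cohort.

    ``means`` and ``sems`` are the per-group mean and standard error over
    animals.  The between-animal SD defaults to S.E.M·√n_animals (the printed
    dispersion is an animal-level standard error); the within-animal SD
    defaults to twice that, reflecting site-to-site scatter dominating in
    16-sites-per-animal designs.  Values in percent units are clipped to
    [0, 100] (a stated generator contract).
    """

    labels: tuple[str, ...]
    means: tuple[float, ...]
    sems: tuple[float, ...]
    n_animals: int | tuple[int, ...] = 3
    sites_per_animal: int = 16
    between_sd: tuple[float, ...] | None = None
    within_sd: float | tuple[float, ...] | None = None
    units: str = "um"

    def validate(self) -> None:
        k = len(self.labels)
        if len(self.means) != k or len(self.sems) != k:
            raise ValueError("labels, means, sems must have equal length")
        if any(s <= 0 for s in self.sems):
            raise ValueError("S.E.M values must be positive")
        if self.sites_per_animal < 1:
            raise ValueError("sites_per_animal must be >= 1")
        for arr in (self.between_sd, self._within_tuple()):
            if arr is not None and any(s < 0 for s in arr):
                raise ValueError("SDs must be non-negative")

    def _n_animals_tuple(self) -> tuple[int, ...]:
        if isinstance(self.n_animals, int):
            return (self.n_animals,) * len(self.labels)
        return tuple(self.n_animals)

    def _between_tuple(self) -> tuple[float, ...]:
        if self.between_sd is not None:
            return tuple(self.between_sd)
        return tuple(
            sem * np.sqrt(n) for sem, n in zip(self.sems, self._n_animals_tuple())
        )

    def _within_tuple(self) -> tuple[float, ...] | None:
        if self.within_sd is None:
            return None
        if isinstance(self.within_sd, (int, float)):
            return (float(self.within_sd),) * len(self.labels)
        return tuple(self.within_sd)


def generate_cohort(preset: CohortPreset, seed: int) -> pd.DataFrame:
    """Draw a tidy per-site cohort table with animal / site hierarchy.

    Columns: group, animal_id, site_id, value, units.  Animal means are
    normal around the group mean (between-animal SD); site values are normal
    around the animal mean (within-animal SD).
    """
    preset.validate()
    rng = np.random.default_rng(seed)
    between = preset._between_tuple()
    within = preset._within_tuple()
    if within is None:
        within = tuple(2.0 * b for b in between)
    rows = []
    for g, (label, mean) in enumerate(zip(preset.labels, preset.means)):
        n_anim = preset._n_animals_tuple()[g]
        for a in range(n_anim):
            animal_mean = rng.normal(mean, between[g])
            vals = rng.normal(animal_mean, within[g], size=preset.sites_per_animal)
            if preset.units == "percent":
                vals = np.clip(vals, 0.0, 100.0)
            for sidx, v in enumerate(vals):
                rows.append(
                    {
                        "group": label,
                        "animal_id": f"{label}_a{a}",
                        "site_id": sidx,
                        "value": float(v),
                        "units": preset.units,
                    }
                )
    return pd.DataFrame(rows)


# Cohort presets taken from the reported group summaries (mean ± S.E.M):
# glycocalyx thickness (µm) in young vs aged mice for three lectins, surface
# coverage (%) young vs aged, the post-hemorrhage coverage time course, and
# the cytoplasmic PNA positivity rate.
AGING_THICKNESS_LEL = CohortPreset(
    labels=("young", "aged"), means=(0.821, 0.512), sems=(0.025, 0.034),
    n_animals=3, sites_per_animal=16, units="um",
)
AGING_THICKNESS_PNA = CohortPreset(
    labels=("young", "aged"), means=(0.746, 0.373), sems=(0.031, 0.025),
    n_animals=3, sites_per_animal=16, units="um",
)
AGING_THICKNESS_RCA1 = CohortPreset(
    labels=("young", "aged"), means=(0.796, 0.445), sems=(0.020, 0.028),
    n_animals=3, sites_per_animal=16, units="um",
)
AGING_COVERAGE = CohortPreset(
    labels=("young", "aged"), means=(77.25, 33.06), sems=(1.31, 5.05),
    n_animals=3, sites_per_animal=1, units="percent",
)
IVH_COVERAGE_PNA = CohortPreset(
    labels=("sham", "day3", "day7"), means=(77.3, 24.3, 46.3), sems=(1.3, 3.2, 3.7),
    n_animals=(3, 5, 5), sites_per_animal=1, units="percent",
)
CYTOPLASMIC_PNA_RATE = CohortPreset(
    labels=("young", "aged"), means=(2.97, 20.30), sems=(0.57, 2.78),
    n_animals=3, sites_per_animal=1, units="percent",
)
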