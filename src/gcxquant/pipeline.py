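"""End-to-end orchestration: simulate → measure → summarize → report.

A :class:`RunConfig` (usually loaded from YAML) describes the input source —
synthetic profile ensembles, a synthetic or on-disk surface image, a cohort
preset, or profile CSVs — and :func:`run_pipeline` produces a
:class:`RunReport` with the per-site measurement table, group summaries, test
results, a QC table, and the reproducibility metadata (config echo, seeds,
version).  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .io import measurements_to_frame, read_polyline_csv, read_two_channel_tiff, write_json
from .morphometry import coverage as coverage_op
from .morphometry import thickness_at_site, thickness_survey
from .stats import (
    AgreementResult,
    anova_dunnett,
    bland_altman,
    group_summary,
    paired_t_ci,
    unpaired_t_test,
)
from .synthetic import CohortPreset, ProfileSpec, SurfaceImageSpec, generate_profile_pair

__version__ = "0.1.0"

__all__ = ["RunConfig", "RunReport", "run_pipeline", "validate_method_agreement"]

_PRESETS = {
    name: getattr(synthetic, name)
    for name in dir(synthetic)
    if isinstance(getattr(synthetic, name), CohortPreset)
}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run.

    ``kind`` selects the input source: ``"profiles"`` (synthetic line-profile
    ensembles, optionally grouped), ``"image"`` (synthetic surface scene or a
    TIFF + ROI pair), ``"cohort"`` (value-level hierarchical cohort from a
    preset or inline definition), or ``"profile_csvs"`` (measured profiles on
    disk).  A seed is mandatory; ``method`` may be ``polynomial8``,
    ``logistic4`` or ``both`` (the latter adds a method-agreement section).
    """

    kind: str
    seed: int
    method: str = "polynomial8"
    out_dir: str | None = None
    channels: dict = field(default_factory=lambda: {"lectin": 0, "marker": 1})
    # profiles
    groups: dict[str, dict] | None = None
    n_sites: int = 16
    profile_spec: dict = field(default_factory=dict)
    # cohort
    preset: str | None = None
    cohort: dict | None = None
    control: str | None = None
    # image
    image_spec: dict = field(default_factory=dict)
    image_path: str | None = None
    roi_path: str | None = None
    pixel_size: float | None = None
    coverage_opts: dict = field(default_factory=dict)
    # profile_csvs: list of {lectin: path, marker: path, site_id, animal_id}
    profile_files: list | None = None
    qc_fail_tolerance: float = 0.2

    def validate(self) -> None:
        if self.kind not in {"profiles", "image", "cohort", "profile_csvs"}:
            raise ValueError(f"unknown run kind {self.kind!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.method not in {"polynomial8", "logistic4", "both"}:
            raise ValueError(f"unknown method {self.method!r}")
        names = list(self.channels)
        if len(names) != 2 or len(set(names)) != 2:
            raise ValueError("channel mapping must name two distinct channels")
        if self.kind == "cohort" and not (self.preset or self.cohort):
            raise ValueError("cohort runs need a preset name or inline cohort definition")
        if self.preset is not None and self.preset not in _PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; available: {sorted(_PRESETS)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class RunReport:
    """Everything a run produced, plus what is needed to reproduce it."""

    measurements: pd.DataFrame
    summaries: dict
    tests: dict
    qc: dict
    agreement: dict | None
    coverage: dict | None
    config: dict
    version: str = __version__

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        if len(self.measurements):
            self.measurements.to_csv(os.path.join(out_dir, "measurements.csv"), index=False)
        write_json(
            os.path.join(out_dir, "report.json"),
            {
                "version": self.version,
                "summaries": self.summaries,
                "tests": self.tests,
                "qc": self.qc,
                "agreement": self.agreement,
                "coverage": self.coverage,
            },
        )
        with open(os.path.join(out_dir, "config_echo.yaml"), "w") as fh:
            yaml.safe_dump(self.config, fh, sort_keys=False)

    @property
    def qc_failed_fraction(self) -> float:
        n = self.qc.get("requested", 0)
        return self.qc.get("failed", 0) / n if n else 0.0


def validate_method_agreement(
    positions_poly, positions_sigmoid, equivalence_margin_um: float = 0.1
) -> tuple[AgreementResult, str]:
    """Paired t + Bland–Altman between the two inflection methods.

    The verdict is ``"equivalent"`` iff the 95% confidence interval of the
    bias lies entirely within the declared equivalence margin (default
    0.1 µm, one default pixel).  This is a genuine equivalence criterion: a
    tiny but statistically significant bias still counts as equivalent when
    it is bounded well inside the margin, while a non-significant result
    with a wide interval does not.
    """
    a = np.asarray(positions_poly, dtype=float)
    b = np.asarray(positions_sigmoid, dtype=float)
    if a.size < 2 or a.size != b.size:
        raise ValueError("need at least 2 paired sites measured by both methods")
    res = bland_altman(a, b)
    lo, hi = res.ci95
    verdict = (
        "equivalent"
        if -equivalence_margin_um < lo and hi < equivalence_margin_um
        else "not equivalent"
    )
    return res, verdict


def _summary_dict(values) -> dict:
    s = group_summary(values)
    return {"n": s.n, "mean": s.mean, "sem": s.sem}


def _group_tests(by_group: dict[str, np.ndarray], control: str | None, seed: int) -> dict:
    labels = list(by_group)
    tests: dict[str, Any] = {}
    if len(labels) == 2:
        try:
            t, df, p = unpaired_t_test(by_group[labels[0]], by_group[labels[1]])
            tests["unpaired_t"] = {"groups": labels, "t": t, "df": df, "p": p}
        except ValueError as err:  # degenerate (e.g. zero-variance) designs
            tests["unpaired_t"] = {"groups": labels, "error": str(err)}
    elif len(labels) > 2:
        ctrl = control if control in labels else labels[0]
        res = anova_dunnett(
            [by_group[l] for l in labels],
            labels=labels,
            control_index=labels.index(ctrl),
            seed=seed,
        )
        tests["anova_dunnett"] = {
            "F": res.f_statistic,
            "p_anova": res.p_anova,
            "control": res.control,
            "adjusted_p": res.adjusted_p,
            "seed": res.seed,
        }
    return tests


def _measure_profile_groups(config: RunConfig):
    groups = config.groups or {"all": {}}
    methods = (
        ["polynomial8", "logistic4"] if config.method == "both" else [config.method]
    )
    rng = np.random.default_rng(config.seed)
    records = []
    poly_pos, sig_pos = [], []
    requested = 0
    for label, overrides in groups.items():
        spec = ProfileSpec(**{**config.profile_spec, **overrides})
        for site in range(config.n_sites):
            requested += 1
            site_seed = int(rng.integers(2**31))
            lec, mar, truth = generate_profile_pair(spec, site_seed)
            per_method = {}
            for m in methods:
                meas = thickness_at_site(lec, mar, method=m, site_id=site)
                per_method[m] = meas
                records.append(
                    {
                        "group": label,
                        "site_id": site,
                        "seed": site_seed,
                        "T_true_um": truth.thickness_true,
                        "T_um": meas.thickness,
                        "x_lectin_um": meas.x_inflection_lectin,
                        "x_marker_um": meas.x_inflection_marker,
                        "method": m,
                        "qc_flags": ";".join(meas.qc_flags),
                        "ok": meas.ok,
                    }
                )
            if config.method == "both":
                a, b = per_method["polynomial8"], per_method["logistic4"]
                if a.ok and b.ok:
                    poly_pos += [a.x_inflection_lectin, a.x_inflection_marker]
                    sig_pos += [b.x_inflection_lectin, b.x_inflection_marker]
    df = pd.DataFrame(records)
    return df, requested, (np.array(poly_pos), np.array(sig_pos))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one run; deterministic given the config (which embeds seeds)."""
    config.validate()
    agreement = None
    coverage_out = None
    tests: dict = {}
    summaries: dict = {}

    if config.kind in ("profiles",):
        df, requested, (pp, sp) = _measure_profile_groups(config)
        primary = "polynomial8" if config.method in ("polynomial8", "both") else "logistic4"
        ok = df[(df["method"] == primary) & df["ok"]]
        by_group = {g: sub["T_um"].to_numpy() for g, sub in ok.groupby("group")}
        summaries = {g: _summary_dict(v) for g, v in by_group.items() if len(v) >= 2}
        if len(by_group) >= 2:
            tests = _group_tests(by_group, config.control, config.seed)
        if config.method == "both" and len(pp) >= 2:
            res, verdict = validate_method_agreement(pp, sp)
            agreement = {
                "n_pairs": res.n, "bias_um": res.bias, "sd_um": res.sd,
                "t": res.t, "df": res.df, "p": res.p,
                "ci95_um": list(res.ci95), "loa_um": list(res.loa),
                "verdict": verdict,
            }
        n_method_rows = len(df[df["method"] == primary])
        qc = {
            "requested": requested,
            "measured": int(ok.shape[0]),
            "failed": int(n_method_rows - ok.shape[0]),
            "negative_T": int((ok["T_um"] < 0).sum()),
        }

    elif config.kind == "cohort":
        preset = (
            _PRESETS[config.preset] if config.preset else CohortPreset(**config.cohort)
        )
        df = synthetic.generate_cohort(preset, config.seed)
        by_group = {g: sub["value"].to_numpy() for g, sub in df.groupby("group", sort=False)}
        summaries = {g: _summary_dict(v) for g, v in by_group.items()}
        tests = _group_tests(by_group, config.control or preset.labels[0], config.seed)
        qc = {"requested": len(df), "measured": len(df), "failed": 0}

    elif config.kind == "image":
        if config.image_path:
            img, px = read_two_channel_tiff(config.image_path, config.pixel_size)
            poly = read_polyline_csv(config.roi_path)
        else:
            spec = SurfaceImageSpec(**config.image_spec)
            img, truth = synthetic.generate_surface_image(spec, config.seed)
            px = spec.pixel_size
            poly = spec.build_polyline()
        cov = coverage_op(img, px, poly, **config.coverage_opts)
        coverage_out = {
            "total_um": cov.total_surface_length,
            "denuded_excluded_um": cov.denuded_length_excluded,
            "analyzable_um": cov.analyzable_length,
            "positive_um": cov.positive_length,
            "coverage_percent": cov.coverage_percent,
        }
        method = "polynomial8" if config.method == "both" else config.method
        meas = thickness_survey(
            img, px, poly, n_sites=config.n_sites, seed=config.seed, method=method
        )
        df = measurements_to_frame(meas)
        ok = df[df["ok"]]
        if len(ok) >= 2:
            summaries = {"thickness": _summary_dict(ok["T_um"].to_numpy())}
        qc = {
            "requested": config.n_sites,
            "measured": int(ok.shape[0]),
            "failed": int(df.shape[0] - ok.shape[0]),
            "negative_T": int((ok["T_um"] < 0).sum()),
        }

    elif config.kind == "profile_csvs":
        from .profiles import IntensityProfile

        records = []
        requested = 0
        for entry in config.profile_files or []:
            requested += 1
            lec = IntensityProfile.from_csv(entry["lectin"])
            mar = IntensityProfile.from_csv(entry["marker"])
            meas = thickness_at_site(
                lec, mar,
                method="polynomial8" if config.method == "both" else config.method,
                site_id=entry.get("site_id", requested - 1),
                animal_id=entry.get("animal_id", ""),
            )
            records.append(meas)
        df = measurements_to_frame(records)
        ok = df[df["ok"]]
        if len(ok) >= 2:
            summaries = {"thickness": _summary_dict(ok["T_um"].to_numpy())}
        qc = {
            "requested": requested,
            "measured": int(ok.shape[0]),
            "failed": int(df.shape[0] - ok.shape[0]),
        }

    report = RunReport(
        measurements=df,
        summaries=summaries,
        tests=tests,
        qc=qc,
        agreement=agreement,
        coverage=coverage_out,
        config=asdict(config),
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
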