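"""The statistical battery: summaries, t procedures, ANOVA + Dunnett,
Pearson correlation, and Bland–Altman agreement.

Conventions follow common practice in this literature: dispersion is reported
as mean ± S.E.M (SD/√n), two-group comparisons use the pooled-variance
Student t (Welch optional), multi-group time courses use one-way ANOVA with
Dunnett's many-to-one comparisons against a control, and method agreement is
summarized by the paired t plus Bland–Altman bias and 1.96·SD limits of
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AgreementResult",
    "DunnettResult",
    "group_summary",
    "unpaired_t_test",
    "paired_t_ci",
    "bland_altman",
    "anova_dunnett",
    "pearson_correlation",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float

    def __str__(self):
        return f"{self.mean:.3g} ± {self.sem:.3g} (n={self.n})"


@dataclass(frozen=True)
class AgreementResult:
    """Paired-difference agreement between two measurement methods.

    ``bias`` is the mean difference a−b, ``loa`` the 95% limits of agreement
    bias ± 1.96·SD (the conventional fixed multiplier, matching published
    limits), ``ci95`` the t-based confidence interval for the bias.
    """

    n: int
    bias: float
    sd: float
    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    loa: tuple[float, float]
    means: np.ndarray | None = None
    diffs: np.ndarray | None = None


@dataclass(frozen=True)
class DunnettResult:
    f_statistic: float
    p_anova: float
    control: str
    comparisons: tuple[tuple[str, float, float], ...]  # (label, statistic, p_adj)
    seed: int | None = None

    @property
    def adjusted_p(self) -> dict[str, float]:
        return {lab: p for lab, _, p in self.comparisons}


def _asarray(v, name="values"):
    a = np.asarray(v, dtype=float).ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contain non-finite entries")
    return a


def group_summary(values) -> GroupSummary:
    """Sample mean and S.E.M (SD with n−1 denominator, over √n)."""
    a = _asarray(values)
    if a.size < 2:
        raise ValueError("S.E.M needs n >= 2")
    return GroupSummary(n=int(a.size), mean=float(a.mean()),
                        sem=float(a.std(ddof=1) / np.sqrt(a.size)))


def unpaired_t_test(a, b, equal_var: bool = True) -> tuple[float, float, float]:
    """Two-sided unpaired t test; returns (t, df, p).

    Pooled-variance Student t by default; Welch with ``equal_var=False``.
    Degenerate case: both groups constant with equal means gives (0, df, 1);
    constant groups with unequal means are rejected.
    """
    a, b = _asarray(a, "a"), _asarray(b, "b")
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2 if equal_var else float("nan")
            return 0.0, float(df), 1.0
        raise ValueError("zero variance with unequal means: t undefined")
    if equal_var:
        n1, n2 = a.size, b.size
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2.0 * sps.t.sf(abs(t), df)
        return float(t), float(df), float(p)
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def paired_t_ci(differences, conf: float = 0.95):
    """Paired t on a vector of differences; returns (mean, ci, t, df, p).

    t = d̄/(SD_d/√n), df = n−1, two-sided p, CI from the t quantile.  A
    zero-SD, zero-mean vector gives t = 0, p = 1 and a degenerate CI.
    """
    d = _asarray(differences, "differences")
    n = d.size
    if n < 2:
        raise ValueError("paired t needs n >= 2 differences")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
        p = 1.0 if mean == 0.0 else 0.0
        return mean, (mean, mean), t, df, p
    sem = sd / np.sqrt(n)
    t = mean / sem
    p = 2.0 * sps.t.sf(abs(t), df)
    q = sps.t.ppf(0.5 + conf / 2.0, df)
    ci = (mean - q * sem, mean + q * sem)
    return mean, (float(ci[0]), float(ci[1])), float(t), df, float(p)


def bland_altman(method_a, method_b) -> AgreementResult:
    """Bland–Altman agreement between two paired measurement vectors.

    Differences are a−b.  Limits of agreement use the fixed 1.96 multiplier;
    bias and SD agree with :func:`paired_t_ci` on the same differences.
    """
    a, b = _asarray(method_a, "a"), _asarray(method_b, "b")
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    if a.size < 2:
        raise ValueError("Bland–Altman needs n >= 2 pairs")
    d = a - b
    bias, ci, t, df, p = paired_t_ci(d)
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)
    return AgreementResult(
        n=int(a.size), bias=bias, sd=sd, t=t, df=df, p=p,
        ci95=ci, loa=(float(loa[0]), float(loa[1])),
        means=(a + b) / 2.0, diffs=d,
    )


def anova_dunnett(
    groups, labels=None, control_index: int = 0, seed: int | None = None
) -> DunnettResult:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons.

    Each non-control group is compared two-sidedly against the control with
    familywise error control via the multivariate t distribution (general
    group sizes handled through its correlation structure); the integration
    is seeded and the seed recorded.  Adjusted p values are clipped to be at
    least the unadjusted pooled-t p (a numerical guard: the inequality holds
    exactly, Monte-Carlo integration error must not violate it).
    """
    samples = [_asarray(g, f"group {i}") for i, g in enumerate(groups)]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("each group needs n >= 2")
    if not 0 <= control_index < k:
        raise ValueError(f"control_index {control_index} out of range for {k} groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]

    f_stat, p_anova = sps.f_oneway(*samples)
    control = samples[control_index]
    treats = [s for i, s in enumerate(samples) if i != control_index]
    treat_labels = [l for i, l in enumerate(labels) if i != control_index]

    rng = np.random.default_rng(seed)
    res = sps.dunnett(*treats, control=control, alternative="two-sided", random_state=rng)
    nu = sum(s.size for s in samples) - k  # error df of the pooled design
    comparisons = []
    for lab, stat, p_adj in zip(
        treat_labels, np.atleast_1d(res.statistic), np.atleast_1d(res.pvalue)
    ):
        p_raw = 2.0 * sps.t.sf(abs(stat), nu)
        comparisons.append((lab, float(stat), float(min(1.0, max(p_adj, p_raw)))))
    return DunnettResult(
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
        control=labels[control_index],
        comparisons=tuple(comparisons),
        seed=seed,
    )


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from t = r·√((n−2)/(1−r²))."""
    x, y = _asarray(x, "x"), _asarray(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
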