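"""Diagnostic plots: profile + fitted curve + inflection markers,
Bland–Altman agreement, and estimated-vs-true correlation."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["plot_profile_fit", "plot_bland_altman", "plot_correlation"]


def plot_profile_fit(profile, fit=None, inflection=None, ax=None, color="C3"):
    """One channel's profile with its fitted curve and inflection marker."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.positions, profile.intensities, ".", ms=3, color=color, alpha=0.5,
            label=profile.channel_label or "profile")
    if fit is not None:
        lo, hi = fit.domain
        xs = np.linspace(lo, hi, 400)
        ax.plot(xs, fit(xs), "-", color=color, lw=1.5)
    if inflection is not None:
        ax.axvline(inflection.position, color=color, ls="--", lw=1)
        ax.plot([inflection.position], [fit(inflection.position) if fit else 0], "o",
                color="k", ms=5)
    ax.set_xlabel("position along line (µm, lumen → parenchyma)")
    ax.set_ylabel("intensity (a.u.)")
    if profile.channel_label:
        ax.legend(frameon=False)
    return ax


def plot_bland_altman(result, ax=None):
    """Per-pair mean vs difference with bias and limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    if result.means is not None:
        ax.plot(result.means, result.diffs, "o", ms=4, alpha=0.7)
    for y, style in ((result.bias, "-"), (result.loa[0], "--"), (result.loa[1], "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of methods (µm)")
    ax.set_ylabel("difference (µm)")
    ax.set_title(f"bias {result.bias:.3f} µm, LoA [{result.loa[0]:.3f}, {result.loa[1]:.3f}]")
    return ax


def plot_correlation(x, y, r=None, ax=None, xlabel="true T (µm)", ylabel="estimated T (µm)"):
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(x, y, "o", ms=4, alpha=0.7)
    lims = [min(np.min(x), np.min(y)), max(np.max(x), np.max(y))]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if r is not None:
        ax.set_title(f"r = {r:.3f}")
    return ax
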