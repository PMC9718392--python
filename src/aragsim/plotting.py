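"""Matplotlib helpers for dosing profiles, fits and spectra."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt


def plot_profiles(profiles, labels=None, ax=None):
    """Cumulative titrant volume vs time for one or more profiles."""
    if ax is None:
        _, ax = plt.subplots()
    for i, prof in enumerate(profiles):
        label = labels[i] if labels else prof.metadata.get("water", f"run {i}")
        ax.plot(prof.times / 3600.0, prof.cumulative_volume, label=str(label))
    ax.set_xlabel("time (h)")
    ax.set_ylabel("titrant dosed (mL per titrant)")
    ax.legend(fontsize=8)
    return ax


def plot_fit(estimate, observed=None, ax=None):
    """Observed profile (points) with the lag-shifted best-fit prediction."""
    if ax is None:
        _, ax = plt.subplots()
    if observed is not None:
        ax.plot(observed.times / 3600.0, observed.cumulative_volume,
                "k.", ms=2, label="observed")
    if estimate.predicted is not None:
        ax.plot(estimate.predicted.times / 3600.0,
                estimate.predicted.cumulative_volume,
                "r--", label=f"predicted (R={estimate.rate:.0f}, "
                             f"lag={estimate.lag:.0f} s)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("titrant dosed (mL per titrant)")
    ax.legend(fontsize=8)
    return ax


def plot_spectrum(spec, fit=None, ax=None):
    """Raman spectrum with the fitted ν₁ centre marked."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(spec.wavenumbers, spec.intensities, lw=0.8)
    if fit is not None:
        ax.axvline(fit.center, color="r", ls=":",
                   label=f"nu1 {fit.center:.1f} cm-1, FWHM {fit.fwhm:.2f}")
        ax.legend(fontsize=8)
    ax.set_xlabel("Raman shift (cm$^{-1}$)")
    ax.set_ylabel("intensity (counts)")
    return ax
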