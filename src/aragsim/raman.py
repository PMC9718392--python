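"""Raman spectrum handling for CaCO3 polymorph work.

Covers the three analysis steps applied to the precipitates:

* polymorph identification — aragonite shows the strong ν₁ symmetric
  C–O stretch near 1084 cm⁻¹ together with the ν₄ in-plane bend split
  into a 700–710 cm⁻¹ doublet (orthorhombic); calcite shows a single ν₄
  peak (~711 cm⁻¹);
* ν₁ peak fitting — linear baseline + Voigt profile least squares
  (lmfit); the FWHM, an index of rotational disorder in the lattice,
  is read off the fitted profile numerically by bisection at half
  maximum rather than from an approximation formula;
* grouped comparison — one-way ANOVA on the per-spectrum centre or FWHM
  followed by Tukey's HSD pairwise comparison at α = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Literal

import numpy as np
from lmfit.models import LinearModel, VoigtModel
from scipy.optimize import brentq
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import f_oneway

__all__ = [
    "Spectrum",
    "PeakFit",
    "GroupComparison",
    "CoverageError",
    "PeakFitError",
    "identify_polymorph",
    "fit_v1_peak",
    "compare_groups",
    "in_vitro_fraction",
    "InVitroFraction",
]


class CoverageError(ValueError):
    """Spectrum does not cover the wavenumber range an analysis needs."""


class PeakFitError(RuntimeError):
    """Voigt fit failed to converge."""


@dataclass
class Spectrum:
    """A Raman spectrum: strictly increasing wavenumber grid + intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must have equal length")
        if np.any(np.diff(self.wavenumbers) <= 0.0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def crop(self, lo: float, hi: float) -> "Spectrum":
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        return Spectrum(self.wavenumbers[mask], self.intensities[mask], self.label)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavenumbers[0] <= lo and self.wavenumbers[-1] >= hi

    def to_txt(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavenumbers, self.intensities]),
                   fmt="%.4f", header="wavenumber_cm-1 intensity", comments="# ")

    @classmethod
    def from_txt(cls, path, label: str = "") -> "Spectrum":
        arr = np.loadtxt(path, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], label=label)


@dataclass(frozen=True)
class PeakFit:
    """Voigt fit of a single band over a linear baseline.

    ``fwhm`` is measured numerically on the fitted Voigt component;
    ``gaussian_width`` is the Gaussian σ and ``lorentzian_width`` the
    Lorentzian γ (HWHM) of the Voigt parameterisation.
    """

    center: float
    fwhm: float
    amplitude: float
    gaussian_width: float
    lorentzian_width: float
    baseline_params: tuple[float, float]  # (slope, intercept)
    r2_fit: float
    window: tuple[float, float]
    at_window_edge: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0.0:
            raise ValueError("fwhm must be positive")
        if not self.window[0] <= self.center <= self.window[1]:
            raise ValueError("fitted centre lies outside the fit window")
        if not 0.0 <= self.r2_fit <= 1.0:
            raise ValueError("r2_fit must lie in [0, 1]")


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA + Tukey HSD across groups of peak statistics."""

    groups: tuple[str, ...]
    n_per_group: tuple[int, ...]
    anova_F: float
    anova_p: float
    tukey_pairs: tuple[tuple[tuple[str, str], float, float, bool], ...]
    response: str = "fwhm"

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, _, _, sig in self.tukey_pairs if sig]

    def summary(self) -> str:
        lines = [
            f"One-way ANOVA on {self.response}",
            f"  groups: {', '.join(self.groups)} (n = {list(self.n_per_group)})",
            f"  F = {self.anova_F:.3f}, p = {self.anova_p:.3g}",
            "Tukey HSD (alpha = 0.05):",
        ]
        for (a, b), diff, p, sig in self.tukey_pairs:
            mark = "*" if sig else " "
            lines.append(f"  {a} vs {b}: diff = {diff:+.3f}, p = {p:.3g} {mark}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# polymorph identification

_V1_WINDOW = (1070.0, 1100.0)
_V4_WINDOW = (695.0, 715.0)


def _noise_sd(intensities: np.ndarray, smooth: np.ndarray) -> float:
    """Robust noise estimate from the smoothing residual (MAD-scaled)."""
    resid = intensities - smooth
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(max(1.4826 * mad, 1e-12))


def _quiet_noise_sd(spec: Spectrum) -> float:
    """Noise sd from the band-free 800–1000 cm⁻¹ region (detrended, robust)."""
    region = spec.crop(800.0, 1000.0)
    x, y = region.wavenumbers, region.intensities
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(max(1.4826 * mad, 1e-12))


def identify_polymorph(spec: Spectrum) -> Literal["aragonite", "calcite", "unknown"]:
    """Classify a carbonate spectrum from its ν₁ and ν₄ bands.

    aragonite: strong peak near 1084 cm⁻¹ AND two resolvable maxima in
    695–715 cm⁻¹; calcite: ν₁ present with a single ν₄ maximum;
    otherwise unknown.  The noise floor is estimated from the band-free
    800–1000 cm⁻¹ region; ν₄ components must rise ≥ 3× that sd above
    their surroundings, with a relative floor (20% of the strongest ν₄
    prominence) so noise wiggles beside a real band do not mimic a
    doublet.
    """
    if not spec.covers(650.0, 1150.0):
        raise CoverageError(
            f"spectrum covers {spec.wavenumbers[0]:.0f}-"
            f"{spec.wavenumbers[-1]:.0f} cm-1; need 650-1150"
        )
    sd = _quiet_noise_sd(spec)

    def _peaks_in(lo: float, hi: float, strong: float) -> int:
        region = spec.crop(lo - 15.0, hi + 15.0)
        n = region.intensities.size
        # light smoothing only: a wide window would merge the ~4 cm-1
        # separated doublet components
        wl = min(5, n - (1 - n % 2))
        smooth = savgol_filter(region.intensities, wl, 2) if n >= 7 else region.intensities
        idx, props = find_peaks(smooth, prominence=3.0 * sd)
        in_window = (region.wavenumbers[idx] >= lo) & (region.wavenumbers[idx] <= hi)
        proms = props["prominences"][in_window]
        if proms.size == 0 or proms.max() < strong * sd:
            return 0
        return int(np.sum(proms >= 0.2 * proms.max()))

    has_v1 = _peaks_in(*_V1_WINDOW, strong=10.0) >= 1
    n_v4 = _peaks_in(*_V4_WINDOW, strong=5.0)
    if has_v1 and n_v4 >= 2:
        return "aragonite"
    if has_v1 and n_v4 == 1:
        return "calcite"
    return "unknown"


# ---------------------------------------------------------------------------
# nu1 Voigt fit

def _voigt_fwhm_numeric(voigt_eval, center: float, half_max: float,
                        span: float) -> float:
    """FWHM by bisection at half maximum on each side of the centre."""
    def g(x: float) -> float:
        return voigt_eval(x) - half_max

    lo = brentq(g, center - span, center, xtol=1e-8)
    hi = brentq(g, center, center + span, xtol=1e-8)
    return hi - lo


def fit_v1_peak(
    spec: Spectrum, window: tuple[float, float] = (1060.0, 1110.0)
) -> PeakFit:
    """Fit linear baseline + Voigt to the ν₁ band inside ``window``.

    Initial guesses come from the window maximum and a moment-based
    width; the Lorentzian γ is a free parameter (not tied to σ).  The
    FWHM is computed numerically from the fitted Voigt component by
    bisection at half maximum.  A centre within 2 grid steps of the
    window edge sets ``at_window_edge``.
    """
    region = spec.crop(*window)
    if region.wavenumbers.size < 12:
        raise CoverageError("fewer than 12 points inside the fit window")
    x, y = region.wavenumbers, region.intensities

    base = (y[0] + y[-1]) / 2.0
    slope0 = (y[-1] - y[0]) / (x[-1] - x[0])
    y_net = np.clip(y - (y[0] + slope0 * (x - x[0])), 0.0, None)
    total = y_net.sum()
    if total <= 0.0:
        raise PeakFitError("no positive signal above the baseline in the window")
    c0 = float((x * y_net).sum() / total)
    width0 = float(np.sqrt(np.clip(((x - c0) ** 2 * y_net).sum() / total, 0.04, None)))

    voigt = VoigtModel(prefix="v_")
    baseline = LinearModel(prefix="b_")
    model = voigt + baseline
    params = model.make_params()
    params["v_center"].set(value=c0, min=window[0], max=window[1])
    params["v_sigma"].set(value=max(width0 / 2.0, 0.2), min=1e-3)
    # free the Lorentzian gamma (lmfit ties it to sigma by default)
    params["v_gamma"].set(value=max(width0 / 4.0, 0.05), min=0.0, vary=True, expr="")
    step = float(np.median(np.diff(x)))
    amp0 = float(y_net.max()) * max(width0, step) * math.sqrt(2.0 * math.pi)
    params["v_amplitude"].set(value=amp0, min=0.0)
    params["b_slope"].set(value=slope0)
    params["b_intercept"].set(value=base - slope0 * (x[0] + x[-1]) / 2.0)

    result = model.fit(y, params, x=x)
    if not result.success:
        raise PeakFitError(f"Voigt fit did not converge: {result.message}")

    center = float(result.params["v_center"].value)
    sigma = float(result.params["v_sigma"].value)
    gamma = float(result.params["v_gamma"].value)

    def voigt_at(xq: float) -> float:
        return float(result.eval_components(x=np.array([xq]))["v_"][0])

    peak_height = voigt_at(center)
    span = 10.0 * (sigma + gamma) + 5.0 * step
    fwhm = _voigt_fwhm_numeric(voigt_at, center, peak_height / 2.0, span)

    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(result.residual ** 2)) / ss_tot if ss_tot > 0 else 0.0
    at_edge = center - window[0] < 2.0 * step or window[1] - center < 2.0 * step
    return PeakFit(
        center=center,
        fwhm=fwhm,
        amplitude=float(result.params["v_amplitude"].value),
        gaussian_width=sigma,
        lorentzian_width=gamma,
        baseline_params=(
            float(result.params["b_slope"].value),
            float(result.params["b_intercept"].value),
        ),
        r2_fit=max(0.0, min(1.0, r2)),
        window=window,
        at_window_edge=at_edge,
        label=spec.label,
    )


# ---------------------------------------------------------------------------
# grouped statistics

def compare_groups(
    fits: dict[str, list[PeakFit]] | dict[str, list[float]],
    response: Literal["fwhm", "center"] = "fwhm",
    alpha: float = 0.05,
) -> GroupComparison:
    """One-way ANOVA + Tukey HSD on a peak statistic across groups.

    ``fits`` maps group label to a list of :class:`PeakFit` (or plain
    floats).  Every group needs n ≥ 2; unbalanced designs are allowed.
    Groups with zero total variance are handled: F is reported as NaN
    and no pair is significant.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 groups")
    labels = tuple(fits.keys())
    values: list[np.ndarray] = []
    for lab in labels:
        vals = [
            getattr(f, response) if isinstance(f, PeakFit) else float(f)
            for f in fits[lab]
        ]
        if len(vals) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")
        values.append(np.asarray(vals, dtype=float))
    n_per_group = tuple(len(v) for v in values)

    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0.0:
        pairs = tuple(
            (((labels[i], labels[j]), 0.0, 1.0, False))
            for i in range(len(labels)) for j in range(i + 1, len(labels))
        )
        return GroupComparison(labels, n_per_group, float("nan"), 1.0, pairs, response)

    F, p = f_oneway(*values)

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    endog = pooled
    group_codes = np.concatenate(
        [np.full(len(v), lab, dtype=object) for v, lab in zip(values, labels)]
    )
    tukey = pairwise_tukeyhsd(endog, group_codes, alpha=alpha)
    pairs = []
    for row in tukey.summary().data[1:]:
        a, b, diff, p_adj, _, _, reject = row
        pairs.append(((str(a), str(b)), float(diff), float(p_adj), bool(reject)))
    return GroupComparison(
        labels, n_per_group, float(F), float(p), tuple(pairs), response
    )


# ---------------------------------------------------------------------------
# seed-dilution arithmetic

#: Minimum in-vitro mass fraction (%) at which the precipitate signature
#: separates from the seed's.
RESOLVABILITY_THRESHOLD = 60.0


@dataclass(frozen=True)
class InVitroFraction:
    """Mass fraction of the analysed solid precipitated in vitro."""

    percent: float
    resolvable: bool

    def __float__(self) -> float:
        return self.percent


def in_vitro_fraction(seed_mass: float, precipitated_mass: float) -> InVitroFraction:
    """In-vitro mass fraction (%) of a seed + precipitate mixture.

    fraction = 100·precipitated/(seed + precipitated).  The Raman
    signature of the in-vitro deposit is resolvable from the seed's when
    the fraction reaches 60% (seed ≤ 40% by mass).
    """
    if seed_mass < 0.0 or precipitated_mass < 0.0:
        raise ValueError("masses must be non-negative")
    total = seed_mass + precipitated_mass
    if total == 0.0:
        raise ValueError("seed and precipitated mass cannot both be zero")
    pct = 100.0 * precipitated_mass / total
    return InVitroFraction(pct, pct >= RESOLVABILITY_THRESHOLD)
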