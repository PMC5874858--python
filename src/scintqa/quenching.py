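"""Birks-law quenching: forward model, constant estimation, and correction.

Plastic scintillators under-respond where LET is high, so the Bragg peak of
a measured light profile is suppressed relative to dose. Birks law models
the light per unit path as

    dL/dx = L0 * (dE/dx) / (1 + kB * dE/dx)

with kB (mm/MeV) the Birks constant. Per depth bin this gives
light(z) = L0 * dose(z) / (1 + kB * LET(z)), an algebraically invertible
relation: the correction factor 1 + kB * LET(z) restores the dose shape.
kB itself is estimated by nonlinear least squares on measured light versus
simulated LET pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .profiles import DepthProfile, distal_crossing, register_profiles


@dataclass(frozen=True)
class QuenchModel:
    """Birks parameters: kB in mm/MeV, L0 a relative scintillation efficiency."""

    kB: float
    L0: float = 1.0

    def __post_init__(self):
        if self.kB < 0:
            raise ValueError("kB must be non-negative")
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")


@dataclass
class QuenchFit:
    """Result of a Birks-constant fit with a 95% asymptotic CI."""

    kB: float
    kB_ci_low: float
    kB_ci_high: float
    L0: float
    rss: float
    n_points: int

    def __post_init__(self):
        if not (self.kB_ci_low <= self.kB <= self.kB_ci_high):
            raise ValueError("CI must bracket the estimate")
        if self.n_points < 3:
            raise ValueError("fit needs at least 3 points")

    def as_dict(self) -> dict:
        return {
            "kB_mm_per_MeV": self.kB,
            "kB_ci95": [self.kB_ci_low, self.kB_ci_high],
            "L0": self.L0,
            "rss": self.rss,
            "n_points": self.n_points,
        }


@dataclass
class CorrectionCurve:
    """Per-bin ratio of ideal to quenched light, = 1 + kB * LET(z)."""

    depths: np.ndarray
    factor: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        self.factor = np.asarray(self.factor, dtype=float)
        if self.depths.shape != self.factor.shape:
            raise ValueError("depths and factor must have equal length")
        if np.any(self.factor < 1.0 - 1e-12):
            raise ValueError("correction factor must be >= 1")


@dataclass(frozen=True)
class RegistrationSpec:
    """How to register a measured profile before fitting or correcting.

    ``reference`` is the profile whose distal ``level`` crossing the
    measured profile is aligned to (typically the simulated quenched
    light); ``None`` means the profiles already share a depth frame.
    """

    reference: DepthProfile | None = None
    level: float = 0.5


def _check_common_grid(a: DepthProfile, b: DepthProfile) -> None:
    if a.depths.shape != b.depths.shape or not np.allclose(a.depths, b.depths):
        raise ValueError("profiles must share one depth grid")


def quench_light(dose: DepthProfile, let: DepthProfile,
                 model: QuenchModel) -> DepthProfile:
    """Quenched light profile: L0 * dose / (1 + kB * LET), kind='light'."""
    _check_common_grid(dose, let)
    vals = model.L0 * dose.values / (1.0 + model.kB * let.values)
    return DepthProfile(dose.depths, vals, "light", meta=dict(dose.meta))


def correction_curve(dose: DepthProfile, let: DepthProfile,
                     model: QuenchModel) -> CorrectionCurve:
    """Quenching correction factor ideal/quenched = 1 + kB * LET(z).

    ``dose`` fixes the grid the curve is defined on (and is what the ratio
    is taken of); the factor itself depends only on LET and kB.
    """
    _check_common_grid(dose, let)
    return CorrectionCurve(dose.depths.copy(), 1.0 + model.kB * let.values)


def correct_profile(measured: DepthProfile, curve: CorrectionCurve,
                    normalization: str = "plateau",
                    plateau_window: tuple = (2.0, 7.0)) -> DepthProfile:
    """Apply a quenching correction to a measured light profile.

    The measurement is interpolated onto the curve's grid, multiplied by
    the per-bin factor, and renormalized: ``plateau`` divides by the mean
    over ``plateau_window`` (mm), ``peak`` by the maximum, ``area`` by the
    depth integral.
    """
    if measured.depths[-1] < curve.depths[0] or measured.depths[0] > curve.depths[-1]:
        raise ValueError("measured profile and correction curve do not overlap in depth")
    m = measured.interp(curve.depths)
    vals = m * curve.factor
    if normalization == "peak":
        scale = vals.max()
    elif normalization == "area":
        scale = np.trapezoid(vals, curve.depths)
    elif normalization == "plateau":
        lo, hi = plateau_window
        sel = (curve.depths >= lo) & (curve.depths <= hi)
        if not sel.any():
            raise ValueError("plateau window outside the correction grid")
        scale = vals[sel].mean()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if scale <= 0:
        raise ValueError("corrected profile normalizes to zero")
    return DepthProfile(curve.depths, vals / scale, "corrected",
                        meta=dict(measured.meta))


def _fit_window(light: DepthProfile) -> np.ndarray:
    """Depth bins used in the Birks fit.

    Entrance up to the light maximum, plus the distal 80%→20% falloff
    window. Beyond 20% the track-averaged LET of the few surviving
    protons spikes while the light is essentially zero; those points carry
    no information about kB and are excluded.
    """
    v = light.values
    z = light.depths
    i_max = int(np.argmax(v))
    mask = np.zeros(len(v), dtype=bool)
    mask[: i_max + 1] = True
    try:
        z80 = distal_crossing(light, 0.8)
        z20 = distal_crossing(light, 0.2)
        mask |= (z >= z80) & (z <= z20)
    except ValueError:
        pass                               # truncated profile: pre-peak only
    return mask


def fit_birks(light: DepthProfile, let: DepthProfile,
              registration: RegistrationSpec | None = None,
              dose: DepthProfile | None = None,
              weights: np.ndarray | None = None,
              window: str = "standard") -> QuenchFit:
    """Estimate (L0, kB) by nonlinear least squares against simulated LET.

    Without ``dose`` this fits the classic light-versus-LET curve,
    light = L0 * LET / (1 + kB * LET), which implicitly assumes the dose
    is proportional to LET (constant primary fluence). With the simulated
    depth-dose supplied it fits the exact per-bin relation
    light = L0 * dose / (1 + kB * LET), which stays unbiased where the
    primary fluence declines (nuclear attenuation, straggling losses near
    the peak) and is the recommended form when a simulation provides both
    curves.

    The fit runs over the windowed depth bins (see :func:`_fit_window`;
    ``window="all"`` disables windowing, ``"prepeak"`` keeps only
    entrance-to-maximum — advisable for the LET-only model, whose
    assumption fails distal to the light maximum). The 95% CI comes from
    the asymptotic linearized covariance with a t quantile. A negative kB
    estimate is clipped to zero with a warning.
    """
    if registration is not None and registration.reference is not None:
        light = register_profiles(light, registration.reference,
                                  level=registration.level)
    if light.depths.shape != let.depths.shape or not np.allclose(
            light.depths, let.depths):
        light = light.resample(let.depths)
    if dose is not None:
        _check_common_grid(dose, let)

    if window == "standard":
        mask = _fit_window(light)
    elif window == "prepeak":
        mask = np.zeros(len(light.values), dtype=bool)
        mask[: int(np.argmax(light.values)) + 1] = True
    elif window == "all":
        mask = np.ones(len(light.values), dtype=bool)
    else:
        raise ValueError(f"unknown window {window!r}")
    mask &= (let.values > 0) & (light.values > 0)

    x = let.values[mask]
    y = light.values[mask]
    if len(x) < 3:
        raise ValueError("fewer than 3 usable points for the Birks fit")

    kb0 = 0.1
    if dose is None:
        def birks(l, l0, kb):
            return l0 * l / (1.0 + kb * l)
        num = x
    else:
        d = dose.values[mask]

        def birks(l, l0, kb):
            return l0 * d / (1.0 + kb * l)
        num = d

    order = np.argsort(x)[: max(3, len(x) // 10)]
    l0_0 = float(np.mean(y[order] / num[order]) * (1 + kb0 * np.mean(x[order])))
    sigma = None if weights is None else 1.0 / np.sqrt(np.asarray(weights)[mask])
    try:
        popt, pcov = optimize.curve_fit(
            birks, x, y, p0=[l0_0, kb0], sigma=sigma, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"Birks fit failed to converge on {len(x)} points "
            f"(LET {x.min():.2f}-{x.max():.2f} MeV/mm): {exc}") from exc

    l0_hat, kb_hat = popt
    se_kb = float(np.sqrt(pcov[1, 1]))
    tq = stats.t.ppf(0.975, max(len(x) - 2, 1))
    lo, hi = kb_hat - tq * se_kb, kb_hat + tq * se_kb
    if kb_hat < 0:
        warnings.warn("negative kB estimate clipped to 0", stacklevel=2)
        kb_hat = 0.0
        hi = max(hi, 0.0)
        lo = min(lo, 0.0)
    rss = float(np.sum((y - birks(x, l0_hat, max(kb_hat, 0.0))) ** 2))
    return QuenchFit(kB=float(kb_hat), kB_ci_low=float(lo), kB_ci_high=float(hi),
                     L0=float(l0_hat), rss=rss, n_points=int(len(x)))
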