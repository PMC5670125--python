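"""Thermal-curve descriptors and Michaelis–Menten kinetics fitting.

Both thermal assays are described by a two-state logistic — the minimal
model of cooperative unfolding/inactivation with an analytic maximum slope:

* thermal shift (dye fluorescence): after normalization to unfolded
  fraction, f(T) = 1/(1 + exp((Tm − T)/k)); the midpoint Tm is T0.5, the
  maximum slope of the percentage curve is 25/k %/°C, and the onset
  ("initial unfolding temperature") is the fitted 5%-unfolded crossing,
  Tm − k·ln(19).
* thermal inactivation (residual activity after a fixed heat treatment):
  A(T) = 100/(1 + exp((T − T50)/k)); the midpoint is T50.

Kinetics: nonlinear least squares on v = Vmax·S/(Km + S). With the enzyme
amount E0 given in both mg and nmol, Vmax (µmol·min⁻¹) converts to
kcat = Vmax·1000/(60·E0_nmol) s⁻¹ and specific activity Vmax/E0_mg U·mg⁻¹
(1 U = 1 µmol substrate converted per minute); efficiency is kcat/Km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .structio import CurveTable

__all__ = [
    "StabilityFit",
    "KineticsFit",
    "FitError",
    "normalize_melting",
    "fit_unfolding",
    "fit_t50",
    "fit_michaelis_menten",
]

ONSET_FRACTION = 0.05     # unfolded fraction defining the onset temperature
BASELINE_FRACTION = 0.10  # lowest-temperature points used for the baseline
LN19 = math.log((1 - ONSET_FRACTION) / ONSET_FRACTION)


class FitError(RuntimeError):
    """Curve fitting failed (non-convergence or unusable input)."""


@dataclass
class StabilityFit:
    """Descriptors of one thermal curve."""

    midpoint: float          # °C: T0.5 (melting) or T50 (inactivation)
    k: float                 # °C, logistic scale
    max_slope: float         # %/°C, analytic maximum of the % curve
    onset: float             # °C, 5% transition crossing
    residual_rms: float      # RMS residual in normalized units
    direction: str           # "unfolding" | "activity"
    midpoint_se: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("logistic scale k must be > 0")
        if self.direction == "unfolding" and not self.onset < self.midpoint:
            raise ValueError("onset must precede the midpoint for rising curves")


@dataclass
class KineticsFit:
    """Michaelis–Menten parameters and derived catalytic quantities."""

    km: float                 # mM
    vmax: float               # µmol·min⁻¹ at the assayed enzyme amount
    kcat: float               # s⁻¹
    specific_activity: float  # U/mg
    efficiency: float         # kcat/Km, mM⁻¹·s⁻¹
    km_se: float
    vmax_se: float
    kcat_se: float
    efficiency_se: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("km", "vmax", "kcat", "specific_activity", "efficiency"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not math.isclose(self.efficiency, self.kcat / self.km,
                            rel_tol=1e-12):
            raise ValueError("efficiency must equal kcat/Km")


# ---------------------------------------------------------------------------
# Melting-curve normalization and fit
# ---------------------------------------------------------------------------

def normalize_melting(curve: CurveTable) -> CurveTable:
    """Normalize a raw melting signal to unfolded fraction (p.d.u.).

    Baseline = mean of the lowest-temperature 10% of points; plateau = the
    maximum of a 3-point moving average (robust to post-peak dye quenching).
    y' = (y − baseline)/(plateau − baseline), clipped to [0, 1.05], so a
    value of 1 corresponds to completely unfolded protein. Idempotent: the
    baseline window of a normalized curve averages 0 and its plateau is 1.
    """
    if curve.kind != "melting":
        raise ValueError("normalize_melting expects a melting curve")
    y = curve.y
    n_base = max(1, math.ceil(BASELINE_FRACTION * len(y)))
    baseline = float(np.mean(y[:n_base]))
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="valid")
    plateau = float(np.max(smooth))
    if plateau - baseline <= 1e-9 * max(1.0, abs(plateau)):
        raise FitError("no transition: plateau indistinguishable from baseline")
    norm = np.clip((y - baseline) / (plateau - baseline), 0.0, 1.05)
    meta = dict(curve.metadata)
    meta.update({"baseline": baseline, "plateau": plateau, "normalized": True})
    return CurveTable(x=curve.x.copy(), y=norm, kind="melting", metadata=meta)


def _rising_logistic(t, tm, k):
    return 1.0 / (1.0 + np.exp((tm - t) / k))


def _interp_crossing(x: np.ndarray, y: np.ndarray, level: float) -> float | None:
    """First monotone linear-interpolation crossing of ``level``."""
    sign = np.sign(y - level)
    for i in range(len(x) - 1):
        if sign[i] == 0:
            return float(x[i])
        if sign[i] * sign[i + 1] < 0:
            f = (level - y[i]) / (y[i + 1] - y[i])
            return float(x[i] + f * (x[i + 1] - x[i]))
    return None


def fit_unfolding(curve: CurveTable) -> StabilityFit:
    """Two-state logistic fit of a normalized melting curve.

    Returns the midpoint T0.5, the logistic scale k, the analytic maximum
    slope 25/k %/°C, and the onset temperature (fitted 5% crossing,
    Tm − k·ln 19, clipped to the observed range). If the nonlinear fit fails,
    the midpoint falls back to monotone linear interpolation of the 0.5
    crossing.
    """
    if curve.kind != "melting":
        raise ValueError("fit_unfolding expects a melting curve")
    t, y = curve.x, curve.y
    tm0 = _interp_crossing(t, y, 0.5)
    if tm0 is None:
        raise FitError("curve never crosses 0.5: no transition to fit")
    # scale guess from the 0.25->0.75 span: logistic covers it in 2·ln(3)·k
    lo = _interp_crossing(t, y, 0.25)
    hi = _interp_crossing(t, y, 0.75)
    k0 = (hi - lo) / (2 * math.log(3)) if lo is not None and hi is not None else 2.0
    k0 = max(k0, 1e-2)
    try:
        popt, pcov = curve_fit(
            _rising_logistic, t, y, p0=[tm0, k0], maxfev=10000
        )
        tm, k = float(popt[0]), float(abs(popt[1]))
        se = float(np.sqrt(np.diag(pcov))[0]) if np.all(np.isfinite(pcov)) else float("nan")
        resid = y - _rising_logistic(t, tm, k)
        rms = float(np.sqrt(np.mean(resid**2)))
    except RuntimeError:
        # fall back to the interpolated midpoint only
        tm, k, se = tm0, k0, float("nan")
        rms = float("nan")
    onset = tm - k * LN19
    onset = float(np.clip(onset, t[0], t[-1]))
    return StabilityFit(
        midpoint=tm,
        k=k,
        max_slope=25.0 / k,
        onset=onset,
        residual_rms=rms,
        direction="unfolding",
        midpoint_se=se,
        metadata={
            "model": "two-state logistic (assumed; assay names no model)",
            "onset_fraction": ONSET_FRACTION,
        },
    )


def _falling_logistic(t, t50, k):
    return 100.0 / (1.0 + np.exp((t - t50) / k))


def fit_t50(curve: CurveTable) -> StabilityFit:
    """Decreasing-logistic fit of a residual-activity curve; midpoint = T50.

    Activity must be expressed as % of the untreated control (roughly
    0–100%); A(T50) = 50% by construction of the model.
    """
    if curve.kind != "activity":
        raise ValueError("fit_t50 expects an activity curve")
    t, y = curve.x, curve.y
    if np.max(y) > 150.0 or np.all(y < 1.0):
        raise FitError(
            "activity must be a percentage of the untreated control "
            f"(range seen: {y.min():.3g}–{y.max():.3g})"
        )
    t50_0 = _interp_crossing(t, y, 50.0)
    if t50_0 is None:
        raise FitError("activity never crosses 50%: no transition to fit")
    lo = _interp_crossing(t, y, 75.0)
    hi = _interp_crossing(t, y, 25.0)
    k0 = (hi - lo) / (2 * math.log(3)) if lo is not None and hi is not None else 2.0
    k0 = max(k0, 1e-2)
    try:
        popt, pcov = curve_fit(_falling_logistic, t, y, p0=[t50_0, k0], maxfev=10000)
        t50, k = float(popt[0]), float(abs(popt[1]))
        se = float(np.sqrt(np.diag(pcov))[0]) if np.all(np.isfinite(pcov)) else float("nan")
        resid = (y - _falling_logistic(t, t50, k)) / 100.0
        rms = float(np.sqrt(np.mean(resid**2)))
    except RuntimeError:
        t50, k, se, rms = t50_0, k0, float("nan"), float("nan")
    onset = float(np.clip(t50 - k * LN19, t[0], t[-1]))  # 5% activity loss
    return StabilityFit(
        midpoint=t50,
        k=k,
        max_slope=25.0 / k,
        onset=onset,
        residual_rms=rms,
        direction="activity",
        midpoint_se=se,
        metadata={"model": "two-state logistic (assumed; assay names no model)"},
    )


# ---------------------------------------------------------------------------
# Michaelis–Menten kinetics
# ---------------------------------------------------------------------------

def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    data: CurveTable, e0_mg: float, e0_nmol: float
) -> KineticsFit:
    """Nonlinear least-squares Michaelis–Menten fit with derived constants.

    Initial guesses: Vmax = 1.05·max(v), Km = substrate at half-maximal rate
    by interpolation. Standard errors come from the fit covariance; the
    efficiency SE is first-order propagated from Km and kcat.
    """
    if data.kind != "kinetics":
        raise ValueError("fit_michaelis_menten expects a kinetics curve")
    if e0_mg <= 0 or e0_nmol <= 0:
        raise ValueError("enzyme amounts must be positive")
    order = np.argsort(data.x)
    s, v = data.x[order], data.y[order]
    if len(s) < 5:
        raise FitError("need >= 5 substrate points")
    vmax0 = 1.05 * float(np.max(v))
    km0 = _interp_crossing(s, v, vmax0 / 2.1)  # half of the plateau guess
    if km0 is None or km0 <= 0:
        km0 = float(np.median(s))
    try:
        popt, pcov = curve_fit(_mm, s, v, p0=[vmax0, km0], maxfev=10000)
    except RuntimeError as exc:
        raise FitError(
            f"Michaelis–Menten fit did not converge "
            f"(initial guesses Vmax={vmax0:.4g}, Km={km0:.4g})"
        ) from exc
    vmax, km = float(popt[0]), float(popt[1])
    if vmax <= 0 or km <= 0:
        raise FitError(f"non-physical estimates Vmax={vmax:.4g}, Km={km:.4g}")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.nan)
    vmax_se, km_se = float(se[0]), float(se[1])

    # unit conversion: Vmax [µmol/min] over E0 [nmol] -> kcat [s^-1]
    kcat = vmax * 1000.0 / (60.0 * e0_nmol)
    kcat_se = vmax_se * 1000.0 / (60.0 * e0_nmol)
    efficiency = kcat / km
    eff_se = efficiency * math.sqrt(
        (kcat_se / kcat) ** 2 + (km_se / km) ** 2
    ) if np.isfinite(kcat_se) and np.isfinite(km_se) else float("nan")
    return KineticsFit(
        km=km,
        vmax=vmax,
        kcat=kcat,
        specific_activity=vmax / e0_mg,
        efficiency=efficiency,
        km_se=km_se,
        vmax_se=vmax_se,
        kcat_se=kcat_se,
        efficiency_se=eff_se,
        metadata={"e0_mg": e0_mg, "e0_nmol": e0_nmol},
    )
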