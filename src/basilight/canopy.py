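"""Thermal time, leaf-area trajectories, Beer-Lambert light absorption,
and the light/energy-use-efficiency metrics.

The core quantity is the light a plant's canopy actually absorbs.  Daily
incident light energy I (MJ m-2 d-1, natural plus supplemental) is
attenuated through the canopy following Beer-Lambert's law,

    Q_daily = I * (1 - exp(-k * LAI)),

with extinction coefficient k (0.8 for basil) and leaf area index
LAI = leaf area / ground area (0.002025 m2 per plant at the planting
density used here).  Because leaf area is only measured destructively at
harvests, the daily leaf-area course is interpolated on thermal time
(growing degree days above an 11 degC base) between a small seedling
anchor at day 0 and the measured harvest values, assuming exponential
growth in thermal time — with a two-segment fallback when a single
exponential misses a measured anchor by more than 25 %.

Light use efficiency (LUE, g MJ-1) is dry weight per unit absorbed light;
energy use efficiency (EUE, g MJ-1) relates the dry weight attributable to
the lamps to the electrical energy they drew, through the lamp's electrical
conversion efficacy mu (MJ light per MJ electricity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GROUND_AREA_M2",
    "K_EXTINCTION",
    "T_BASE_C",
    "SEEDLING_LEAF_AREA_M2",
    "ThermalTime",
    "LeafAreaTrajectory",
    "thermal_time",
    "interpolate_leaf_area",
    "daily_absorbed_light",
    "cumulative_absorbed",
    "light_use_efficiency",
    "energy_use_efficiency",
    "supplemental_dw",
]

#: Ground area per plant (m2) at the experimental planting density.
GROUND_AREA_M2 = 0.002025
#: Canopy light extinction coefficient assumed for basil.
K_EXTINCTION = 0.8
#: Base temperature for basil thermal time (degC).
T_BASE_C = 11.0
#: Leaf area assigned to the day-0 anchor (m2).  The treatment starts from
#: transplants, not literal zero leaf area; log-scale interpolation needs a
#: positive anchor, and 0.5 cm2 is a typical basil seedling at transplant.
SEEDLING_LEAF_AREA_M2 = 5e-5


@dataclass(frozen=True)
class ThermalTime:
    """Accumulated growing degree days over a treatment period."""

    t_base_C: float
    daily_gdd: np.ndarray
    cumulative: np.ndarray


def thermal_time(daily_mean_temps, t_base: float = T_BASE_C) -> ThermalTime:
    """Growing degree days: ``max(0, T_mean - t_base)`` per day, accumulated.

    Negative increments are floored at zero (no "devernalization"), so the
    cumulative sum is non-decreasing.
    """
    temps = np.asarray(daily_mean_temps, dtype=float)
    if temps.size == 0:
        raise ValueError("temperature sequence is empty")
    gdd = np.maximum(temps - t_base, 0.0)
    return ThermalTime(t_base_C=t_base, daily_gdd=gdd, cumulative=np.cumsum(gdd))


@dataclass
class LeafAreaTrajectory:
    """Daily leaf-area course interpolated on thermal time.

    ``method_used`` records whether the single three-point exponential or
    the two-segment fallback produced the trajectory; ``anchor_deviations``
    holds the relative error of the three-point fit at each measured
    anchor (the quantity the >25 % rule is applied to).
    """

    tt_daily: np.ndarray
    leaf_area_m2: np.ndarray
    anchors_tt: np.ndarray
    anchors_la: np.ndarray
    method_used: str
    anchor_deviations: np.ndarray = field(default_factory=lambda: np.array([]))

    def lai(self, ground_area_m2: float = GROUND_AREA_M2) -> np.ndarray:
        return self.leaf_area_m2 / ground_area_m2


def _exp_through_two(tt0, la0, tt1, la1, tt):
    """Exponential in thermal time through two (tt, la) points exactly."""
    b = (np.log(la1) - np.log(la0)) / (tt1 - tt0)
    a = np.log(la0) - b * tt0
    return np.exp(a + b * np.asarray(tt, dtype=float))


def interpolate_leaf_area(
    anchors,
    tt_daily,
    deviation_threshold: float = 0.25,
) -> LeafAreaTrajectory:
    """Interpolate a daily leaf-area course from harvest anchors.

    Parameters
    ----------
    anchors
        Sequence of (cumulative thermal time degCd, leaf area m2) points in
        ascending thermal-time order: the day-0 seedling anchor, the
        intermediate-harvest measurement and (for final-harvest plants) the
        final-harvest measurement.  All leaf areas must be positive.
    tt_daily
        Cumulative thermal time at each day for which a leaf area is wanted.
    deviation_threshold
        Relative-error threshold of the >25 % fallback rule.  The three
        anchors are fitted with one regression of ln(LA) on thermal time;
        if the back-transformed prediction at either measured anchor
        deviates from the measurement by more than this fraction, two exact
        log-linear segments (start->intermediate, intermediate->final) are
        used instead.  ``np.inf`` disables the fallback.

    Returns
    -------
    LeafAreaTrajectory
        With ``method_used`` one of ``"three-point-exponential"`` or
        ``"two-segment"``.  The two-segment trajectory passes through every
        anchor exactly.
    """
    pts = [(float(t), float(a)) for t, a in anchors]
    if len(pts) not in (2, 3):
        raise ValueError("expected two or three (thermal time, leaf area) anchors")
    tts = np.array([p[0] for p in pts])
    las = np.array([p[1] for p in pts])
    if np.any(np.diff(tts) <= 0):
        raise ValueError("anchors must be strictly ascending in thermal time")
    if np.any(las <= 0):
        raise ValueError("leaf areas must be positive (log-scale interpolation)")
    tt_daily = np.asarray(tt_daily, dtype=float)

    if len(pts) == 2:
        la = _exp_through_two(tts[0], las[0], tts[1], las[1], tt_daily)
        return LeafAreaTrajectory(
            tt_daily=tt_daily,
            leaf_area_m2=la,
            anchors_tt=tts,
            anchors_la=las,
            method_used="three-point-exponential",
            anchor_deviations=np.zeros(1),
        )

    # single exponential: OLS of ln(LA) on thermal time over the 3 anchors
    coef = np.polyfit(tts, np.log(las), 1)
    pred_anchor = np.exp(np.polyval(coef, tts[1:]))
    deviations = np.abs(pred_anchor - las[1:]) / las[1:]

    if np.any(deviations > deviation_threshold):
        seg1 = _exp_through_two(tts[0], las[0], tts[1], las[1], tt_daily)
        seg2 = _exp_through_two(tts[1], las[1], tts[2], las[2], tt_daily)
        la = np.where(tt_daily <= tts[1], seg1, seg2)
        method = "two-segment"
    else:
        la = np.exp(np.polyval(coef, tt_daily))
        method = "three-point-exponential"

    return LeafAreaTrajectory(
        tt_daily=tt_daily,
        leaf_area_m2=la,
        anchors_tt=tts,
        anchors_la=las,
        method_used=method,
        anchor_deviations=deviations,
    )


def daily_absorbed_light(incident, lai, k: float = K_EXTINCTION):
    """Beer-Lambert daily absorbed light: ``I * (1 - exp(-k * LAI))``.

    Accepts scalars or arrays (broadcast).  Bounded above by the incident
    light; strictly increasing in both LAI and k.
    """
    incident = np.asarray(incident, dtype=float)
    lai = np.asarray(lai, dtype=float)
    if np.any(incident < 0) or np.any(lai < 0):
        raise ValueError("incident light and LAI must be non-negative")
    if k <= 0:
        raise ValueError("extinction coefficient k must be positive")
    out = incident * -np.expm1(-k * lai)
    return float(out) if out.ndim == 0 else out


def cumulative_absorbed(q_daily_series) -> float:
    """Total absorbed light over a period: the sum of daily values (MJ m-2)."""
    q = np.asarray(q_daily_series, dtype=float)
    if q.size == 0:
        return 0.0
    if np.any(q < 0):
        raise ValueError("daily absorbed light cannot be negative")
    return float(np.sum(q))


def light_use_efficiency(dw: float, q_total: float) -> float:
    """Dry weight produced per unit absorbed light, g MJ-1."""
    if q_total <= 0:
        raise ValueError("q_total must be positive")
    if dw < 0:
        raise ValueError("dry weight must be non-negative")
    return dw / q_total


def energy_use_efficiency(dw_sl: float, sl: float, mu: float) -> float:
    """Dry weight from supplemental light per unit electrical energy, g MJ-1.

    ``dw_sl`` is the dry weight attributable to the lamps (g m-2), ``sl``
    the supplemental light energy received (MJ m-2), and ``mu`` the lamp's
    electrical conversion efficacy (MJ light output per MJ electricity),
    e.g. 0.63 for the red LED and 0.37 for blue or white+far-red.
    """
    if sl <= 0:
        raise ValueError("supplemental light sum must be positive")
    if not 0 <= mu <= 1:
        raise ValueError("conversion efficacy mu must be within [0, 1]")
    return (dw_sl / sl) * mu


def supplemental_dw(fit, dose: float, ground_area_m2: float = GROUND_AREA_M2) -> float:
    """Dry weight attributable to supplemental light, g m-2.

    Defined from a fitted dry-weight dose-response as the natural-scale
    prediction at the plant's dose minus the prediction at dose zero,
    divided by the ground area per plant.  ``fit`` must expose
    ``predict_log(dose)`` returning ln(dry weight) (see
    :class:`basilight.dose_response.DoseResponseFit`) and a fitted dose
    range ``dose_range``.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    lo, hi = getattr(fit, "dose_range", (0.0, np.inf))
    if dose < lo or dose > hi:
        warnings.warn(
            f"dose {dose:g} outside fitted range [{lo:g}, {hi:g}]; extrapolating",
            stacklevel=2,
        )
    dw_at_dose = np.exp(fit.predict_log(dose))
    dw_at_zero = np.exp(fit.predict_log(0.0))
    return float(dw_at_dose - dw_at_zero) / ground_area_m2
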