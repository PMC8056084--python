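"""End-to-end analysis of one experiment: light accounting per plant,
stage-1 dose-response fits, and the stage-2 efficiency model.

The entry point is :func:`analyze_experiment`, which takes a
:class:`~basilight.synthetic_data.SimulatedExperiment` (or anything with
the same observation/environment/spectra layout read from disk) and a
photometric band — 700 for PPFD over 400-700 nm, 800 to count far-red
photons as well — and produces

* a per-plant table of absorbed light (Q_total), light use efficiency and
  energy use efficiency,
* the stage-1 fit table (one linear and one monomolecular fit per
  replicate x color x season x harvest x trait, with the F comparison),
* stage-2 mixed-model results per trait for slopes and intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import canopy, photometry
from .dose_response import (
    compare_models,
    efficiency_table,
    fit_linear,
    fit_monomolecular,
)
from .stage2 import MixedModelResult, fit_efficiency_model
from .synthetic_data import SimulatedExperiment, ppfd800_factor

__all__ = [
    "ANALYSIS_TRAITS",
    "AnalysisResult",
    "band_dose_column",
    "plant_efficiency_table",
    "stage1_fits",
    "stage2_models",
    "analyze_experiment",
]

#: Traits carried through the dose-response and stage-2 analysis.
ANALYSIS_TRAITS = [
    "shoot_fw_g",
    "shoot_dw_g",
    "leaf_area_m2",
    "plant_height_mm",
    "epicotyl_mm",
    "internode_mm",
    "lma_g_m2",
    "stem_leaf_ratio",
]

DEFAULT_MU = {"blue": 0.37, "red": 0.63, "white_fr": 0.37}

CELL = ["color", "season", "replication", "harvest"]


@dataclass
class AnalysisResult:
    band: int
    plants: pd.DataFrame = field(repr=False)
    fits: pd.DataFrame = field(repr=False)
    stage2: dict = field(repr=False)  # (trait, "slope"|"intercept") -> MixedModelResult
    warnings: list = field(default_factory=list)

    def stage2_table(self) -> pd.DataFrame:
        """All stage-2 ANOVA rows in one long table."""
        rows = []
        for (trait, kind), res in self.stage2.items():
            t = res.anova.copy()
            t.insert(0, "response_kind", kind)
            t.insert(0, "trait", trait)
            t["method"] = res.method
            rows.append(t)
        return pd.concat(rows, ignore_index=True)


def band_dose_column(
    observations: pd.DataFrame, spectra: dict, band: int
) -> tuple[pd.DataFrame, str]:
    """Attach the dose column for the requested band.

    For band 700 the recorded supplemental PPFD is used as-is; for band 800
    each treatment's dose is multiplied by its lamp spectrum's
    PPFD800:PPFD700 ratio (far-red-rich lamps deliver extra photons above
    700 nm that band-700 accounting ignores).
    """
    obs = observations.copy()
    if band == 700:
        return obs, "dose_ppfd700"
    if band != 800:
        raise ValueError("band must be 700 or 800")
    factors = {color: ppfd800_factor(spec) for color, spec in spectra.items()}
    missing = set(obs["treatment"].unique()) - set(factors)
    if missing:
        raise ValueError(f"no lamp spectrum for treatments: {sorted(missing)}")
    obs["dose_ppfd800"] = obs["dose_ppfd700"] * obs["treatment"].map(factors)
    return obs, "dose_ppfd800"


def _harvest_days(experiment: SimulatedExperiment, harvest_days: dict | None) -> dict:
    if harvest_days is not None:
        return harvest_days
    if experiment.config is not None:
        return {
            s: (sc.days_to_intermediate, sc.days_to_final)
            for s, sc in experiment.config.seasons.items()
        }
    raise ValueError(
        "harvest days unknown: pass harvest_days={season: (day_int, day_final)}"
    )


def _fit_group_trajectories(tt_anchor, la_anchor_rows, deviation_threshold):
    """Vectorised three-point log-linear fit across plants.

    ``tt_anchor`` is the shared (3,) thermal-time vector of the anchors;
    ``la_anchor_rows`` an (n_plants, 3) array of leaf areas.  Returns the
    per-plant (a, b) of ln(LA) = a + b*TT, a fallback mask where the single
    exponential misses a measured anchor by more than the threshold, and
    the anchor deviations.  Matches :func:`basilight.canopy.interpolate_leaf_area`
    applied plant by plant.
    """
    t = np.asarray(tt_anchor, dtype=float)
    Y = np.log(np.asarray(la_anchor_rows, dtype=float))
    tbar = t.mean()
    b = ((t - tbar) @ (Y - Y.mean(axis=1, keepdims=True)).T) / np.sum((t - tbar) ** 2)
    a = Y.mean(axis=1) - b * tbar
    pred = np.exp(a[:, None] + b[:, None] * t[None, 1:])
    deviations = np.abs(pred - np.exp(Y[:, 1:])) / np.exp(Y[:, 1:])
    fallback = (deviations > deviation_threshold).any(axis=1)
    return a, b, fallback, deviations


def plant_efficiency_table(
    experiment: SimulatedExperiment,
    band: int = 700,
    k: float = canopy.K_EXTINCTION,
    deviation_threshold: float = 0.25,
    seedling_leaf_area_m2: float | None = None,
    harvest_days: dict | None = None,
    mu: dict | None = None,
    dw_fits: dict | None = None,
    warnings_out: list | None = None,
) -> pd.DataFrame:
    """Per-plant light absorption and efficiency metrics.

    For every plant the daily leaf-area course is interpolated on thermal
    time (final-harvest plants use the dose-matched intermediate-harvest
    plant at the same gradient position as their middle anchor), incident
    daily light is the band-matched natural DLI plus the plant's
    supplemental DLI, both in MJ via the 0.219 factor, and Q_total
    accumulates the Beer-Lambert absorbed light to the plant's harvest.

    LUE = shoot dry weight / Q_total.  EUE additionally needs the cell's
    fitted dry-weight dose-response (``dw_fits``, keyed by the
    (color, season, replication, harvest) tuple); without it the EUE
    column is NaN.

    Returns a DataFrame with ``q_total_MJ``, ``sl_MJ``, ``lue``, ``eue``
    and the interpolation method per plant.
    """
    cfg = experiment.config
    la0 = (
        seedling_leaf_area_m2
        if seedling_leaf_area_m2 is not None
        else (cfg.seedling_leaf_area_m2 if cfg else canopy.SEEDLING_LEAF_AREA_M2)
    )
    hdays = _harvest_days(experiment, harvest_days)
    mu = mu or (
        {c: t.mu for c, t in cfg.treatments.items()} if cfg else DEFAULT_MU
    )
    warnings_out = warnings_out if warnings_out is not None else []

    obs, dose_col = band_dose_column(experiment.observations, experiment.spectra, band)
    nat_col = f"natural_dli_{band}"

    pieces = []
    for (season, color, rep), group in obs.groupby(
        ["season", "treatment", "replication"], observed=True
    ):
        env = experiment.environments[season]
        d_int, d_fin = hdays[season]
        tt = canopy.thermal_time(env["mean_temp_C"].to_numpy()).cumulative
        tt_int, tt_fin = tt[d_int - 1], tt[d_fin - 1]

        inter = group[group["harvest"] == "intermediate"]
        final = group[group["harvest"] == "final"]
        la_int_by_pos = inter.set_index("position")["leaf_area_m2"]

        for harvest, sub in (("intermediate", inter), ("final", final)):
            if sub.empty:
                continue
            n = len(sub)
            d_h = d_int if harvest == "intermediate" else d_fin
            la_own = sub["leaf_area_m2"].to_numpy()
            if harvest == "intermediate":
                # two anchors: seedling and own harvest; exact exponential
                b = (np.log(la_own) - np.log(la0)) / tt_int
                a = np.full(n, np.log(la0))
                method = np.full(n, "three-point-exponential", dtype=object)
            else:
                partner = la_int_by_pos.reindex(sub["position"]).to_numpy()
                have_partner = np.isfinite(partner)
                if not have_partner.all():
                    warnings_out.append(
                        f"{season}/{color}/rep{rep}: "
                        f"{int((~have_partner).sum())} final plants without a "
                        "dose-matched intermediate anchor; using two anchors"
                    )
                anchors = np.column_stack(
                    [np.full(n, la0), np.where(have_partner, partner, la_own), la_own]
                )
                a, b, fallback, _ = _fit_group_trajectories(
                    (0.0, tt_int, tt_fin), anchors, deviation_threshold
                )
                method = np.where(fallback, "two-segment", "three-point-exponential")
                # plants without a partner: exact exponential through (0, own)
                b = np.where(have_partner, b, (np.log(la_own) - np.log(la0)) / tt_fin)
                a = np.where(have_partner, a, np.log(la0))
                if fallback.any():
                    warnings_out.append(
                        f"{season}/{color}/rep{rep}/final: two-segment "
                        f"interpolation for {int(fallback.sum())} plants "
                        f"(> {deviation_threshold:.0%} anchor deviation)"
                    )

            days = np.arange(1, d_h + 1)
            tt_days = tt[days - 1]
            if harvest == "final":
                # two-segment plants: exact exponentials through anchor pairs
                la_daily = np.empty((d_h, n))
                single = np.exp(a[None, :] + np.outer(tt_days, b))
                if (method == "two-segment").any():
                    b1 = (np.log(anchors[:, 1]) - np.log(la0)) / tt_int
                    b2 = (np.log(la_own) - np.log(anchors[:, 1])) / (tt_fin - tt_int)
                    seg1 = la0 * np.exp(np.outer(tt_days, b1))
                    seg2 = anchors[:, 1][None, :] * np.exp(
                        np.outer(tt_days - tt_int, b2)
                    )
                    two_seg = np.where(tt_days[:, None] <= tt_int, seg1, seg2)
                    la_daily = np.where(method[None, :] == "two-segment", two_seg, single)
                else:
                    la_daily = single
            else:
                la_daily = np.exp(a[None, :] + np.outer(tt_days, b))

            dose_band = sub[dose_col].to_numpy()
            photoperiod = float(env["photoperiod_h"].iloc[0])
            suppl_dli = dose_band * photoperiod * 3600.0 * 1e-6
            incident = (
                env[nat_col].to_numpy()[days - 1, None] + suppl_dli[None, :]
            ) * photometry.ENERGY_PER_MOL_PAR
            q_daily = canopy.daily_absorbed_light(
                incident, la_daily / canopy.GROUND_AREA_M2, k=k
            )
            q_total = q_daily.sum(axis=0)
            sl = suppl_dli * photometry.ENERGY_PER_MOL_PAR * d_h

            dw = sub["shoot_dw_g"].to_numpy()
            lue = dw / q_total

            eue = np.full(n, np.nan)
            if dw_fits is not None:
                fit = dw_fits.get((color, season, rep, harvest))
                if fit is not None:
                    dose700 = sub["dose_ppfd700"].to_numpy()
                    with np.errstate(all="ignore"):
                        dw_sl = (
                            fit.predict(dose700) - fit.predict(0.0)
                        ) / canopy.GROUND_AREA_M2
                    ok = sl > 0
                    eue[ok] = dw_sl[ok] / sl[ok] * mu.get(color, np.nan)

            pieces.append(
                pd.DataFrame(
                    {
                        "plant_id": sub["plant_id"].to_numpy(),
                        "treatment": color,
                        "season": season,
                        "replication": rep,
                        "harvest": harvest,
                        "dose_ppfd700": sub["dose_ppfd700"].to_numpy(),
                        "band": band,
                        "dw_g": dw,
                        "q_total_MJ": q_total,
                        "sl_MJ": sl,
                        "lue": lue,
                        "eue": eue,
                        "interp_method": method,
                    }
                )
            )
    return pd.concat(pieces, ignore_index=True)


def stage1_fits(
    observations: pd.DataFrame,
    dose_col: str,
    traits=ANALYSIS_TRAITS,
    fit_mono: bool = True,
    warnings_out: list | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Dose-response fits for every cell and trait.

    Returns the long fit table (linear rows, plus monomolecular rows when
    ``fit_mono``) and a dict of the *linear* fits keyed by
    (color, season, replication, harvest, trait) for downstream use.
    Failed cells appear in the table with the failure reason.
    """
    warnings_out = warnings_out if warnings_out is not None else []
    items = []
    linear_fits = {}
    for (color, season, rep, harvest), group in observations.groupby(
        ["treatment", "season", "replication", "harvest"], observed=True
    ):
        meta = {
            "color": color,
            "season": season,
            "replication": rep,
            "harvest": harvest,
        }
        for trait in traits:
            try:
                lin = fit_linear(group, trait, dose_col)
            except (ValueError, RuntimeError) as err:
                items.append(({**meta, "trait": trait}, err))
                warnings_out.append(
                    f"{season}/{color}/rep{rep}/{harvest}/{trait}: fit failed ({err})"
                )
                continue
            lin.meta = {**meta}
            items.append(lin)
            linear_fits[(color, season, rep, harvest, trait)] = lin
            if lin.n_excluded:
                warnings_out.append(
                    f"{season}/{color}/rep{rep}/{harvest}/{trait}: "
                    f"{lin.n_excluded} plants with non-positive values excluded"
                )
            if fit_mono:
                try:
                    mono = fit_monomolecular(group, trait, dose_col)
                    cmp_ = compare_models(lin, mono)
                    lin.f_stat = mono.f_stat = cmp_.f_stat
                    lin.p_value = mono.p_value = cmp_.p_value
                    mono.meta = {**meta}
                    items.append(mono)
                except (ValueError, RuntimeError) as err:
                    items.append(({**meta, "trait": trait + ":monomolecular"}, err))
                    warnings_out.append(
                        f"{season}/{color}/rep{rep}/{harvest}/{trait}: "
                        f"monomolecular fit failed ({err})"
                    )
    return efficiency_table(items), linear_fits


def stage2_models(
    fits: pd.DataFrame,
    traits=ANALYSIS_TRAITS,
    compute_varcomp: bool = True,
    warnings_out: list | None = None,
) -> dict:
    """Stage-2 mixed model per trait for slopes and intercepts."""
    warnings_out = warnings_out if warnings_out is not None else []
    linear = fits[fits["model"] == "linear"]
    out: dict[tuple[str, str], MixedModelResult] = {}
    for trait in traits:
        sub = linear[linear["trait"] == trait]
        if sub.empty:
            continue
        for kind, col in (("slope", "slope"), ("intercept", "intercept")):
            records = sub[CELL + [col]].rename(columns={col: "value"})
            try:
                res = fit_efficiency_model(records, compute_varcomp=compute_varcomp)
                out[(trait, kind)] = res
                warnings_out.extend(f"{trait}/{kind}: {n}" for n in res.notes)
            except ValueError as err:
                warnings_out.append(f"{trait}/{kind}: stage-2 fit failed ({err})")
    return out


def analyze_experiment(
    experiment: SimulatedExperiment,
    band: int = 700,
    traits=ANALYSIS_TRAITS,
    k: float = canopy.K_EXTINCTION,
    fit_mono: bool = True,
    compute_varcomp: bool = True,
    harvest_days: dict | None = None,
) -> AnalysisResult:
    """Run the full analysis on one experiment for one photometric band."""
    warns: list = []
    obs, dose_col = band_dose_column(
        experiment.observations, experiment.spectra, band
    )
    fits, linear_fits = stage1_fits(
        obs, dose_col, traits=traits, fit_mono=fit_mono, warnings_out=warns
    )
    dw_fits = {
        (c, s, r, h): f
        for (c, s, r, h, trait), f in linear_fits.items()
        if trait == "shoot_dw_g"
    }
    plants = plant_efficiency_table(
        experiment,
        band=band,
        k=k,
        harvest_days=harvest_days,
        dw_fits=dw_fits,
        warnings_out=warns,
    )
    stage2 = stage2_models(
        fits, traits=traits, compute_varcomp=compute_varcomp, warnings_out=warns
    )
    return AnalysisResult(
        band=band, plants=plants, fits=fits, stage2=stage2, warnings=warns
    )
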