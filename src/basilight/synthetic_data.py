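"""Virtual supplemental-lighting experiments.

The generator reproduces the statistical structure the analysis pipeline
assumes: three LED colors (blue, red, white plus far-red) crossed with four
seasons and two replications; within every treatment a continuous gradient
of supplemental PPFD from ~230 umol m-2 s-1 under the lamp down to <1 at
the compartment edge, with 120 plants per harvest half and a dose-matched
mirror plant in the other half; seasonal daily environments anchored to the
study's greenhouse records (mean temperature and natural daily light
integral per season); and trait responses that are log-linear in the square
root of the dose with lognormal noise.

Two generative modes are provided:

* ``phenomenological`` (default) — every trait is drawn directly from
  ``ln(y) = alpha + beta * sqrt(dose) + rep effect + noise`` with per-color
  and per-season parameter offsets; derived traits (shoot weights, height,
  LMA, stem-leaf ratio) are built from their components so the table's
  internal consistency invariants hold by construction.
* ``mechanistic`` — leaf area grows exponentially in thermal time from a
  seedling anchor and dry weight accrues as a fixed true light-use
  efficiency times the Beer-Lambert absorbed light, noise-free, so the
  pipeline's LUE estimate must return the configured truth exactly.

Ground-truth parameters are stored alongside every simulated experiment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import canopy, photometry
from .photometry import Spectrum

__all__ = [
    "SeasonConfig",
    "GradientConfig",
    "TreatmentConfig",
    "TraitParams",
    "SimulationConfig",
    "SimulatedExperiment",
    "COLORS",
    "SEASONS",
    "OBSERVATION_COLUMNS",
    "lamp_spectrum",
    "simulate_environment",
    "simulate_gradient",
    "simulate_plants",
    "write_experiment",
    "read_experiment",
]

COLORS = ("blue", "red", "white_fr")
SEASONS = ("late_winter", "mid_spring", "early_summer", "late_summer")
HARVESTS = ("intermediate", "final")

OBSERVATION_COLUMNS = [
    "plant_id",
    "treatment",
    "season",
    "replication",
    "harvest",
    "position",
    "dose_ppfd700",
    "leaf_fw_g",
    "stem_fw_g",
    "shoot_fw_g",
    "leaf_dw_g",
    "stem_dw_g",
    "shoot_dw_g",
    "leaf_area_m2",
    "hypocotyl_mm",
    "epicotyl_mm",
    "internode_mm",
    "plant_height_mm",
    "lma_g_m2",
    "stem_leaf_ratio",
]


@dataclass
class SeasonConfig:
    """One season's greenhouse environment and experiment timing."""

    mean_temp_C: float
    mean_natural_dli_700: float
    days_to_intermediate: int
    days_to_final: int
    temp_sd_C: float = 1.5
    dli_cv: float = 0.3


@dataclass
class GradientConfig:
    """The supplemental light gradient below a single lamp."""

    max_ppfd: float = 230.0
    min_ppfd: float = 0.5
    n_positions: int = 120
    shape: str = "exponential"  # "exponential" | "linear" | "inverse_square"


@dataclass
class TreatmentConfig:
    """A light-color treatment: its electrical conversion efficacy."""

    mu: float


@dataclass
class TraitParams:
    """Log-scale dose-response parameters of one measured trait.

    ``alpha`` is ln(trait) at dose 0 (intermediate harvest, late winter);
    ``beta`` the slope per sqrt(umol m-2 s-1).  ``beta_by_color`` gives the
    per-color slopes (overriding ``beta``); season offsets are additive on
    alpha and beta respectively, so color and season act without
    interaction by default.
    """

    alpha: float
    beta: float
    sigma: float = 0.2
    beta_by_color: dict = field(default_factory=dict)
    alpha_final_offset: float = 0.0
    alpha_by_season: dict = field(default_factory=dict)
    beta_by_season: dict = field(default_factory=dict)

    def slope(self, color: str, season: str) -> float:
        return self.beta_by_color.get(color, self.beta) + self.beta_by_season.get(
            season, 0.0
        )

    def level(self, season: str, harvest: str) -> float:
        a = self.alpha + self.alpha_by_season.get(season, 0.0)
        if harvest == "final":
            a += self.alpha_final_offset
        return a


def _default_seasons() -> dict:
    return {
        "late_winter": SeasonConfig(19.3, 7.1, 18, 32),
        "mid_spring": SeasonConfig(20.6, 9.8, 20, 28),
        "early_summer": SeasonConfig(24.4, 15.7, 15, 29),
        "late_summer": SeasonConfig(24.1, 13.8, 14, 33),
    }


def _default_treatments() -> dict:
    return {
        "blue": TreatmentConfig(mu=0.37),
        "red": TreatmentConfig(mu=0.63),
        "white_fr": TreatmentConfig(mu=0.37),
    }


_SEASON_ALPHA = {
    "late_winter": 0.0,
    "mid_spring": 0.10,
    "early_summer": 0.35,
    "late_summer": 0.30,
}
_SEASON_BETA = {
    "late_winter": 0.004,
    "mid_spring": 0.002,
    "early_summer": -0.004,
    "late_summer": -0.002,
}


def _default_traits() -> dict:
    """Primary trait parameters; magnitudes typical for greenhouse basil.

    Slope ordering follows the study's qualitative finding: blue least
    efficient, red and white+far-red similar and higher; elongation traits
    respond mainly to red and far-red.
    """

    def tp(alpha, betas, final, beta_season=True):
        return TraitParams(
            alpha=alpha,
            beta=betas[1],
            beta_by_color={"blue": betas[0], "red": betas[1], "white_fr": betas[2]},
            alpha_final_offset=final,
            alpha_by_season=dict(_SEASON_ALPHA),
            beta_by_season=dict(_SEASON_BETA) if beta_season else {},
        )

    return {
        "leaf_dw_g": tp(np.log(0.6), (0.060, 0.090, 0.090), 0.9),
        "stem_dw_g": tp(np.log(0.25), (0.065, 0.100, 0.095), 1.1),
        "leaf_area_m2": tp(np.log(0.012), (0.035, 0.055, 0.045), 0.7),
        "hypocotyl_mm": tp(np.log(22.0), (0.004, 0.004, 0.004), 0.05, False),
        "epicotyl_mm": tp(np.log(14.0), (0.008, 0.030, 0.035), 0.2, False),
        "internode_mm": tp(np.log(55.0), (0.010, 0.030, 0.040), 0.5, False),
    }


@dataclass
class SimulationConfig:
    """Complete description of one virtual experiment."""

    seed: int = 0
    seasons: dict = field(default_factory=_default_seasons)
    gradient: GradientConfig = field(default_factory=GradientConfig)
    treatments: dict = field(default_factory=_default_treatments)
    traits: dict = field(default_factory=_default_traits)
    n_replications: int = 2
    photoperiod_h: float = 18.0
    natural_800_factor: float = 1.25
    mode: str = "phenomenological"  # | "mechanistic"
    sigma_rep: float = 0.05
    dmc_mean: float = 0.08
    dmc_sigma: float = 0.05
    lue_true: dict = field(
        default_factory=lambda: {"blue": 0.060, "red": 0.075, "white_fr": 0.080}
    )
    mech_la_alpha: float = np.log(0.015)
    mech_la_beta: float = 0.03
    seedling_leaf_area_m2: float = canopy.SEEDLING_LEAF_AREA_M2

    def __post_init__(self):
        if self.gradient.n_positions < 3:
            raise ValueError("n_positions must be >= 3")
        if self.gradient.min_ppfd >= self.gradient.max_ppfd:
            raise ValueError("gradient min_ppfd must be below max_ppfd")
        if self.mode not in ("phenomenological", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, t in self.traits.items():
            if t.sigma < 0 or not np.isfinite(t.alpha) or not np.isfinite(t.beta):
                raise ValueError(f"invalid parameters for trait {name!r}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return json.loads(json.dumps(d, default=float))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "seasons" in d:
            d["seasons"] = {k: SeasonConfig(**v) for k, v in d["seasons"].items()}
        if "gradient" in d:
            d["gradient"] = GradientConfig(**d["gradient"])
        if "treatments" in d:
            d["treatments"] = {
                k: TreatmentConfig(**v) for k, v in d["treatments"].items()
            }
        if "traits" in d:
            d["traits"] = {k: TraitParams(**v) for k, v in d["traits"].items()}
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class SimulatedExperiment:
    """A complete virtual experiment plus its ground truth."""

    config: SimulationConfig
    observations: pd.DataFrame
    environments: dict  # season -> DataFrame (ENVIRONMENT_COLUMNS)
    spectra: dict  # color -> Spectrum
    gradient: np.ndarray
    ground_truth: dict


# ---------------------------------------------------------------------------
# lamp spectra (synthetic templates emulating narrow-band LED lamps)
# ---------------------------------------------------------------------------

def _gaussian(wl, center, width):
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def lamp_spectrum(color: str, r_fr_target: float = 0.1) -> Spectrum:
    """Synthetic spectral template for one LED treatment.

    Narrow Gaussian emission bands: blue 440+470 nm, red 660 nm; the
    white+far-red lamp combines a flat white continuum (400-700 nm) with a
    730 nm far-red band scaled so the red:far-red ratio equals
    ``r_fr_target`` (0.1 by default).  All templates are normalised to unit
    PPFD over 400-700 nm, so scaling by a plant's dose gives its spectral
    photon flux.
    """
    wl = np.arange(350.0, 851.0, 1.0)
    if color == "blue":
        flux = _gaussian(wl, 440, 10) + 0.8 * _gaussian(wl, 470, 10)
    elif color == "red":
        flux = _gaussian(wl, 660, 10)
    elif color == "white_fr":
        white = np.clip((wl - 400) / 5, 0, 1) * np.clip((700 - wl) / 5, 0, 1)
        fr_unit = _gaussian(wl, 730, 10)
        base = Spectrum(wl, white)
        red = photometry.integrate_band(base, *photometry.RED_BAND).value
        fr_band_unit = photometry.integrate_band(
            Spectrum(wl, fr_unit), *photometry.FARRED_BAND
        ).value
        amp = red / (r_fr_target * fr_band_unit)
        flux = white + amp * fr_unit
    else:
        raise ValueError(f"unknown light color {color!r}")
    spec = Spectrum(wl, flux)
    ppfd700 = photometry.integrate_band(spec, 400, 700).value
    return spec.scaled(1.0 / ppfd700)


def ppfd800_factor(spectrum: Spectrum) -> float:
    """Ratio of a lamp's PPFD over 400-800 nm to its PPFD over 400-700 nm."""
    p800 = photometry.integrate_band(spectrum, 400, 800).value
    p700 = photometry.integrate_band(spectrum, 400, 700).value
    return p800 / p700


# ---------------------------------------------------------------------------
# environment and gradient
# ---------------------------------------------------------------------------

def simulate_environment(
    config: SimulationConfig, season: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Daily greenhouse environment for one season.

    Temperatures are Gaussian around the seasonal mean; natural DLIs are
    lognormal day-to-day multipliers normalised to mean one over the
    period, so the realised period-mean DLI equals the configured seasonal
    mean exactly (the seasonal mean is an observed quantity, and the
    simulation conditions on it).  Setting both variabilities to zero gives
    constant days.
    """
    sc = config.seasons[season]
    n = sc.days_to_final
    temps = sc.mean_temp_C + (
        rng.normal(0.0, sc.temp_sd_C, n) if sc.temp_sd_C > 0 else np.zeros(n)
    )
    if sc.dli_cv > 0:
        s_log = np.sqrt(np.log1p(sc.dli_cv**2))
        mult = np.exp(rng.normal(0.0, s_log, n))
        mult /= mult.mean()
    else:
        mult = np.ones(n)
    dli700 = sc.mean_natural_dli_700 * mult
    return pd.DataFrame(
        {
            "day": np.arange(1, n + 1),
            "mean_temp_C": temps,
            "natural_dli_700": dli700,
            "natural_dli_800": dli700 * config.natural_800_factor,
            "photoperiod_h": config.photoperiod_h,
        }
    )


def simulate_gradient(config: SimulationConfig) -> np.ndarray:
    """Strictly decreasing supplemental PPFD per gradient position."""
    g = config.gradient
    n = g.n_positions
    t = np.arange(n) / (n - 1)
    if g.shape == "exponential":
        doses = g.max_ppfd * (g.min_ppfd / g.max_ppfd) ** t
    elif g.shape == "linear":
        doses = g.max_ppfd + (g.min_ppfd - g.max_ppfd) * t
    elif g.shape == "inverse_square":
        a = np.sqrt(g.max_ppfd / g.min_ppfd) - 1.0
        doses = g.max_ppfd / (1.0 + a * t) ** 2
    else:
        raise ValueError(f"unknown gradient shape {g.shape!r}")
    return doses


# ---------------------------------------------------------------------------
# plants
# ---------------------------------------------------------------------------

def _assemble_block(config, color, season, rep, harvest, doses, traits_values, rng):
    """Build observation rows for one treatment cell from trait components."""
    n = len(doses)
    leaf_dw = traits_values["leaf_dw_g"]
    stem_dw = traits_values["stem_dw_g"]
    leaf_area = traits_values["leaf_area_m2"]
    hyp = traits_values["hypocotyl_mm"]
    epi = traits_values["epicotyl_mm"]
    inter = traits_values["internode_mm"]
    dmc = config.dmc_mean * np.exp(
        rng.normal(0.0, config.dmc_sigma, n) if config.dmc_sigma > 0 else np.zeros(n)
    )
    leaf_fw = leaf_dw / dmc
    stem_fw = stem_dw / dmc
    return pd.DataFrame(
        {
            "plant_id": [
                f"{color}_{season}_r{rep}_{harvest[:3]}_{p:03d}" for p in range(n)
            ],
            "treatment": color,
            "season": season,
            "replication": rep,
            "harvest": harvest,
            "position": np.arange(n),
            "dose_ppfd700": doses,
            "leaf_fw_g": leaf_fw,
            "stem_fw_g": stem_fw,
            "shoot_fw_g": leaf_fw + stem_fw,
            "leaf_dw_g": leaf_dw,
            "stem_dw_g": stem_dw,
            "shoot_dw_g": leaf_dw + stem_dw,
            "leaf_area_m2": leaf_area,
            "hypocotyl_mm": hyp,
            "epicotyl_mm": epi,
            "internode_mm": inter,
            "plant_height_mm": hyp + epi + inter,
            "lma_g_m2": leaf_dw / leaf_area,
            "stem_leaf_ratio": stem_dw / leaf_dw,
        }
    )


def _phenomenological_traits(config, color, season, harvest, doses, rep_effects, rng):
    root = np.sqrt(doses)
    out = {}
    for name, tp in config.traits.items():
        mean_log = tp.level(season, harvest) + tp.slope(color, season) * root
        mean_log = mean_log + rep_effects[name]
        noise = rng.normal(0.0, tp.sigma, len(doses)) if tp.sigma > 0 else 0.0
        out[name] = np.exp(mean_log + noise)
    return out


def _mechanistic_traits(config, color, season, harvest, doses, env, harvest_day):
    """Noise-free mechanistic components for one treatment cell.

    Leaf area is exponential in thermal time, reaching a dose-dependent
    target at the final harvest; dry weight equals the configured true LUE
    times the Beer-Lambert light absorbed up to the harvest day (PAR band).
    """
    tt = canopy.thermal_time(env["mean_temp_C"].to_numpy()).cumulative
    tt_final = tt[-1]
    la0 = config.seedling_leaf_area_m2
    la_target = np.exp(config.mech_la_alpha + config.mech_la_beta * np.sqrt(doses))
    growth = (np.log(la_target) - np.log(la0)) / tt_final  # per degCd, per plant

    days = np.arange(1, harvest_day + 1)
    la_daily = la0 * np.exp(np.outer(tt[days - 1], growth))  # (day, plant)
    suppl_dli = doses * config.photoperiod_h * 3600e-6
    incident = (
        env["natural_dli_700"].to_numpy()[days - 1, None] + suppl_dli[None, :]
    ) * photometry.ENERGY_PER_MOL_PAR
    q_daily = canopy.daily_absorbed_light(
        incident, la_daily / canopy.GROUND_AREA_M2
    )
    q_total = q_daily.sum(axis=0)
    shoot_dw = config.lue_true[color] * q_total

    leaf_dw = 0.7 * shoot_dw
    stem_dw = 0.3 * shoot_dw
    leaf_area = la0 * np.exp(tt[harvest_day - 1] * growth)
    n = len(doses)
    return {
        "leaf_dw_g": leaf_dw,
        "stem_dw_g": stem_dw,
        "leaf_area_m2": leaf_area,
        "hypocotyl_mm": np.full(n, 22.0),
        "epicotyl_mm": 14.0 * np.exp(0.02 * np.sqrt(doses)),
        "internode_mm": 55.0 * np.exp(0.03 * np.sqrt(doses)),
    }, q_total


def simulate_plants(config: SimulationConfig, seed: int | None = None) -> SimulatedExperiment:
    """Generate a full virtual experiment under the configured design."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    doses = simulate_gradient(config)
    environments = {s: simulate_environment(config, s, rng) for s in config.seasons}
    spectra = {c: lamp_spectrum(c) for c in config.treatments}

    mechanistic = config.mode == "mechanistic"
    blocks = []
    truth_q = {}
    for season in config.seasons:
        env = environments[season]
        sc = config.seasons[season]
        for rep in range(1, config.n_replications + 1):
            rep_effects = {
                name: (rng.normal(0.0, config.sigma_rep) if config.sigma_rep > 0 else 0.0)
                for name in config.traits
            }
            for color in config.treatments:
                for harvest in HARVESTS:
                    if mechanistic:
                        harvest_day = (
                            sc.days_to_intermediate
                            if harvest == "intermediate"
                            else sc.days_to_final
                        )
                        values, q_total = _mechanistic_traits(
                            config, color, season, harvest, doses, env, harvest_day
                        )
                        truth_q[f"{color}:{season}:{rep}:{harvest}"] = q_total.tolist()
                    else:
                        values = _phenomenological_traits(
                            config, color, season, harvest, doses, rep_effects, rng
                        )
                    blocks.append(
                        _assemble_block(
                            config, color, season, rep, harvest, doses, values, rng
                        )
                    )
    observations = pd.concat(blocks, ignore_index=True)

    ground_truth = {
        "mode": config.mode,
        "gradient_doses": doses.tolist(),
        "traits": {
            name: {
                "sigma": tp.sigma,
                "slopes": {
                    c: {s: tp.slope(c, s) for s in config.seasons}
                    for c in config.treatments
                },
                "levels": {
                    s: {h: tp.level(s, h) for h in HARVESTS} for s in config.seasons
                },
            }
            for name, tp in config.traits.items()
        },
    }
    if mechanistic:
        ground_truth["lue_true"] = dict(config.lue_true)
        ground_truth["q_total"] = truth_q

    return SimulatedExperiment(
        config=config,
        observations=observations,
        environments=environments,
        spectra=spectra,
        gradient=doses,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

def write_experiment(experiment: SimulatedExperiment, directory: str | Path) -> None:
    """Write an experiment as plain CSV/YAML/JSON files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    experiment.observations.to_csv(d / "observations.csv", index=False)
    for season, env in experiment.environments.items():
        photometry.write_environment_csv(env, d / f"environment_{season}.csv")
    for color, spec in experiment.spectra.items():
        spec.to_csv(d / f"spectrum_{color}.csv")
    experiment.config.to_yaml(d / "config.yaml")
    (d / "ground_truth.json").write_text(json.dumps(experiment.ground_truth, indent=1))


def read_experiment(directory: str | Path) -> SimulatedExperiment:
    """Read an experiment directory written by :func:`write_experiment`.

    The ground-truth and config files are optional (the real-data path);
    observation and environment tables are validated against their schemas
    and a :class:`ValueError` names any offending columns.
    """
    d = Path(directory)
    obs_path = d / "observations.csv"
    if not obs_path.exists():
        raise FileNotFoundError(f"no observations.csv in {d}")
    observations = pd.read_csv(obs_path)
    missing = set(OBSERVATION_COLUMNS) - set(observations.columns)
    if missing:
        raise ValueError(
            f"observations.csv missing required columns: {sorted(missing)}"
        )

    config = None
    if (d / "config.yaml").exists():
        config = SimulationConfig.from_yaml(d / "config.yaml")

    environments = {}
    for path in sorted(d.glob("environment_*.csv")):
        season = path.stem.removeprefix("environment_")
        environments[season] = photometry.read_environment_csv(path)
    if not environments:
        raise ValueError(f"no environment_<season>.csv tables in {d}")

    spectra = {}
    for path in sorted(d.glob("spectrum_*.csv")):
        spectra[path.stem.removeprefix("spectrum_")] = Spectrum.from_csv(path)

    ground_truth = {}
    if (d / "ground_truth.json").exists():
        ground_truth = json.loads((d / "ground_truth.json").read_text())

    doses = np.sort(observations["dose_ppfd700"].unique())[::-1]
    return SimulatedExperiment(
        config=config,
        observations=observations,
        environments=environments,
        spectra=spectra,
        gradient=doses,
        ground_truth=ground_truth,
    )
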