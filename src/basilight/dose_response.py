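"""Trait-vs-supplemental-dose curve fitting along the light gradient.

Each replicate of each light-color treatment exposes ~120 plants to a
continuous gradient of supplemental PPFD, so a dose-response curve can be
fitted within a single treatment.  Responses are log transformed and the
dose square-root transformed before fitting (variance stabilisation and
approximate linearity), giving the working model

    ln(trait) = intercept + slope * sqrt(dose) + error.

The slope is the treatment's *efficiency* (relative trait gain per unit
root-dose) and the intercept its *magnitude* (log trait level without
supplemental light).  Where a trait saturates, a monomolecular curve

    ln(trait) = A - B * exp(-r * sqrt(dose)),   r > 0

is fitted on the same transformed scale and compared to the straight line
with an extra-sum-of-squares F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "DoseResponseFit",
    "ModelComparison",
    "fit_linear",
    "fit_monomolecular",
    "compare_models",
    "fit_dose_response",
    "efficiency_table",
    "FIT_COLUMNS",
]

FIT_COLUMNS = [
    "trait",
    "season",
    "color",
    "replication",
    "harvest",
    "model",
    "slope",
    "intercept",
    "A",
    "B",
    "r",
    "rss",
    "n",
    "f_stat",
    "p_value",
    "n_excluded",
    "reason",
]


@dataclass
class DoseResponseFit:
    """A fitted trait-vs-dose curve on the (ln trait, sqrt dose) scale."""

    model: str  # "linear" | "monomolecular"
    trait: str
    slope: Optional[float]
    intercept: Optional[float]
    A: Optional[float]
    B: Optional[float]
    r: Optional[float]
    rss: float
    df: int
    n: int
    dose_range: tuple[float, float]
    n_excluded: int = 0
    f_stat: Optional[float] = None
    p_value: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def predict_log(self, dose):
        """ln(trait) predicted at a dose (natural units, not sqrt)."""
        x = np.sqrt(np.asarray(dose, dtype=float))
        if self.model == "linear":
            return self.intercept + self.slope * x
        return self.A - self.B * np.exp(-self.r * x)

    def predict(self, dose):
        """Trait predicted at a dose, back-transformed to the natural scale."""
        return np.exp(self.predict_log(dose))


@dataclass(frozen=True)
class ModelComparison:
    """Extra-sum-of-squares comparison of the two candidate curves."""

    f_stat: float
    p_value: float
    selected: str  # "linear" | "monomolecular"


def _design_vectors(observations: pd.DataFrame, trait: str, dose_col: str):
    """Transformed (x, y) vectors with non-positive trait values excluded."""
    if trait not in observations.columns:
        raise KeyError(f"trait column {trait!r} not in observations")
    if dose_col not in observations.columns:
        raise KeyError(f"dose column {dose_col!r} not in observations")
    dose = observations[dose_col].to_numpy(dtype=float)
    y_raw = observations[trait].to_numpy(dtype=float)
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    keep = np.isfinite(y_raw) & (y_raw > 0)
    n_excluded = int((~keep).sum())
    dose, y_raw = dose[keep], y_raw[keep]
    return np.sqrt(dose), np.log(y_raw), dose, n_excluded


def fit_linear(
    observations: pd.DataFrame,
    trait: str,
    dose_col: str = "dose_ppfd700",
) -> DoseResponseFit:
    """OLS of ln(trait) on sqrt(dose).

    Plants with non-positive trait values (e.g. no internodes formed yet)
    are excluded; the count is carried on the fit.  Raises if fewer than
    three usable observations remain or all doses coincide.
    """
    x, y, dose, n_excluded = _design_vectors(observations, trait, dose_col)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 usable observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("all doses identical; slope is not estimable")
    X = np.column_stack([np.ones(n), x])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design; slope is not estimable")
    resid = y - X @ beta
    return DoseResponseFit(
        model="linear",
        trait=trait,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        A=None,
        B=None,
        r=None,
        rss=float(resid @ resid),
        df=n - 2,
        n=n,
        dose_range=(float(dose.min()), float(dose.max())),
        n_excluded=n_excluded,
    )


def _rss_at_r(r: float, x: np.ndarray, y: np.ndarray):
    """Profile RSS: with r fixed, A and B solve by OLS on [1, exp(-r x)]."""
    u = np.exp(-r * x)
    X = np.column_stack([np.ones_like(x), u])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def fit_monomolecular(
    observations: pd.DataFrame,
    trait: str,
    dose_col: str = "dose_ppfd700",
    n_grid: int = 60,
) -> DoseResponseFit:
    """Least squares for ln(trait) = A - B exp(-r sqrt(dose)), r > 0.

    The rate r is profiled: for each candidate r the remaining parameters
    are linear and solved exactly, so the search is a deterministic
    one-dimensional minimisation (log-spaced grid plus bounded polish)
    with no dependence on starting values.  As r -> 0 the family approaches
    the straight line, so the returned RSS never exceeds the linear fit's
    RSS by more than numerical tolerance.
    """
    x, y, dose, n_excluded = _design_vectors(observations, trait, dose_col)
    n = x.size
    if n < 4:
        raise ValueError(f"need >= 4 usable observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("all doses identical; curve is not estimable")

    # grid scaled to the dose range so exp(-r x) sweeps from near-linear
    # (r*max(x) << 1) to a step at low dose (r*max(x) >> 1)
    scale = float(np.max(x))
    grid = np.geomspace(1e-5, 50.0, n_grid) / scale
    rss_grid = np.array([_rss_at_r(r, x, y)[0] for r in grid])
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda r: _rss_at_r(r, x, y)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    r_best = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])
    rss, beta = _rss_at_r(r_best, x, y)
    return DoseResponseFit(
        model="monomolecular",
        trait=trait,
        slope=None,
        intercept=None,
        A=float(beta[0]),
        B=float(-beta[1]),
        r=r_best,
        rss=rss,
        df=n - 3,
        n=n,
        dose_range=(float(dose.min()), float(dose.max())),
        n_excluded=n_excluded,
    )


def compare_models(
    linear_fit: DoseResponseFit,
    mono_fit: DoseResponseFit,
    alpha: float = 0.05,
) -> ModelComparison:
    """Extra-sum-of-squares F-test of the saturating curve against the line.

    F = (RSS_lin - RSS_mono) / (RSS_mono / (n - 3)) with 1 numerator and
    n - 3 denominator degrees of freedom; the monomolecular curve is
    selected when p < alpha.  Both fits must come from the same data.
    """
    if linear_fit.n != mono_fit.n:
        raise ValueError("fits are not on identical observations")
    n = linear_fit.n
    rss_lin, rss_mono = linear_fit.rss, mono_fit.rss
    # the straight line is only the r->0 limit of the saturating family, so
    # a well-converged mono fit can sit a hair above the linear RSS
    tol = 1e-4 * max(rss_lin, 1e-300)
    if rss_mono > rss_lin + tol:
        raise RuntimeError(
            "monomolecular RSS exceeds linear RSS beyond tolerance; "
            f"optimization failed (rss_mono={rss_mono:g}, rss_lin={rss_lin:g})"
        )
    rss_mono = min(rss_mono, rss_lin)
    if rss_mono == 0.0:
        # perfect saturating fit; infinitely strong evidence
        f_stat, p = np.inf, 0.0
    else:
        f_stat = (rss_lin - rss_mono) / (rss_mono / (n - 3))
        p = float(stats.f.sf(f_stat, 1, n - 3))
    selected = "monomolecular" if p < alpha else "linear"
    return ModelComparison(f_stat=float(f_stat), p_value=p, selected=selected)


def fit_dose_response(
    observations: pd.DataFrame,
    trait: str,
    dose_col: str = "dose_ppfd700",
    alpha: float = 0.05,
) -> tuple[DoseResponseFit, DoseResponseFit, ModelComparison]:
    """Fit both candidate curves and compare them.

    Returns ``(linear_fit, mono_fit, comparison)`` with the comparison's
    F statistic and p-value copied onto both fits.
    """
    lin = fit_linear(observations, trait, dose_col)
    mono = fit_monomolecular(observations, trait, dose_col)
    cmp_ = compare_models(lin, mono, alpha=alpha)
    lin.f_stat = mono.f_stat = cmp_.f_stat
    lin.p_value = mono.p_value = cmp_.p_value
    return lin, mono, cmp_


def efficiency_table(fits) -> pd.DataFrame:
    """Assemble stage-1 results into the long table stage 2 consumes.

    Parameters
    ----------
    fits
        Iterable of :class:`DoseResponseFit` (with ``meta`` carrying at
        least ``color, season, replication, harvest``) or of
        ``(meta_dict, exception)`` pairs for cells whose fit failed.
        Failed cells yield rows with missing slope/intercept and the
        failure reason — never a silent drop.

    Returns
    -------
    pandas.DataFrame with :data:`FIT_COLUMNS`.
    """
    rows = []
    for item in fits:
        if isinstance(item, DoseResponseFit):
            f = item
            rows.append(
                {
                    "trait": f.trait,
                    **{k: f.meta.get(k) for k in ("season", "color", "replication", "harvest")},
                    "model": f.model,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "A": f.A,
                    "B": f.B,
                    "r": f.r,
                    "rss": f.rss,
                    "n": f.n,
                    "f_stat": f.f_stat,
                    "p_value": f.p_value,
                    "n_excluded": f.n_excluded,
                    "reason": "",
                }
            )
        else:
            meta, err = item
            rows.append(
                {
                    "trait": meta.get("trait"),
                    **{k: meta.get(k) for k in ("season", "color", "replication", "harvest")},
                    "model": None,
                    "slope": np.nan,
                    "intercept": np.nan,
                    "A": np.nan,
                    "B": np.nan,
                    "r": np.nan,
                    "rss": np.nan,
                    "n": 0,
                    "f_stat": np.nan,
                    "p_value": np.nan,
                    "n_excluded": 0,
                    "reason": str(err),
                }
            )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)
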