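"""Second-stage analysis of dose-response coefficients.

Stage 1 reduces every replicate x color x season x harvest cell to a slope
(efficiency) and an intercept (magnitude).  Stage 2 asks whether those
coefficients differ between light colors, seasons and harvests, with the
model

    y = color + season + harvest + all two-way interactions
        + RS + RSC + RSCH + e,

where RS, RSC and RSCH are random intercepts for the randomization units:
replication within season, replication within season by color, and
replication within season by color by harvest.  With one coefficient per
cell (the experimental design analysed here) RSCH is confounded with the
residual e, so the design is the classic split-split plot: season is tested
in the replication-within-season stratum, color and color:season in the
replication-by-color stratum, and harvest terms against the residual.  For
balanced complete data those stratum F-tests are exact (they coincide with
what REML plus Satterthwaite degrees of freedom produce); variance
components are additionally estimated by REML.  Unbalanced tables fall back
to REML with Wald chi-square tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixedModelResult",
    "fit_efficiency_model",
    "marginal_means",
    "compact_letters",
]

FACTORS = ("color", "season", "harvest")


@dataclass
class MixedModelResult:
    """ANOVA table, variance components and the data behind them."""

    anova: pd.DataFrame  # term, df_num, df_den, F, p
    varcomp: dict  # rs, rsc, rsch, residual (rsch confounded -> NaN)
    method: str  # "exact-strata" | "reml-wald"
    data: pd.DataFrame = field(repr=False)
    strata: dict = field(default_factory=dict, repr=False)  # error MS/df per stratum
    notes: list = field(default_factory=list)

    def p_value(self, term: str) -> float:
        row = self.anova.loc[self.anova["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in ANOVA table")
        return float(row["p"].iloc[0])


def _safe_f(ss_num, df_num, ms_err, df_err):
    """F and p with the all-equal degenerate case mapped to (0, 1)."""
    if df_num <= 0 or df_err <= 0:
        return np.nan, np.nan
    ms_num = ss_num / df_num
    if ms_err <= 0:
        if ms_num <= 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f = ms_num / ms_err
    return float(f), float(stats.f.sf(f, df_num, df_err))


def _check_records(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = set(FACTORS) | {"replication", value_col}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    df = records.dropna(subset=[value_col]).copy()
    if df["replication"].nunique() < 2:
        raise ValueError(
            "unreplicated design: need >= 2 replications per season to "
            "separate the RS stratum from the season effect"
        )
    for f in FACTORS:
        if df[f].nunique() < 1:
            raise ValueError(f"factor {f} has no levels")
    return df


def _is_balanced(df: pd.DataFrame, value_col: str) -> bool:
    counts = df.groupby(["replication", *FACTORS], observed=True)[value_col].count()
    full = (
        df["replication"].nunique()
        * df["color"].nunique()
        * df["season"].nunique()
        * df["harvest"].nunique()
    )
    return len(counts) == full and counts.min() == 1 and counts.max() == 1


def _exact_strata_anova(df: pd.DataFrame, value_col: str):
    reps = np.sort(df["replication"].unique())
    seasons = np.sort(df["season"].astype(str).unique())
    colors = np.sort(df["color"].astype(str).unique())
    harvests = np.sort(df["harvest"].astype(str).unique())
    R, S, C, H = len(reps), len(seasons), len(colors), len(harvests)

    idx = {
        "replication": {v: i for i, v in enumerate(reps)},
        "season": {v: i for i, v in enumerate(seasons)},
        "color": {v: i for i, v in enumerate(colors)},
        "harvest": {v: i for i, v in enumerate(harvests)},
    }
    Y = np.full((R, S, C, H), np.nan)
    for row in df.itertuples(index=False):
        d = row._asdict()
        Y[
            idx["replication"][d["replication"]],
            idx["season"][str(d["season"])],
            idx["color"][str(d["color"])],
            idx["harvest"][str(d["harvest"])],
        ] = d[value_col]

    m = Y.mean()
    m_s = Y.mean(axis=(0, 2, 3))
    m_c = Y.mean(axis=(0, 1, 3))
    m_h = Y.mean(axis=(0, 1, 2))
    m_rs = Y.mean(axis=(2, 3))
    m_cs = Y.mean(axis=(0, 3))  # (S, C)
    m_rsc = Y.mean(axis=3)  # (R, S, C)
    m_ch = Y.mean(axis=(0, 1))  # (C, H)
    m_sh = Y.mean(axis=(0, 2))  # (S, H)

    ss_s = R * C * H * np.sum((m_s - m) ** 2)
    ss_err_rs = C * H * np.sum((m_rs - m_s[None, :]) ** 2)
    ss_c = R * S * H * np.sum((m_c - m) ** 2)
    ss_cs = R * H * np.sum((m_cs - m_s[:, None] - m_c[None, :] + m) ** 2)
    ss_err_rsc = H * np.sum(
        (m_rsc - m_rs[:, :, None] - m_cs[None, :, :] + m_s[None, :, None]) ** 2
    )
    ss_h = R * S * C * np.sum((m_h - m) ** 2)
    ss_ch = R * S * np.sum((m_ch - m_c[:, None] - m_h[None, :] + m) ** 2)
    ss_sh = R * C * np.sum((m_sh - m_s[:, None] - m_h[None, :] + m) ** 2)
    ss_tot = np.sum((Y - m) ** 2)
    ss_resid = ss_tot - (
        ss_s + ss_err_rs + ss_c + ss_cs + ss_err_rsc + ss_h + ss_ch + ss_sh
    )
    ss_resid = max(float(ss_resid), 0.0)

    # constant response: every sum of squares is numerical dust
    if ss_tot <= (1e-9 * (1.0 + abs(m))) ** 2:
        ss_s = ss_err_rs = ss_c = ss_cs = ss_err_rsc = 0.0
        ss_h = ss_ch = ss_sh = ss_resid = 0.0

    df_s, df_err_rs = S - 1, S * (R - 1)
    df_c, df_cs = C - 1, (C - 1) * (S - 1)
    df_err_rsc = S * (R - 1) * (C - 1)
    df_h, df_ch, df_sh = H - 1, (C - 1) * (H - 1), (S - 1) * (H - 1)
    df_resid = (
        R * S * C * H
        - 1
        - (df_s + df_err_rs + df_c + df_cs + df_err_rsc + df_h + df_ch + df_sh)
    )

    ms_err_rs = ss_err_rs / df_err_rs if df_err_rs > 0 else np.nan
    ms_err_rsc = ss_err_rsc / df_err_rsc if df_err_rsc > 0 else np.nan
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    rows = []
    for term, ss, dnum, ms_err, derr in [
        ("color", ss_c, df_c, ms_err_rsc, df_err_rsc),
        ("season", ss_s, df_s, ms_err_rs, df_err_rs),
        ("harvest", ss_h, df_h, ms_resid, df_resid),
        ("color:season", ss_cs, df_cs, ms_err_rsc, df_err_rsc),
        ("color:harvest", ss_ch, df_ch, ms_resid, df_resid),
        ("season:harvest", ss_sh, df_sh, ms_resid, df_resid),
    ]:
        f, p = _safe_f(ss, dnum, ms_err, derr)
        rows.append(
            {"term": term, "df_num": dnum, "df_den": derr, "F": f, "p": p}
        )
    anova = pd.DataFrame(rows)

    strata = {
        "season": (float(ms_err_rs), int(df_err_rs)),
        "color": (float(ms_err_rsc), int(df_err_rsc)),
        "harvest": (float(ms_resid), int(df_resid)),
    }
    return anova, strata


def _reml_varcomp(df: pd.DataFrame, value_col: str, notes: list) -> dict:
    import statsmodels.formula.api as smf

    d = df.copy()
    d["rs_unit"] = (
        d["replication"].astype(str) + ":" + d["season"].astype(str)
    )
    d["rsc_unit"] = d["rs_unit"] + ":" + d["color"].astype(str)
    d = d.rename(columns={value_col: "_y"})
    formula = (
        "_y ~ C(color) + C(season) + C(harvest) + C(color):C(season)"
        " + C(color):C(harvest) + C(season):C(harvest)"
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                d,
                groups=d["rs_unit"],
                re_formula="1",
                vc_formula={"rsc": "0 + C(rsc_unit)"},
            )
            res = model.fit(reml=True)
        rs = float(res.cov_re.iloc[0, 0])
        rsc = float(res.vcomp[0]) if len(res.vcomp) else np.nan
        resid = float(res.scale)
    except Exception as err:  # pragma: no cover - numerical edge cases
        notes.append(f"REML variance-component fit failed: {err}")
        return {"rs": np.nan, "rsc": np.nan, "rsch": np.nan, "residual": np.nan}
    notes.append(
        "RSCH variance is confounded with the residual (one record per "
        "replication:season:color:harvest cell) and reported as part of it"
    )
    return {"rs": rs, "rsc": rsc, "rsch": np.nan, "residual": resid}


def _reml_wald_anova(df: pd.DataFrame, value_col: str, notes: list):
    import statsmodels.formula.api as smf

    d = df.copy()
    d["rs_unit"] = d["replication"].astype(str) + ":" + d["season"].astype(str)
    d["rsc_unit"] = d["rs_unit"] + ":" + d["color"].astype(str)
    d = d.rename(columns={value_col: "_y"})
    terms = {
        "color": "C(color)",
        "season": "C(season)",
        "harvest": "C(harvest)",
        "color:season": "C(color):C(season)",
        "color:harvest": "C(color):C(harvest)",
        "season:harvest": "C(season):C(harvest)",
    }
    formula = "_y ~ " + " + ".join(terms.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            d,
            groups=d["rs_unit"],
            re_formula="1",
            vc_formula={"rsc": "0 + C(rsc_unit)"},
        )
        res = model.fit(reml=True)
        wald = res.wald_test_terms(scalar=True)
    rows = []
    table = wald.table
    for term, patsy_name in terms.items():
        if patsy_name in table.index:
            chi2 = float(table.loc[patsy_name, "statistic"])
            dfn = int(table.loc[patsy_name, "df_constraint"])
            rows.append(
                {
                    "term": term,
                    "df_num": dfn,
                    "df_den": np.inf,
                    "F": chi2 / dfn if dfn else np.nan,
                    "p": float(table.loc[patsy_name, "pvalue"]),
                }
            )
    notes.append("unbalanced records: REML fit with Wald chi-square tests")
    return pd.DataFrame(rows)


def fit_efficiency_model(
    records: pd.DataFrame,
    value_col: str = "value",
    compute_varcomp: bool = True,
) -> MixedModelResult:
    """Fit the two-stage efficiency model to coefficient records.

    Parameters
    ----------
    records
        One row per replication x color x season x harvest cell with the
        stage-1 coefficient in ``value_col``; NaN values mark failed cells
        and are dropped (the fit then uses the unbalanced path).
    compute_varcomp
        Estimate RS/RSC variance components by REML (statsmodels MixedLM).
        Skipping this makes repeated fits (permutation loops) much faster;
        the F-tests do not depend on it for balanced data.

    Returns
    -------
    MixedModelResult
        With exact split-split-plot stratum F-tests for balanced complete
        tables, or REML Wald tests otherwise.
    """
    df = _check_records(records, value_col)
    notes: list = []
    if _is_balanced(df, value_col):
        anova, strata = _exact_strata_anova(df, value_col)
        method = "exact-strata"
    else:
        anova = _reml_wald_anova(df, value_col, notes)
        strata = {}
        method = "reml-wald"
    varcomp = (
        _reml_varcomp(df, value_col, notes)
        if compute_varcomp
        else {"rs": np.nan, "rsc": np.nan, "rsch": np.nan, "residual": np.nan}
    )
    return MixedModelResult(
        anova=anova,
        varcomp=varcomp,
        method=method,
        data=df,
        strata=strata,
        notes=notes,
    )


def compact_letters(levels, sig_pairs) -> dict:
    """Compact letter display by the insert-and-absorb algorithm.

    ``levels`` are ordered (typically by descending mean); ``sig_pairs`` is
    an iterable of 2-tuples of levels that differ significantly.  Levels
    sharing a letter do not differ.
    """
    levels = list(levels)
    columns: list[set] = [set(levels)]
    for a, b in sig_pairs:
        new_cols = []
        for col in columns:
            if a in col and b in col:
                new_cols.append(col - {a})
                new_cols.append(col - {b})
            else:
                new_cols.append(col)
        # absorb columns contained in another
        columns = [
            c
            for i, c in enumerate(new_cols)
            if c and not any(i != j and c < d for j, d in enumerate(new_cols))
        ]
        # drop duplicates
        uniq = []
        for c in columns:
            if c not in uniq:
                uniq.append(c)
        columns = uniq
    # order columns by the first (best-ranked) level they contain
    rank = {lv: i for i, lv in enumerate(levels)}
    columns.sort(key=lambda c: min(rank[lv] for lv in c))
    letters = {lv: "" for lv in levels}
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for lv in col:
            letters[lv] += ch
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def marginal_means(result: MixedModelResult, factor: str) -> pd.DataFrame:
    """Estimated marginal means per factor level with Tukey letter groups.

    For the balanced designs this package targets, the marginal means equal
    the raw level means and their standard errors come from the error
    stratum against which the factor is tested (replication-by-color mean
    square for color, replication-within-season for season, residual for
    harvest).  Pairwise comparisons use the studentized range (Tukey) at
    alpha = 0.05; levels sharing a letter do not differ.
    """
    if factor not in FACTORS:
        raise KeyError(f"factor must be one of {FACTORS}, got {factor!r}")
    df = result.data
    value_col = [c for c in df.columns if c == "value" or c == "_y"]
    vcol = value_col[0] if value_col else "value"
    means = df.groupby(factor, observed=True)[vcol].mean().sort_values(ascending=False)
    levels = list(means.index)
    n_per = len(df) / len(levels)

    if result.method == "exact-strata" and factor in result.strata:
        ms_err, df_err = result.strata[factor]
    else:
        # approximate: residual variance from the REML fit (or sample)
        ms_err = result.varcomp.get("residual", np.nan)
        if not np.isfinite(ms_err):
            ms_err = float(df[vcol].var())
        df_err = max(len(df) - len(levels), 1)

    se = np.sqrt(ms_err / n_per) if ms_err > 0 else 0.0
    k = len(levels)
    sig_pairs = []
    if k > 1 and ms_err > 0 and df_err > 0:
        for a, b in combinations(levels, 2):
            q = abs(means[a] - means[b]) / np.sqrt(ms_err / n_per)
            p = float(stats.studentized_range.sf(q, k, df_err))
            if p < 0.05:
                sig_pairs.append((a, b))
    letters = (
        compact_letters(levels, sig_pairs) if k > 1 else {levels[0]: "a"}
    )
    return pd.DataFrame(
        {
            "factor": factor,
            "level": levels,
            "emmean": [means[lv] for lv in levels],
            "se": se,
            "letter": [letters[lv] for lv in levels],
        }
    )
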