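import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from basilight.stage2 import (
    compact_letters,
    fit_efficiency_model,
    marginal_means,
)

COLORS = ("blue", "red", "white_fr")
SEASONS = ("late_winter", "mid_spring", "early_summer", "late_summer")
HARVESTS = ("intermediate", "final")


def design_frame(n_rep=2):
    rows = [
        {"color": c, "season": s, "harvest": h, "replication": r}
        for r in range(1, n_rep + 1)
        for s in SEASONS
        for c in COLORS
        for h in HARVESTS
    ]
    return pd.DataFrame(rows)


def simulate_records(rng, color_eff=None, season_eff=None, harvest_eff=None,
                     sigma=0.1, sigma_rs=0.0, sigma_rsc=0.0, n_rep=2):
    df = design_frame(n_rep)
    color_eff = color_eff or {c: 0.0 for c in COLORS}
    season_eff = season_eff or {s: 0.0 for s in SEASONS}
    harvest_eff = harvest_eff or {h: 0.0 for h in HARVESTS}
    rs = {
        (r, s): rng.normal(0, sigma_rs)
        for r in df["replication"].unique()
        for s in SEASONS
    }
    rsc = {
        (r, s, c): rng.normal(0, sigma_rsc)
        for r in df["replication"].unique()
        for s in SEASONS
        for c in COLORS
    }
    df["value"] = [
        color_eff[row.color]
        + season_eff[row.season]
        + harvest_eff[row.harvest]
        + rs[(row.replication, row.season)]
        + rsc[(row.replication, row.season, row.color)]
        + rng.normal(0, sigma)
        for row in df.itertuples()
    ]
    return df


class TestExactStrataAnova:
    def test_identical_values_give_f_zero_p_one(self):
        df = design_frame()
        df["value"] = 1.234
        res = fit_efficiency_model(df, compute_varcomp=False)
        assert (res.anova["F"] == 0).all()
        assert (res.anova["p"] == 1).all()

    def test_pure_color_effect_detected_without_interactions(self, rng):
        df = simulate_records(
            rng, color_eff={"blue": 0.0, "red": 0.3, "white_fr": 0.3}, sigma=0.02
        )
        res = fit_efficiency_model(df, compute_varcomp=False)
        assert res.method == "exact-strata"
        assert res.p_value("color") < 1e-4
        assert res.p_value("color:season") > 0.05
        assert res.p_value("color:harvest") > 0.05

    def test_split_plot_degrees_of_freedom(self, rng):
        res = fit_efficiency_model(simulate_records(rng), compute_varcomp=False)
        t = res.anova.set_index("term")
        assert (t.loc["color", "df_num"], t.loc["color", "df_den"]) == (2, 8)
        assert (t.loc["season", "df_num"], t.loc["season", "df_den"]) == (3, 4)
        assert (t.loc["harvest", "df_num"], t.loc["harvest", "df_den"]) == (1, 18)
        assert (t.loc["color:season", "df_num"], t.loc["color:season", "df_den"]) == (6, 8)

    def test_unreplicated_design_errors(self, rng):
        df = simulate_records(rng)
        with pytest.raises(ValueError, match="nreplicated|replication"):
            fit_efficiency_model(df[df["replication"] == 1], compute_varcomp=False)

    def test_missing_cell_uses_reml_fallback(self, rng):
        df = simulate_records(rng).drop(index=[0, 1])
        res = fit_efficiency_model(df, compute_varcomp=False)
        assert res.method == "reml-wald"
        assert set(res.anova["term"]) >= {"color", "season", "harvest"}

    def test_agrees_with_r_split_plot_aov(self, rng, tmp_path):
        """Independent oracle: base R aov with Error(rep:season/color) strata."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the stage-2 oracle")
        df = simulate_records(
            rng,
            color_eff={"blue": 0.0, "red": 0.1, "white_fr": 0.12},
            season_eff={s: v for s, v in zip(SEASONS, (0.0, 0.05, -0.1, 0.02))},
            harvest_eff={"intermediate": 0.0, "final": 0.04},
            sigma=0.08,
            sigma_rs=0.05,
            sigma_rsc=0.03,
        )
        csv = tmp_path / "records.csv"
        out = tmp_path / "anova.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            """
            args <- commandArgs(trailingOnly = TRUE)
            d <- read.csv(args[1])
            d$c <- factor(d$color); d$s <- factor(d$season); d$h <- factor(d$harvest)
            d$rs <- factor(paste(d$replication, d$season))
            m <- aov(value ~ c + s + h + c:s + c:h + s:h + Error(rs/c), data = d)
            sm <- summary(m)
            rows <- do.call(rbind, lapply(names(sm), function(nm) {
              tab <- as.data.frame(sm[[nm]][[1]])
              data.frame(term = trimws(rownames(tab)),
                         F = tab[["F value"]], p = tab[["Pr(>F)"]])
            }))
            write.csv(rows, args[2], row.names = FALSE)
            """
        )
        subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv), str(out)],
            check=True,
            capture_output=True,
        )
        r_tab = pd.read_csv(out).set_index("term")
        res = fit_efficiency_model(df, compute_varcomp=False)
        mine = res.anova.set_index("term")
        mapping = {
            "color": "c",
            "season": "s",
            "harvest": "h",
            "color:season": "c:s",
            "color:harvest": "c:h",
            "season:harvest": "s:h",
        }
        for term, rname in mapping.items():
            assert mine.loc[term, "F"] == pytest.approx(
                r_tab.loc[rname, "F"], rel=1e-6
            ), term
            assert mine.loc[term, "p"] == pytest.approx(
                r_tab.loc[rname, "p"], rel=1e-6
            ), term


class TestVarianceComponents:
    def test_vc_only_simulation_recovers_total_variance(self, rng):
        df = simulate_records(
            rng, sigma=0.1, sigma_rs=0.3, sigma_rsc=0.2, n_rep=6
        )
        res = fit_efficiency_model(df)
        vc = res.varcomp
        assert vc["rs"] >= 0 and vc["rsc"] >= 0 and vc["residual"] > 0
        total = df["value"].var()
        explained = vc["rs"] + vc["rsc"] + vc["residual"]
        assert explained == pytest.approx(total, rel=0.35)


class TestMarginalMeans:
    def test_balanced_means_equal_raw_level_means(self, rng):
        df = simulate_records(rng, color_eff={"blue": 0.0, "red": 0.2, "white_fr": 0.4})
        res = fit_efficiency_model(df, compute_varcomp=False)
        mm = marginal_means(res, "color").set_index("level")
        raw = df.groupby("color")["value"].mean()
        for level in raw.index:
            assert mm.loc[level, "emmean"] == pytest.approx(raw[level], abs=1e-12)

    def test_letters_separate_extremes_overlap_middle(self):
        # deterministic construction: color means 0 / 0.1 / 0.2 with a
        # rep-by-color perturbation (+-e) that sets the color-stratum error
        # mean square to 4e^2 exactly.  With e = 0.08 the Tukey studentized
        # range separates the extremes (q = 5) but not adjacent levels
        # (q = 2.5 < q_crit(3, 8) ~ 4.04).
        eff = {"blue": 0.0, "red": 0.1, "white_fr": 0.2}
        e = 0.08
        df = design_frame()
        pattern = {"blue": e, "red": 0.0, "white_fr": -e}
        df["value"] = [
            eff[row.color] + (1 if row.replication == 1 else -1) * pattern[row.color]
            for row in df.itertuples()
        ]
        res = fit_efficiency_model(df, compute_varcomp=False)
        mm = marginal_means(res, "color").set_index("level")
        assert mm.loc["white_fr", "letter"] == "a"
        assert mm.loc["red", "letter"] == "ab"
        assert mm.loc["blue", "letter"] == "b"

    def test_unknown_factor_errors(self, rng):
        res = fit_efficiency_model(simulate_records(rng), compute_varcomp=False)
        with pytest.raises(KeyError):
            marginal_means(res, "bench")


class TestCompactLetters:
    def test_no_differences_single_letter(self):
        assert compact_letters(["a1", "a2", "a3"], []) == {
            "a1": "a",
            "a2": "a",
            "a3": "a",
        }

    def test_chain_pattern(self):
        # high differs from low; middle differs from neither
        letters = compact_letters(["high", "mid", "low"], [("high", "low")])
        assert letters == {"high": "a", "mid": "ab", "low": "b"}

    def test_all_different(self):
        letters = compact_letters(
            ["x", "y", "z"], [("x", "y"), ("x", "z"), ("y", "z")]
        )
        assert sorted(letters.values()) == ["a", "b", "c"]
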