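import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from tripfidelity.errors import ConfigError
from tripfidelity.models import (
    DESIGNS,
    fit_lmm,
    lrt_random_effect,
    run_analysis,
    vif,
)


def simulate_comparison_table(
    rng,
    n_birds=40,
    pairs_per_bird=3,
    delta=0.8,
    intercept=2.5,
    sd_bird=0.4,
    sd_resid=0.5,
    slope_dstart=0.0,
):
    """Comparison-style table drawn from the fitted model family:
    sqrt(response) = b0 + delta*[between] + slope*z(dstart) + u_bird + e."""
    rows = []
    for b in range(n_birds):
        u = rng.normal(0, sd_bird)
        for k in range(pairs_per_bird):
            for ctype, x in (("within_individual", 0.0), ("between_individual", 1.0)):
                dstart = rng.uniform(0, 2000)
                rows.append(
                    dict(bird_a=f"b{b}", year_a=2021, comparison_type=ctype,
                         dstart_min=dstart, raw=np.nan, x=x,
                         sqrt_y=intercept + delta * x + u + rng.normal(0, sd_resid),
                         )
                )
    df = pd.DataFrame(rows)
    zd = (df.dstart_min - df.dstart_min.mean()) / df.dstart_min.std(ddof=0)
    df["sqrt_y"] = df["sqrt_y"] + slope_dstart * zd
    df["nnd_km"] = df["sqrt_y"] ** 2
    return df


class TestFitLmm:
    def test_recovers_planted_contrast(self):
        rng = np.random.default_rng(0)
        df = simulate_comparison_table(rng, delta=0.8)
        fit = fit_lmm(df, "nnd", ["comparison_type", "dstart_min"], random="individual")
        est = fit.params["comparison_type_between_individual"]
        se = fit.bse["comparison_type_between_individual"]
        assert abs(est - 0.8) < 3 * se
        assert fit.converged
        # marginal means back-transform: squared sqrt-scale means
        mm = fit_lmm(df, "nnd", ["comparison_type"], random="individual",
                     emm_term="comparison_type").marginal_means
        assert mm["within_individual"]["mean"] == pytest.approx(2.5**2, rel=0.1)
        assert mm["between_individual"]["mean"] == pytest.approx(3.3**2, rel=0.1)
        assert mm["within_individual"]["ci_lo"] < mm["within_individual"]["mean"] < mm["within_individual"]["ci_hi"]

    def test_standardization_is_unit_invariant(self):
        rng = np.random.default_rng(1)
        df = simulate_comparison_table(rng, slope_dstart=0.3)
        f1 = fit_lmm(df, "nnd", ["comparison_type", "dstart_min"], random="individual")
        df2 = df.assign(dstart_min=df.dstart_min * 60.0)  # minutes -> seconds
        f2 = fit_lmm(df2, "nnd", ["comparison_type", "dstart_min"], random="individual")
        assert f1.params["z_dstart_min"] == pytest.approx(f2.params["z_dstart_min"], rel=1e-6)

    def test_zero_variance_random_effect_flagged_singular(self):
        rng = np.random.default_rng(2)
        df = simulate_comparison_table(rng, sd_bird=0.0, n_birds=30)
        fit = fit_lmm(df, "nnd", ["comparison_type"], random="individual")
        assert fit.singular
        assert fit.random_variances["individual"] == pytest.approx(0.0, abs=1e-3)

    def test_constant_response_degenerates_gracefully(self):
        rng = np.random.default_rng(3)
        df = simulate_comparison_table(rng, n_birds=10)
        df["nnd_km"] = 4.0
        fit = fit_lmm(df, "nnd", ["comparison_type"], random="individual")
        assert fit.params["comparison_type_between_individual"] == pytest.approx(0.0, abs=1e-8)
        assert fit.singular

    def test_missing_columns_named(self):
        df = pd.DataFrame({"nnd_km": [1.0, 2.0]})
        with pytest.raises(ConfigError, match="comparison_type"):
            fit_lmm(df, "nnd", ["comparison_type"], random="none")

    def test_empty_table_errors(self):
        with pytest.raises(ConfigError):
            fit_lmm(pd.DataFrame(), "nnd", [], random="none")


class TestLrt:
    def test_planted_variance_detected(self):
        rng = np.random.default_rng(4)
        df = simulate_comparison_table(rng, sd_bird=0.8, n_birds=50)
        chi2, dof, p = lrt_random_effect(
            df, "nnd", ["comparison_type"], "individual", "none"
        )
        assert dof == 1 and chi2 > 10 and p < 0.001

    def test_deterministic_on_identical_input(self):
        rng = np.random.default_rng(5)
        df = simulate_comparison_table(rng, n_birds=20)
        a = lrt_random_effect(df, "nnd", ["comparison_type"], "individual", "none")
        b = lrt_random_effect(df, "nnd", ["comparison_type"], "individual", "none")
        assert a == b

    def test_no_variance_gives_small_statistic(self):
        rng = np.random.default_rng(6)
        df = simulate_comparison_table(rng, sd_bird=0.0, n_birds=30)
        chi2, _, p = lrt_random_effect(
            df, "nnd", ["comparison_type"], "individual", "none"
        )
        assert chi2 < 4.0 and p > 0.04


class TestVif:
    def _orthogonal_pair(self, n=64):
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        return x1, x2

    def test_orthogonal_covariates_give_one(self):
        x1, x2 = self._orthogonal_pair()
        df = pd.DataFrame({"a": x1, "b": x2})
        out = vif(df, ["a", "b"])
        assert out["z_a"] == pytest.approx(1.0, abs=1e-9)
        assert out["z_b"] == pytest.approx(1.0, abs=1e-9)

    def test_correlated_pair_closed_form(self):
        x1, e = self._orthogonal_pair()
        rho = 0.6
        x2 = rho * x1 + np.sqrt(1 - rho**2) * e  # exact sample correlation rho
        df = pd.DataFrame({"a": x1, "b": x2})
        out = vif(df, ["a", "b"])
        assert out["z_a"] == pytest.approx(1.0 / (1.0 - rho**2), rel=1e-9)  # 1.5625
        assert out["z_b"] == pytest.approx(1.5625, rel=1e-9)

    def test_duplicated_column_is_infinite(self):
        x1, _ = self._orthogonal_pair()
        df = pd.DataFrame({"a": x1, "b": x1.copy()})
        out = vif(df, ["a", "b"])
        assert np.isinf(out["z_a"]) and np.isinf(out["z_b"])


class TestRunAnalysis:
    def test_within_year_menu_has_six_fits(self):
        rng = np.random.default_rng(7)
        df = simulate_comparison_table(rng)
        df["distal_km"] = df["nnd_km"] * 1.5
        df["bearing_diff_rad"] = (df["sqrt_y"] - df["sqrt_y"].min()) / 4
        df["capture_dist_m"] = rng.uniform(0, 300, len(df))
        res = run_analysis("within_year", df, with_lrt=False)
        assert len(res["fits"]) == 6  # base + interaction per response
        base = res["fits"][("nnd", "base")]
        assert "z_capture_dist_m" in base.params.index
        bearing = res["fits"][("bearing", "base")]
        assert "z_capture_dist_m" not in bearing.params.index  # nnd/distal only

    def test_single_capture_area_drops_distance_term(self):
        rng = np.random.default_rng(8)
        df = simulate_comparison_table(rng)
        df["capture_dist_m"] = 0.0
        res = run_analysis("within_year", df, responses=("nnd",), with_lrt=False)
        fit = res["fits"][("nnd", "base")]
        assert "capture_dist_m" in fit.dropped_terms

    def test_unknown_design_errors(self):
        with pytest.raises(ConfigError):
            run_analysis("nope", pd.DataFrame({"a": [1]}))

    def test_design_menu_matches_analysis_plan(self):
        assert DESIGNS["within_year"]["random"] == "individual_in_year"
        assert DESIGNS["between_year"]["random"] == "individual"
        assert DESIGNS["colony_overlap"]["random"] == "day_in_year"
        assert "at_sea_overlap" in DESIGNS["at_sea_overlap"]["base"]


def test_matches_lme4_reference(tmp_path):
    """REML fixed effects agree with an independent lme4 fit."""
    rng = np.random.default_rng(9)
    df = simulate_comparison_table(rng, n_birds=25, pairs_per_bird=2)
    fit = fit_lmm(df, "nnd", ["comparison_type"], random="individual")

    csv = tmp_path / "tab.csv"
    export = pd.DataFrame(
        {
            "y": np.sqrt(df["nnd_km"]),
            "x": (df["comparison_type"] == "between_individual").astype(int),
            "g": df["bird_a"],
        }
    )
    export.to_csv(csv, index=False)
    rscript = textwrap.dedent(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        m <- lmer(y ~ x + (1|g), data=d, REML=TRUE)
        cat(fixef(m), sqrt(diag(vcov(m))), sep="\\n")
        """
    )
    out = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    b0, b1, se0, se1 = [float(v) for v in out.stdout.split()]
    assert fit.params["Intercept"] == pytest.approx(b0, abs=1e-4)
    assert fit.params["comparison_type_between_individual"] == pytest.approx(b1, abs=1e-4)
    assert fit.bse["comparison_type_between_individual"] == pytest.approx(se1, rel=1e-3)
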