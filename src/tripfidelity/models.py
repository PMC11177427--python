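"""Linear mixed models for fidelity, effort, and overlap analyses.

All responses (NND, distal-point distance, bearing difference) are
right-skewed and non-negative; they are square-root transformed before
fitting and marginal means are squared back to natural units. Numeric
covariates are mean-centred and scaled so effect sizes are directly
comparable. Random-intercept structures follow the analysis design:
individual (optionally nested in tracking year) for the fidelity models,
day nested in year for the overlap models. REML is used for estimate
tables; likelihood-ratio tests of a random-effect variance refit both
models by ML and refer 2*delta-loglik to chi-square with 1 df. Fixed-effect
tests use Wald t statistics with between-within degrees of freedom (the
asymptotic z reference is anticonservative when the number of individuals
is small).
"""
from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError

logger = logging.getLogger(__name__)

RESPONSE_COLUMNS = {
    "nnd": "nnd_km",
    "distal": "distal_km",
    "bearing": "bearing_diff_rad",
}

# categorical fixed terms and their reference levels (None = first sorted level)
CATEGORICAL_REFS = {
    "comparison_type": "within_individual",
    "day_match": "within_day",
    "colony_overlap": False,
    "comparison_species": None,
    "tagging_year": None,
}

_SINGULAR_TOL = 1e-6


def _clean(name: str) -> str:
    return re.sub(r"\W+", "_", str(name))


@dataclass
class ModelFit:
    """Fitted mixed model: estimates on the transformed scale plus
    back-transformed marginal means in natural units."""

    response: str
    terms: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    marginal_means: dict = field(default_factory=dict)
    random_variances: dict = field(default_factory=dict)
    residual_variance: float = float("nan")
    loglik: float = float("nan")
    n_obs: int = 0
    converged: bool = True
    singular: bool = False
    dropped_terms: list[str] = field(default_factory=list)
    random: str = "none"

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "p": self.pvalues,
                "ci_lo": self.conf_int[0],
                "ci_hi": self.conf_int[1],
            }
        )
        return out


def _build_design(
    table: pd.DataFrame, terms: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]], list[str]]:
    """Expand model terms into numeric design columns.

    Categorical terms become treatment-coded indicators against their
    reference level; numeric terms are z-scored; ``a:b`` builds products of
    the expanded columns. Numeric terms with zero variance are dropped (with
    a note) — e.g. the capture-area distance when all individuals share one
    capture area.
    """
    cols: dict[str, pd.Series] = {}
    term_map: dict[str, list[str]] = {}
    dropped: list[str] = []

    def expand(term: str) -> list[str]:
        if term in term_map:
            return term_map[term]
        if ":" in term:
            left, right = term.split(":", 1)
            names = []
            for ln in expand(left):
                for rn in expand(right):
                    name = f"{ln}_x_{rn}"
                    cols[name] = cols[ln] * cols[rn]
                    names.append(name)
        elif term in CATEGORICAL_REFS:
            ref = CATEGORICAL_REFS[term]
            levels = sorted(table[term].unique(), key=str)
            if ref is None:
                ref = levels[0]
            names = []
            for lev in levels:
                if lev == ref:
                    continue
                name = _clean(f"{term}_{lev}")
                cols[name] = (table[term] == lev).astype(float)
                names.append(name)
        else:
            x = table[term].astype(float)
            sd = x.std(ddof=0)
            if not np.isfinite(sd) or sd == 0:
                dropped.append(term)
                term_map[term] = []
                return []
            name = _clean(f"z_{term}")
            cols[name] = (x - x.mean()) / sd
            names = [name]
        term_map[term] = names
        return names

    for t in terms:
        expand(t)
    X = pd.DataFrame(cols, index=table.index)
    return X, term_map, dropped


def _group_columns(random: str) -> list[str]:
    return {
        "none": [],
        "individual": ["_individual"],
        "year": ["_year"],
        "day": ["_day"],
        "individual_in_year": ["_year", "_individual"],
        "day_in_year": ["_year", "_day"],
    }[random]


def _demote_random(random: str, data: pd.DataFrame) -> str:
    """Simplify the random structure when a grouping factor is degenerate.

    A factor with fewer than two levels carries no estimable variance (and
    a single-group mixed fit is numerically ill-posed), so it is dropped:
    e.g. individual-in-year collapses to individual when only one year is
    present.
    """
    levels = {c: data[c].nunique() for c in data.columns}
    if random == "individual_in_year" and levels.get("_year", 2) < 2:
        random = "individual"
    if random == "day_in_year" and levels.get("_year", 2) < 2:
        random = "day"
    if random == "individual" and levels.get("_individual", 2) < 2:
        random = "none"
    if random == "year" and levels.get("_year", 2) < 2:
        random = "none"
    if random == "day" and levels.get("_day", 2) < 2:
        random = "none"
    return random


def _fit_engine(y, X, data, random: str, reml: bool):
    """Fit by REML/ML for a given random structure; returns a statsmodels result."""
    if random == "none":
        model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
        return model.fit()
    rhs = " + ".join(X.columns) if len(X.columns) else "1"
    df = pd.concat([pd.Series(y, name="_y", index=X.index), X, data], axis=1)
    if random == "individual":
        groups, vc = "_individual", None
    elif random == "year":
        groups, vc = "_year", None
    elif random == "day":
        groups, vc = "_day", None
    elif random == "individual_in_year":
        groups, vc = "_year", {"individual": "0 + C(_individual)"}
    elif random == "day_in_year":
        groups, vc = "_year", {"day": "0 + C(_day)"}
    else:
        raise ConfigError(f"unknown random structure '{random}'")
    model = sm.MixedLM.from_formula(
        f"_y ~ {rhs}", data=df, groups=groups, re_formula="1", vc_formula=vc
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=reml)


def _marginal_means(result, term_cols: list[str], levels: list, ref) -> dict:
    """Back-transformed (squared) marginal means per level of one factor,
    evaluated at covariate means (zero after centring)."""
    params = result.params
    cov = result.cov_params()
    names = list(params.index)
    const = "Intercept" if "Intercept" in names else "const"
    out = {}
    for lev, col in zip(levels, [None] + term_cols):
        c = pd.Series(0.0, index=names)
        c[const] = 1.0
        if col is not None:
            c[col] = 1.0
        est = float(c @ params)
        se = float(np.sqrt(c @ cov.loc[names, names] @ c))
        lo, hi = est - 1.96 * se, est + 1.96 * se
        out[str(lev)] = {
            "mean": est * abs(est),
            "ci_lo": lo * abs(lo),
            "ci_hi": hi * abs(hi),
        }
    return out


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: list[str],
    random: str = "none",
    individual_col: str = "bird_a",
    year_col: str = "year_a",
    day_col: str = "day",
    emm_term: str | None = None,
    reml: bool = True,
) -> ModelFit:
    """Fit one Gaussian LMM on the square-root-transformed response.

    ``random`` is one of none / individual / year / individual_in_year /
    day_in_year. ``emm_term`` names a categorical fixed term for which
    back-transformed marginal means (natural units, 95% CI) are reported.
    Non-convergence and singular (near-zero) variance components are
    flagged, not raised.
    """
    if table.empty:
        raise ConfigError("cannot fit model on an empty table")
    rcol = RESPONSE_COLUMNS.get(response, response)
    needed = {rcol}
    for t in fixed:
        needed.update(t.split(":"))
    missing = sorted(needed - set(table.columns))
    if missing:
        raise ConfigError(f"table missing columns required by the model: {missing}")

    df = table.dropna(subset=sorted(needed)).copy()
    if df.empty:
        raise ConfigError("no complete rows for the requested model")
    y = np.sqrt(df[rcol].astype(float).clip(lower=0.0)).rename("_y")

    X, term_map, dropped = _build_design(df, list(fixed))
    if dropped:
        logger.info("fit_lmm(%s): dropped zero-variance term(s) %s", response, dropped)

    data = pd.DataFrame(index=df.index)
    for col_name, source in (
        ("_individual", individual_col),
        ("_year", year_col),
        ("_day", day_col),
    ):
        if col_name in _group_columns(random):
            if source not in df.columns:
                raise ConfigError(f"random structure '{random}' needs column '{source}'")
            data[col_name] = df[source].astype(str)
    random = _demote_random(random, data)

    converged, singular = True, False
    try:
        result = _fit_engine(y, X, data, random, reml)
        converged = bool(getattr(result, "converged", True))
    except Exception as exc:  # pragma: no cover - degenerate numerical inputs
        logger.warning("mixed fit failed (%s); falling back to OLS", exc)
        result = _fit_engine(y, X, data, "none", reml)
        converged = False

    random_variances: dict[str, float] = {}
    resid_var = float(getattr(result, "scale", np.nan))
    if hasattr(result, "cov_re") and random != "none" and converged:
        try:
            re_var = float(np.asarray(result.cov_re)[0, 0])
            top = {"individual": "individual", "year": "year", "day": "day",
                   "individual_in_year": "year", "day_in_year": "year"}[random]
            random_variances[top] = re_var
            vcomp = np.asarray(getattr(result, "vcomp", []))
            vc_names = {"individual_in_year": ["individual"], "day_in_year": ["day"]}.get(random, [])
            for name, v in zip(vc_names, vcomp):
                random_variances[name] = float(v)
            total = sum(random_variances.values()) + resid_var
            if total > 0 and any(v < _SINGULAR_TOL * total for v in random_variances.values()):
                singular = True
        except Exception:
            pass
    if np.isfinite(resid_var) and resid_var < 1e-12:
        singular = True

    params = result.params
    keep = [n for n in params.index if not n.startswith("Group") and n != "Group Var"
            and not n.endswith(" Var")]
    bse = result.bse.loc[keep]
    if random != "none" and converged:
        # Wald t with between-within df: the z reference ignores the finite
        # number of random-effect levels and is anticonservative with tens
        # of individuals. m = levels of the finest random factor.
        finest = next(c for c in ("_individual", "_day", "_year") if c in data.columns)
        m = data[finest].nunique()
        n_p = len(keep)
        ddf = {}
        for name in keep:
            if name in ("Intercept", "const"):
                varies_within = True
            else:
                col = X[name] if name in X.columns else None
                varies_within = bool(
                    col is not None
                    and (col.groupby(data[finest]).nunique() > 1).any()
                )
            ddf[name] = max(
                1.0,
                (len(df) - m - n_p) if varies_within else (m - n_p),
            )
        tvals = params.loc[keep] / bse
        pvalues = pd.Series(
            {n: 2.0 * stats.t.sf(abs(tvals[n]), ddf[n]) for n in keep}
        ).loc[keep]
        crit = pd.Series({n: stats.t.ppf(0.975, ddf[n]) for n in keep}).loc[keep]
        conf = pd.DataFrame(
            {0: params.loc[keep] - crit * bse, 1: params.loc[keep] + crit * bse}
        )
    else:
        pvalues = result.pvalues.loc[keep]
        conf = result.conf_int().loc[keep]
    fit = ModelFit(
        response=response,
        terms=list(fixed),
        params=params.loc[keep],
        bse=bse,
        pvalues=pvalues,
        conf_int=conf,
        residual_variance=resid_var,
        random_variances=random_variances,
        loglik=float(result.llf),
        n_obs=int(len(df)),
        converged=converged,
        singular=singular,
        dropped_terms=dropped,
        random=random if converged else "none",
    )
    if emm_term and emm_term in term_map and term_map[emm_term]:
        ref = CATEGORICAL_REFS.get(emm_term)
        levels = sorted(df[emm_term].unique(), key=str)
        if ref is None:
            ref = levels[0]
        ordered = [ref] + [l for l in levels if l != ref]
        fit.marginal_means = _marginal_means(result, term_map[emm_term], ordered, ref)
    return fit


def lrt_random_effect(
    table: pd.DataFrame,
    response: str,
    fixed: list[str],
    random_full: str,
    random_reduced: str,
    **kwargs,
) -> tuple[float, int, float]:
    """Likelihood-ratio test for a single random-intercept variance.

    Both models are fitted by ML; the statistic 2*(ll_full - ll_reduced) is
    floored at zero (boundary estimates can make it marginally negative) and
    referred to chi-square with 1 df.
    """
    full = fit_lmm(table, response, fixed, random=random_full, reml=False, **kwargs)
    reduced = fit_lmm(table, response, fixed, random=random_reduced, reml=False, **kwargs)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < 0:
        if chi2 < -1e-6:
            logger.warning("LRT: reduced loglik above full by %.3g; flooring at 0", -chi2)
        chi2 = 0.0
    return chi2, 1, float(stats.chi2.sf(chi2, 1))


def vif(table: pd.DataFrame, fixed_terms: list[str]) -> dict[str, float]:
    """Variance inflation factor per expanded design column.

    VIF_j = 1 / (1 - R2_j) from regressing column j on the remaining
    columns; perfectly collinear columns report infinity.
    """
    X, _, _ = _build_design(table.dropna(subset=[t for term in fixed_terms for t in term.split(":")]),
                            list(fixed_terms))
    X = sm.add_constant(X, has_constant="add")
    out = {}
    names = [c for c in X.columns if c != "const"]
    for name in names:
        others = X[[c for c in X.columns if c != name]]
        yj = X[name].to_numpy()
        beta, _, _, _ = np.linalg.lstsq(others.to_numpy(), yj, rcond=None)
        resid = yj - others.to_numpy() @ beta
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        if ss_tot == 0:
            out[name] = float("inf")
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


# per-design fixed-term menus; {cd} marks capture-area distance, included
# only for the nnd/distal responses and dropped automatically when it has
# zero variance (single capture area)
DESIGNS = {
    "within_year": {
        "base": ["comparison_type", "dstart_min"],
        "interaction": ["comparison_type", "dstart_min", "comparison_type:dstart_min"],
        "capture_dist": True,
        "random": "individual_in_year",
        "reduced": "year",
        "emm": "comparison_type",
    },
    "between_year": {
        "base": ["comparison_type", "delta_years", "delta_laying_days"],
        "interaction": ["comparison_type", "delta_years", "delta_laying_days",
                        "comparison_type:delta_years"],
        "capture_dist": True,
        "random": "individual",
        "reduced": "none",
        "emm": "comparison_type",
    },
    "effort": {
        "base": ["tagging_year", "dstart_min", "time_to_first_bout_min",
                 "mean_bout_duration_min", "total_foraging_min", "prop_foraging"],
        "interaction": None,
        "capture_dist": False,
        "random": "individual",
        "reduced": "none",
        "emm": None,
    },
    "same_day_within_species": {
        "base": ["day_match", "capture_dist_m"],
        "interaction": None,
        "capture_dist": False,
        "random": "year",
        "reduced": "none",
        "emm": "day_match",
    },
    "same_day_between_species": {
        "base": ["day_match", "capture_dist_m", "comparison_species"],
        "interaction": ["day_match", "capture_dist_m", "comparison_species",
                        "day_match:comparison_species"],
        "capture_dist": False,
        "random": "year",
        "reduced": "none",
        "emm": "day_match",
    },
    "colony_overlap": {
        "base": ["colony_overlap"],
        "interaction": None,
        "capture_dist": False,
        "random": "day_in_year",
        "reduced": "year",
        "emm": "colony_overlap",
    },
    "at_sea_overlap": {
        "base": ["at_sea_overlap", "capture_dist_m"],
        "interaction": None,
        "capture_dist": False,
        "random": "day_in_year",
        "reduced": "year",
        "emm": None,
    },
}


def _prepare_columns(design: str, table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if design == "effort" and "tagging_year" not in df.columns and "year" in df.columns:
        df["tagging_year"] = df["year"].astype(str)
    if design.startswith("same_day"):
        df = df[df["species_match"] == (
            "within_species" if design.endswith("within_species") else "between_species"
        )]
        if design.endswith("between_species") and "comparison_species" not in df.columns:
            df["comparison_species"] = df["species_b"]
    return df


def run_analysis(
    design: str,
    table: pd.DataFrame,
    responses: tuple[str, ...] = ("nnd", "distal", "bearing"),
    with_lrt: bool = True,
) -> dict:
    """Fit the full model menu of one analysis design.

    Fits the base model (and, where defined, the time/species interaction
    variant) for each response, plus the likelihood-ratio test for the
    design's focal random-effect variance. The table should contain a
    single species for the fidelity/effort designs. Returns a nested dict
    of :class:`ModelFit` and LRT tuples.
    """
    if design not in DESIGNS:
        raise ConfigError(f"unknown design '{design}' (choose from {sorted(DESIGNS)})")
    if table.empty:
        raise ConfigError(f"empty comparison table for design '{design}'")
    menu = DESIGNS[design]
    df = _prepare_columns(design, table)

    group_kwargs = {}
    if "bird_id" in df.columns and "bird_a" not in df.columns:
        group_kwargs["individual_col"] = "bird_id"
    if "year" in df.columns and "year_a" not in df.columns:
        group_kwargs["year_col"] = "year"

    out: dict = {"design": design, "fits": {}, "lrt": {}}
    for resp in responses:
        fixed = list(menu["base"])
        if menu["capture_dist"] and resp in ("nnd", "distal"):
            fixed.append("capture_dist_m")
        fit = fit_lmm(df, resp, fixed, random=menu["random"],
                      emm_term=menu["emm"], **group_kwargs)
        out["fits"][(resp, "base")] = fit
        if menu["interaction"]:
            fixed_i = list(menu["interaction"])
            if menu["capture_dist"] and resp in ("nnd", "distal"):
                fixed_i.append("capture_dist_m")
            out["fits"][(resp, "interaction")] = fit_lmm(
                df, resp, fixed_i, random=menu["random"],
                emm_term=menu["emm"], **group_kwargs
            )
        if with_lrt and menu["random"] != "none":
            out["lrt"][resp] = lrt_random_effect(
                df, resp, fixed, menu["random"], menu["reduced"], **group_kwargs
            )
    return out
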