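"""Diversity-richness regressions, group comparisons, collinearity
screening, interaction mixed models and random-forest contributions.

The central association is an ordinary least-squares fit of log EM fungal
diversity on log neighboring plant richness, overall and within each forest
type.  Environmental moderation is tested with a random-intercept mixed
model  y ~ plant + env + plant:env + (1|site)  fitted by REML, with the
environmental covariate entering both intercept and slope.  Variable
importance uses random-forest regression with permutation importance and a
response-permutation test for model significance.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger("emnet")

__all__ = ["fit_diversity_regressions", "anova_duncan", "collinearity_filter",
           "fit_interaction_lmm", "rf_contributions", "LmmResult",
           "ImportanceResult"]


def _transform_response(y: np.ndarray, how: str) -> tuple[np.ndarray, str]:
    if how == "auto":
        how = "log" if (y > 0).all() else "raw"
    if how == "log":
        if (y <= 0).any():
            raise ValueError("log transform needs strictly positive values")
        return np.log(y), "log"
    if how == "signed_log":
        return np.sign(y) * np.log1p(np.abs(y)), "signed_log"
    if how == "raw":
        return y, "raw"
    raise ValueError(f"unknown response transform {how!r}")


def fit_diversity_regressions(div: pd.DataFrame, meta: pd.DataFrame,
                              richness_col: str = "plant_richness",
                              group_col: str = "forest_type",
                              response: str = "auto",
                              min_n: int = 3) -> pd.DataFrame:
    """OLS of (transformed) EM metrics on ln plant richness.

    One fit per metric overall plus one per forest type.  Metrics that are
    strictly positive are natural-log transformed (``response="auto"``);
    metrics spanning zero stay on the raw scale, recorded per row.
    Groups with fewer than ``min_n`` plots or zero predictor variance are
    skipped with a warning.
    """
    meta = meta.loc[div.index]
    x_all = np.log(meta[richness_col].to_numpy(dtype=float))
    rows = []
    groups = ["overall"] + list(pd.unique(meta[group_col]))
    for metric in div.columns:
        y_raw = div[metric].to_numpy(dtype=float)
        try:
            y_all, used = _transform_response(y_raw, response)
        except ValueError as exc:
            logger.warning("skipping %s: %s", metric, exc)
            continue
        for g in groups:
            mask = np.ones(len(div), bool) if g == "overall" \
                else (meta[group_col] == g).to_numpy()
            x, y = x_all[mask], y_all[mask]
            if mask.sum() < min_n or np.std(x) == 0:
                logger.warning("skipping %s/%s: n=%d or constant predictor",
                               metric, g, mask.sum())
                continue
            res = stats.linregress(x, y)
            rows.append({"metric": metric, "group": g,
                         "slope": res.slope, "intercept": res.intercept,
                         "r_squared": res.rvalue ** 2, "p_value": res.pvalue,
                         "n": int(mask.sum()), "transform": used})
    return pd.DataFrame(rows)


@lru_cache(maxsize=512)
def _duncan_q(alpha: float, span: int, df: int) -> float:
    # Duncan's protection level: alpha_p = 1 - (1 - alpha)^(span - 1)
    a_p = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(stats.studentized_range.ppf(1.0 - a_p, span, df))


def anova_duncan(values, groups, alpha: float = 0.05) -> dict:
    """One-way ANOVA with Duncan's multiple range letters.

    Returns ``{"F", "p", "df", "means", "letters", "table"}`` where groups
    sharing a letter do not differ at the protection level ``alpha``.
    Uses the harmonic mean of group sizes in the critical ranges when
    sizes are unequal.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    by = {g: values[groups == g] for g in labels}
    sizes = {g: len(v) for g, v in by.items()}
    if min(sizes.values()) < 2:
        raise ValueError("need at least 2 samples per group")
    n = len(values)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by.values())
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    if ss_between == 0:
        F, p = 0.0, 1.0
    elif mse == 0:
        F, p = float("inf"), 0.0
    else:
        F = (ss_between / df_b) / mse
        p = float(stats.f.sf(F, df_b, df_w))

    means = pd.Series({g: by[g].mean() for g in labels}).sort_values(
        ascending=False)
    nh = k / sum(1.0 / sizes[g] for g in labels)
    order = list(means.index)

    def homogeneous(i: int, j: int) -> bool:
        if i == j:
            return True
        span = j - i + 1
        crit = _duncan_q(alpha, span, df_w) * np.sqrt(mse / nh) if mse > 0 else 0.0
        return means.iloc[i] - means.iloc[j] <= crit

    # maximal homogeneous stretches of the sorted means share a letter
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous(i, j + 1):
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o[0] <= iv[0] and iv[1] <= o[1] and o != iv
                          for o in intervals)]
    letters = {g: "" for g in order}
    for letter_i, (i, j) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + letter_i)
        for g in order[i:j + 1]:
            letters[g] += ch

    table = pd.DataFrame({
        "mean": means,
        "n": pd.Series(sizes)[means.index],
        "letters": pd.Series(letters)[means.index],
    })
    return {"F": float(F), "p": float(p), "df": (df_b, df_w),
            "means": means, "letters": letters, "table": table}


def collinearity_filter(env: pd.DataFrame, cut: float = 0.6
                        ) -> tuple[list[str], list[dict]]:
    """Greedy pruning of covariates correlated at |r| >= ``cut``.

    Repeatedly takes the most correlated violating pair and drops the
    member with the larger mean absolute correlation to all remaining
    covariates (ties broken alphabetically), until every retained pair has
    |r| < cut.  Returns (retained, dropped-with-reason).
    """
    if env.shape[1] < 2:
        return list(env.columns), []
    keep = list(env.columns)
    dropped: list[dict] = []
    while len(keep) > 1:
        corr = env[keep].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        if corr.loc[worst] < cut:
            break
        a, b = sorted(worst)
        mean_a = corr.loc[a].drop(a).mean()
        mean_b = corr.loc[b].drop(b).mean()
        victim = (a if mean_a > mean_b else
                  b if mean_b > mean_a else max(a, b))
        other = b if victim == a else a
        dropped.append({"variable": victim,
                        "reason": f"|r|={corr.loc[a, b]:.3f} with {other}; "
                                  f"mean |r|={max(mean_a, mean_b):.3f}"})
        keep.remove(victim)
    return keep, dropped


@dataclasses.dataclass
class LmmResult:
    fixed_effects: pd.DataFrame   #: estimate / se / p per term
    site_variance: float
    residual_variance: float
    env_name: str
    converged: bool
    method: str                   #: "reml" or fallback "ml"
    singular: bool
    n: int


def fit_interaction_lmm(em, plant, env, site, env_name: str = "env",
                        standardize_env: bool = True,
                        response: str = "raw") -> LmmResult:
    """Random-intercept mixed model  em ~ plant + env + plant:env + (1|site).

    Fitted by REML (ML fallback on non-convergence).  The covariate is
    z-scored by default so intercept and interaction terms are comparable
    across covariates; disable with ``standardize_env=False``.  Wald
    p-values are reported for the fixed effects.
    """
    em = np.asarray(em, dtype=float)
    y, _ = _transform_response(em, response)
    env = np.asarray(env, dtype=float)
    if np.std(env) == 0:
        raise ValueError(f"covariate {env_name!r} is constant; "
                         "interaction is inestimable")
    if standardize_env:
        env = (env - env.mean()) / env.std(ddof=1)
    df = pd.DataFrame({"y": y, "plant": np.asarray(plant, dtype=float),
                       "env": env, "site": np.asarray(site)})
    if df["site"].nunique() < 2:
        raise ValueError("need at least 2 sites for a random intercept")

    def _fit(reml: bool):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ plant + env + plant:env", df,
                                groups=df["site"])
            try:
                return model.fit(reml=reml)
            except np.linalg.LinAlgError:
                # boundary (site variance ~ 0) can leave BFGS with a
                # singular Hessian; Powell is derivative-free
                return model.fit(reml=reml, method="powell")

    method = "reml"
    try:
        res = _fit(reml=True)
        converged = bool(res.converged)
    except Exception:
        converged = False
        res = None
    if res is None or not converged:
        try:
            res = _fit(reml=False)
            method = "ml"
            converged = bool(res.converged)
        except Exception as exc:
            raise RuntimeError(f"mixed model failed to converge: {exc}")

    site_var = float(res.cov_re.iloc[0, 0])
    fixed = pd.DataFrame({
        "estimate": res.fe_params,
        "se": res.bse_fe,
        "p": res.pvalues[res.fe_params.index],
    })
    return LmmResult(fixed_effects=fixed, site_variance=max(site_var, 0.0),
                     residual_variance=float(res.scale), env_name=env_name,
                     converged=converged, method=method,
                     singular=site_var <= 1e-8, n=len(df))


@dataclasses.dataclass
class ImportanceResult:
    importances: pd.Series        #: mean drop in R^2 on permutation
    contributions_pct: pd.Series  #: importances rescaled to percent of total
    explained_variance: float     #: out-of-bag R^2
    p_model: float
    low_n: bool


def rf_contributions(target, predictors: pd.DataFrame, seed: int = 0,
                     n_estimators: int = 500, n_permutations: int = 999,
                     n_repeats: int = 10) -> ImportanceResult:
    """Random-forest contributions of predictors to a response.

    Permutation importance (drop in R^2 over ``n_repeats`` shuffles per
    predictor), out-of-bag explained variance, and a model significance p
    from ``n_permutations`` response permutations compared on OOB R^2.
    """
    y = np.asarray(target, dtype=float)
    X = predictors.to_numpy(dtype=float)
    n, p = X.shape
    low_n = n < 10
    if low_n:
        logger.warning("random forest with n=%d (<10); treat with caution", n)
    mtry = int(np.ceil(p / 3))

    def _fit(yy, rs):
        rf = RandomForestRegressor(n_estimators=n_estimators,
                                   max_features=mtry, oob_score=True,
                                   bootstrap=True, random_state=rs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X, yy)
        return rf

    rf = _fit(y, seed)
    oob = float(rf.oob_score_)
    imp = permutation_importance(rf, X, y, n_repeats=n_repeats,
                                 random_state=seed)
    importances = pd.Series(imp.importances_mean, index=predictors.columns)
    pos = importances.clip(lower=0.0)
    total = pos.sum()
    pct = pos / total * 100.0 if total > 0 else pos * 0.0

    rng = np.random.default_rng(seed)
    null_ge = 0
    for i in range(n_permutations):
        yp = rng.permutation(y)
        if float(_fit(yp, seed + 1 + i).oob_score_) >= oob:
            null_ge += 1
    p_model = (1 + null_ge) / (n_permutations + 1)
    return ImportanceResult(importances=importances, contributions_pct=pct,
                            explained_variance=oob, p_model=float(p_model),
                            low_n=low_n)
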