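"""Natural-log response ratios of group means.

For a variable measured in a treatment group E and a control group C,

    lnR = ln(mean_E) - ln(mean_C)
    v   = SD_E^2 / (n_E mean_E^2) + SD_C^2 / (n_C mean_C^2)

with the percent change reported as (exp(lnR) - 1) * 100.  Significance of
lnR = 0 uses the conventional meta-analytic normal approximation
(z = lnR / sqrt(v)); a one-way ANOVA p across groups is reported alongside
because the study design also compares groups that way.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ResponseRatioResult", "log_response_ratio", "response_ratio_table"]


@dataclasses.dataclass
class ResponseRatioResult:
    lnR: float
    v: float
    se: float
    ci95: tuple[float, float]
    percent_change: float
    z: float
    p: float
    significant: bool
    stars: str
    n_treat: int
    n_control: int


def log_response_ratio(treat, control, alpha: float = 0.05) -> ResponseRatioResult:
    """Log response ratio of ``treat`` relative to ``control``.

    Both groups need >= 2 observations and strictly positive means.
    """
    t = np.asarray(treat, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("both groups need at least 2 observations")
    mt, mc = t.mean(), c.mean()
    if mt <= 0 or mc <= 0:
        raise ValueError("group means must be strictly positive for lnR")
    lnr = math.log(mt) - math.log(mc)
    v = (t.std(ddof=1) ** 2 / (t.size * mt ** 2)
         + c.std(ddof=1) ** 2 / (c.size * mc ** 2))
    se = math.sqrt(v)
    if se > 0:
        z = lnr / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = math.inf if lnr != 0 else 0.0
        p = 0.0 if lnr != 0 else 1.0
    stars = "**" if p < 0.01 else "*" if p < alpha else ""
    return ResponseRatioResult(
        lnR=lnr, v=v, se=se, ci95=(lnr - 1.96 * se, lnr + 1.96 * se),
        percent_change=(math.exp(lnr) - 1.0) * 100.0,
        z=z, p=p, significant=p < alpha, stars=stars,
        n_treat=int(t.size), n_control=int(c.size))


def response_ratio_table(metrics: pd.DataFrame, groups: pd.Series,
                         control: str, treatments: list[str] | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """lnR of every metric column for each treatment level vs the control.

    ``groups`` aligns with ``metrics`` rows (e.g. forest type per sample).
    Also reports the one-way ANOVA p across all levels of ``groups`` for
    each metric, since group comparisons in this design are made both ways.
    """
    groups = groups.loc[metrics.index]
    levels = [g for g in pd.unique(groups) if g != control]
    if treatments is not None:
        levels = [g for g in treatments if g in levels]
    rows = []
    for metric in metrics.columns:
        vals = metrics[metric]
        try:
            _, anova_p = stats.f_oneway(
                *[vals[groups == g].to_numpy() for g in pd.unique(groups)])
        except Exception:
            anova_p = float("nan")
        for g in levels:
            try:
                r = log_response_ratio(vals[groups == g],
                                       vals[groups == control], alpha=alpha)
            except ValueError:
                # metrics spanning zero (z-scored indices) have no defined
                # ratio of means; reported as NaN, not an error
                rows.append({"metric": metric, "treat": g, "control": control,
                             "lnR": float("nan"), "v": float("nan"),
                             "se": float("nan"), "ci_low": float("nan"),
                             "ci_high": float("nan"),
                             "percent_change": float("nan"),
                             "z": float("nan"), "p": float("nan"),
                             "stars": "", "anova_p": float(anova_p)})
                continue
            rows.append({"metric": metric, "treat": g, "control": control,
                         "lnR": r.lnR, "v": r.v, "se": r.se,
                         "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                         "percent_change": r.percent_change,
                         "z": r.z, "p": r.p, "stars": r.stars,
                         "anova_p": float(anova_p)})
    return pd.DataFrame(rows)
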