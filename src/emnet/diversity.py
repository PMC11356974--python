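"""Alpha diversity estimators and Sorensen beta-diversity partitioning.

Alpha indices are the five standard ones for amplicon count tables:
richness, Shannon entropy (nats), Gini-Simpson, bias-corrected Chao1 and
ACE.  Chao1 and ACE delegate to scikit-bio; the entropy-based indices are
computed directly from the composition.

Beta diversity follows the Baselga decomposition of the Sorensen
dissimilarity into a turnover component (Simpson dissimilarity, species
replacement) and a nestedness-resultant component (species loss):

    beta_sor = (b + c) / (2a + b + c)
    beta_sim = min(b, c) / (a + min(b, c))
    beta_sne = beta_sor - beta_sim

with a = shared taxa and b, c = taxa unique to either sample.  Multiple-site
analogues aggregate the pairwise unique fractions over all samples.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skalpha

__all__ = ["DiversityProfile", "BetaPartition", "alpha_diversity",
           "beta_partition"]


@dataclasses.dataclass
class BetaPartition:
    """Pairwise dissimilarity matrices, per-sample reductions and
    multiple-site values for the Sorensen family."""

    beta_sor: pd.DataFrame
    beta_sim: pd.DataFrame
    beta_sne: pd.DataFrame
    summary: pd.DataFrame          #: per-sample BetaSOR/BetaSIM/BetaSNE
    multi_site: dict[str, float]   #: multiple-site beta_sor/sim/sne
    summary_method: str = "mean_pairwise"


#: alias kept for API symmetry with the dataclass-style result containers
DiversityProfile = pd.DataFrame


def _ace(counts: np.ndarray) -> float:
    # scikit-bio raises on communities without rare (<=10) taxa or without
    # singletons in some versions; the estimator then reduces to S_obs
    counts = counts[counts > 0]
    rare = counts[counts <= 10]
    if rare.size == 0 or (rare == 1).all() and rare.size == counts.size:
        # all-singleton or no-rare edge cases: ACE undefined / degenerate
        if rare.size == 0:
            return float(counts.size)
    try:
        return float(_skalpha.ace(counts.astype(int), rare_threshold=10))
    except (ValueError, ZeroDivisionError):
        return float(counts.size)


def alpha_diversity(table: pd.DataFrame, simpson_variant: str = "gini",
                    chao1_bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Parameters
    ----------
    table : samples x taxa nonnegative counts.
    simpson_variant : ``"gini"`` (1 - sum p^2, default), ``"lambda"``
        (sum p^2) or ``"inverse"`` (1 / sum p^2).
    chao1_bias_corrected : use S + F1(F1-1)/(2(F2+1)); the classic
        S + F1^2/(2 F2) form otherwise.

    Returns a DataFrame with columns richness, shannon, simpson, chao1, ace
    indexed like ``table``.
    """
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    empty = X.sum(axis=1) == 0
    if empty.any():
        raise ValueError(
            f"empty samples: {table.index[empty].tolist()}")

    rows = []
    for i, sample in enumerate(table.index):
        c = X[i]
        c = c[c > 0]
        p = c / c.sum()
        lam = float((p ** 2).sum())
        if simpson_variant == "gini":
            simpson = 1.0 - lam
        elif simpson_variant == "lambda":
            simpson = lam
        elif simpson_variant == "inverse":
            simpson = 1.0 / lam
        else:
            raise ValueError(f"unknown simpson_variant {simpson_variant!r}")
        ci = np.round(c).astype(int)
        rows.append({
            "richness": int(c.size),
            "shannon": float(-(p * np.log(p)).sum()),
            "simpson": simpson,
            "chao1": float(_skalpha.chao1(ci, bias_corrected=chao1_bias_corrected)),
            "ace": _ace(ci),
        })
    return pd.DataFrame(rows, index=table.index)


def _pairwise_components(pa: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared / unique presence counts for every ordered sample pair."""
    a = pa @ pa.T                       # shared
    s = pa.sum(axis=1)
    b = s[:, None] - a                  # unique to row sample
    c = s[None, :] - a                  # unique to column sample
    return a, b, c


def beta_partition(table: pd.DataFrame,
                   summary: str = "mean_pairwise") -> BetaPartition:
    """Partition pairwise Sorensen dissimilarity into turnover + nestedness.

    ``summary`` chooses the per-sample reduction: ``"mean_pairwise"``
    (mean dissimilarity of each sample to all others, default) or
    ``"lcbd"`` (squared-deviation local contribution, normalised to sum 1).
    """
    if len(table) < 2:
        raise ValueError("beta diversity needs at least 2 samples")
    pa = (table.to_numpy(dtype=float) > 0).astype(float)
    if (pa.sum(axis=1) == 0).any():
        bad = table.index[pa.sum(axis=1) == 0].tolist()
        raise ValueError(f"samples without taxa: {bad}")

    a, b, c = _pairwise_components(pa)
    bc_min = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        sor = (b + c) / (2 * a + b + c)
        sim = bc_min / (a + bc_min)
    np.fill_diagonal(sor, 0.0)
    np.fill_diagonal(sim, 0.0)
    sne = sor - sim

    idx = table.index
    mats = {k: pd.DataFrame(v, index=idx, columns=idx)
            for k, v in {"beta_sor": sor, "beta_sim": sim, "beta_sne": sne}.items()}

    n = len(idx)
    if summary == "mean_pairwise":
        summ = pd.DataFrame({
            "BetaSOR": sor.sum(axis=1) / (n - 1),
            "BetaSIM": sim.sum(axis=1) / (n - 1),
            "BetaSNE": sne.sum(axis=1) / (n - 1),
        }, index=idx)
    elif summary == "lcbd":
        summ = {}
        for name, m in (("BetaSOR", sor), ("BetaSIM", sim), ("BetaSNE", sne)):
            # Gower-centre the squared dissimilarity; diagonal of the
            # centred matrix is each sample's contribution to total variance
            d2 = m ** 2
            g = -0.5 * d2
            g = g - g.mean(axis=0) - g.mean(axis=1)[:, None] + g.mean()
            diag = np.clip(np.diag(g), 0, None)
            total = diag.sum()
            summ[name] = diag / total if total > 0 else np.zeros(n)
        summ = pd.DataFrame(summ, index=idx)
    else:
        raise ValueError(f"unknown summary {summary!r}")

    # Baselga multiple-site family
    s_i = pa.sum(axis=1)
    union = (pa.sum(axis=0) > 0).sum()
    iu = np.triu_indices(n, k=1)
    sum_min = bc_min[iu].sum()
    sum_max = np.maximum(b, c)[iu].sum()
    core = s_i.sum() - union
    multi_sim = sum_min / (core + sum_min) if core + sum_min > 0 else 0.0
    denom = 2 * core + sum_min + sum_max
    multi_sor = (sum_min + sum_max) / denom if denom > 0 else 0.0
    multi = {"beta_sor": float(multi_sor), "beta_sim": float(multi_sim),
             "beta_sne": float(multi_sor - multi_sim)}

    return BetaPartition(mats["beta_sor"], mats["beta_sim"], mats["beta_sne"],
                         summ, multi, summary_method=summary)
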