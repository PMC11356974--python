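"""Synthetic study-shaped data with known ground truth.

Emulates a three-forest-type design (pure oak PF, oak-pine QPF, oak-broadleaf
QBF) with six plots per type, one composite sample per plot.  Each sample
carries a plant richness value, soil/litter covariates, an ectomycorrhizal
(EM) fungal count table and a rhizosphere bacterial count table.

The generating model is deliberately transparent so every downstream stage
has a recoverable truth:

* plant richness ~ truncated Poisson around a forest-type mean;
* covariates share a latent factor with (log) richness, giving a tunable
  covariate-richness correlation;
* the log of the realized EM taxon pool grows linearly with log richness
  (slope ``coupling_beta``), plus covariate effects, a Gaussian site
  intercept and residual noise; relative abundances are Dirichlet over the
  realized pool and counts multinomial at fixed sequencing depth
  (Dirichlet-multinomial compositional noise);
* bacterial taxa come in planted correlation blocks (Gaussian copula with
  equicorrelation inside a block, independence across blocks), so
  co-occurrence detection and module recovery have an exact answer key.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import write_abundance_table, write_json, write_metadata

__all__ = ["SimParams", "SyntheticDataset", "simulate_dataset",
           "planted_partition_truth", "write_dataset"]

#: covariate name -> (mean, sd); carbon/nitrogen/phosphorus in g/kg,
#: ammonium/nitrate/available-P in mg/kg.
COVARIATE_SCALE: dict[str, tuple[float, float]] = {
    "SOC": (20.0, 5.0), "TN": (1.5, 0.4), "LC": (430.0, 40.0),
    "LP": (1.2, 0.3), "pH": (6.5, 0.3), "NH4": (8.0, 2.0),
    "NO3": (5.0, 1.5), "SAP": (10.0, 3.0),
}


@dataclasses.dataclass
class SimParams:
    """Generator settings; defaults are the study conditions."""

    n_sites_per_type: int = 6
    forest_types: tuple[str, ...] = ("PF", "QPF", "QBF")
    richness_means: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"PF": 12.0, "QPF": 20.0, "QBF": 24.0})
    pool_size_fungi: int = 400
    pool_size_bacteria: int = 300
    coupling_beta: float = 0.5
    base_log_pool: float = 2.5
    #: direct covariate effects on latent EM diversity; zero by default so
    #: that coupling_beta = 0 is exactly the null model (covariates still
    #: correlate with richness through the shared factor)
    env_effect: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"SOC": 0.0, "TN": 0.0, "LC": 0.0, "LP": 0.0})
    env_richness_cor: float = 0.5
    site_sd: float = 0.1
    noise_sd: float = 0.1
    sequencing_depth: int = 10_000
    dirichlet_concentration: float = 1.0
    network_block_sizes: tuple[int, ...] = (8, 6)
    block_rho: float = 0.85
    bacteria_base_log_pool: float = 4.5
    bacteria_richness_coupling: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites_per_type < 1:
            raise ValueError("n_sites_per_type must be >= 1")
        for t in self.forest_types:
            mu = self.richness_means.get(t, 0.0)
            if mu <= 0:
                raise ValueError(f"richness mean for {t} must be > 0, got {mu}")
        if min(self.pool_size_fungi, self.pool_size_bacteria) < 1:
            raise ValueError("taxon pool sizes must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValueError("block_rho must be in [0, 1)")
        if sum(self.network_block_sizes) > self.pool_size_bacteria:
            raise ValueError("planted blocks exceed the bacterial pool")


@dataclasses.dataclass
class SyntheticDataset:
    fungal_table: pd.DataFrame
    bacterial_table: pd.DataFrame
    metadata: pd.DataFrame
    truth: dict


def planted_partition_truth(p: SimParams) -> dict[str, int]:
    """Ground-truth module label for every bacterial taxon.

    Taxa in planted block ``i`` get label ``i``; background taxa get ``-1``.
    Purely positional, hence reproducible across runs with equal sizes.
    """
    labels: dict[str, int] = {}
    idx = 0
    for b, size in enumerate(p.network_block_sizes):
        for _ in range(size):
            labels[f"B{idx:04d}"] = b
            idx += 1
    for j in range(idx, p.pool_size_bacteria):
        labels[f"B{j:04d}"] = -1
    return labels


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def simulate_dataset(p: SimParams | None = None, **overrides) -> SyntheticDataset:
    """Draw one complete synthetic study; see the module docstring for the model."""
    if p is None:
        p = SimParams(**overrides)
    elif overrides:
        p = dataclasses.replace(p, **overrides)
    rng = np.random.default_rng(p.seed)
    n_types = len(p.forest_types)
    n = n_types * p.n_sites_per_type

    site_ids = np.tile(np.arange(1, p.n_sites_per_type + 1), n_types)
    types = np.repeat(list(p.forest_types), p.n_sites_per_type)
    sample_ids = [f"{t}{s}" for t, s in zip(types, site_ids)]

    richness = np.array([
        max(1, rng.poisson(p.richness_means[t])) for t in types], dtype=float)
    z_logr = _standardize(np.log(richness))

    # covariates share a latent factor with log richness
    cov = {}
    for name, (mu, sd) in COVARIATE_SCALE.items():
        rho = p.env_richness_cor if name in p.env_effect else 0.0
        z = rho * z_logr + np.sqrt(1.0 - rho ** 2) * rng.standard_normal(n)
        cov[name] = mu + sd * z
    covariates = pd.DataFrame(cov, index=sample_ids)

    site_effect_by_site = p.site_sd * rng.standard_normal(p.n_sites_per_type)
    site_effects = site_effect_by_site[site_ids - 1]

    env_term = np.zeros(n)
    for name, eff in p.env_effect.items():
        env_term += eff * _standardize(covariates[name].to_numpy())

    eta = (p.base_log_pool + p.coupling_beta * np.log(richness)
           + env_term + site_effects + p.noise_sd * rng.standard_normal(n))

    fungal_ids = [f"F{j:04d}" for j in range(p.pool_size_fungi)]
    fungal = np.zeros((n, p.pool_size_fungi), dtype=int)
    realized = np.zeros(n, dtype=int)
    for i in range(n):
        m = int(np.clip(round(np.exp(eta[i])), 1, p.pool_size_fungi))
        realized[i] = m
        if p.sequencing_depth < m:
            warnings.warn(
                f"sequencing depth {p.sequencing_depth} below realized pool "
                f"{m} for sample {sample_ids[i]}; some taxa will be unobserved")
        chosen = rng.choice(p.pool_size_fungi, size=m, replace=False)
        props = rng.dirichlet(np.full(m, p.dirichlet_concentration))
        fungal[i, chosen] = rng.multinomial(p.sequencing_depth, props)
    fungal_table = pd.DataFrame(fungal, index=sample_ids, columns=fungal_ids)

    # bacteria: planted equicorrelated blocks via a Gaussian copula
    membership = planted_partition_truth(p)
    bact_ids = list(membership)
    n_bact = p.pool_size_bacteria
    latent = rng.standard_normal((n, n_bact))
    start = 0
    for size in p.network_block_sizes:
        g = rng.standard_normal(n)[:, None]
        latent[:, start:start + size] = (
            np.sqrt(p.block_rho) * g
            + np.sqrt(1.0 - p.block_rho) * latent[:, start:start + size])
        start += size
    base_logabund = rng.normal(0.0, 1.0, size=n_bact)
    weights = np.exp(base_logabund[None, :] + latent)

    n_planted = sum(p.network_block_sizes)
    eta_b = (p.bacteria_base_log_pool
             + p.bacteria_richness_coupling * np.log(richness))
    bacterial = np.zeros((n, n_bact), dtype=int)
    for i in range(n):
        m = int(np.clip(round(np.exp(eta_b[i])), 1, n_bact))
        keep = np.zeros(n_bact, dtype=bool)
        keep[:n_planted] = True
        background = np.arange(n_planted, n_bact)
        extra = max(0, m - n_planted)
        if extra and background.size:
            keep[rng.choice(background, size=min(extra, background.size),
                            replace=False)] = True
        w = np.where(keep, weights[i], 0.0)
        bacterial[i] = rng.multinomial(p.sequencing_depth, w / w.sum())
    bacterial_table = pd.DataFrame(bacterial, index=sample_ids,
                                   columns=bact_ids)

    metadata = pd.DataFrame({
        "site": [f"S{s}" for s in site_ids],
        "forest_type": types,
        "plant_richness": richness.astype(int),
    }, index=sample_ids).join(covariates)
    metadata.index.name = "sample"

    truth = {
        "params": dataclasses.asdict(p),
        "latent_log_pool": dict(zip(sample_ids, eta.tolist())),
        "realized_em_richness": dict(zip(sample_ids, realized.tolist())),
        "site_effects": {f"S{s + 1}": float(v)
                         for s, v in enumerate(site_effect_by_site)},
        "module_membership": membership,
        "coupling_beta": p.coupling_beta,
    }
    return SyntheticDataset(fungal_table, bacterial_table, metadata, truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_abundance_table(ds.fungal_table, outdir / "fungal_table.tsv")
    write_abundance_table(ds.bacterial_table, outdir / "bacterial_table.tsv")
    write_metadata(ds.metadata, outdir / "metadata.tsv")
    # tuples are not JSON-stable; normalise for byte-identical reruns
    write_json(ds.truth, outdir / "truth.json")
    return outdir
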