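"""End-to-end analysis pipeline over a synthetic (or supplied) study.

Stages: simulate -> alpha/beta diversity -> fungal and cross-kingdom
co-occurrence networks -> per-sample subnetwork complexity -> response
ratios across forest types -> regressions / mixed models / random forest ->
PLS path model.  All artifacts are written as TSV/GraphML/JSON; every
source of randomness derives from the run seed, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import models as md
from . import network as nw
from . import plspm as pm
from . import response_ratio as rr
from .io import RunConfig, write_json, write_network_graphml
from .simulate import SimParams, SyntheticDataset, simulate_dataset, write_dataset

logger = logging.getLogger("emnet")

__all__ = ["run_all"]

ABIOTIC_CANDIDATES = ["SOC", "TN", "LC", "LP", "pH", "NH4", "NO3", "SAP"]


def _write(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kw)


def run_all(config: RunConfig | None = None, outdir: str | Path = "results",
            dataset: SyntheticDataset | None = None,
            sim_params: SimParams | None = None,
            subnetwork_source: str = "global",
            rf_permutations: int = 99, rf_trees: int = 200) -> dict:
    """Run every stage and write its artifacts under ``outdir``.

    ``subnetwork_source``: ``"global"`` (default) extracts per-sample
    subnetworks from the all-sample fungal network; ``"per_type"`` uses the
    forest-type networks instead (with six samples per type the fungal edge
    p-threshold retains only rank-perfect pairs, so per-type subnetworks
    are close to degenerate — kept as an option, not the default).

    Returns a dict of the main in-memory results.
    """
    cfg = config or RunConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("run-all: seed=%d filter=%g fungal edges |rho|>=%g p<=%g",
                cfg.seed, cfg.abundance_filter, cfg.fungal_edge_r,
                cfg.fungal_edge_p)

    # ------------------------------------------------------------ simulate
    if dataset is None:
        params = sim_params or SimParams(seed=cfg.seed)
        dataset = simulate_dataset(params)
    write_dataset(dataset, outdir / "data")
    fungal, bacterial, meta = (dataset.fungal_table, dataset.bacterial_table,
                               dataset.metadata)

    # ----------------------------------------------------------- diversity
    alpha = dv.alpha_diversity(fungal)
    beta = dv.beta_partition(fungal)
    _write(alpha, outdir / "alpha.tsv")
    _write(beta.beta_sor, outdir / "beta_sor.tsv")
    _write(beta.beta_sim, outdir / "beta_sim.tsv")
    _write(beta.beta_sne, outdir / "beta_sne.tsv")
    _write(beta.summary, outdir / "beta_summary.tsv")
    write_json(beta.multi_site, outdir / "beta_multisite.json")

    # ------------------------------------------------------------ networks
    filtered = nw.filter_by_relative_abundance(fungal, cfg.abundance_filter)
    global_net = nw.build_network(filtered, cfg.fungal_edge_r,
                                  cfg.fungal_edge_p,
                                  provenance={"subset": "all"})
    write_network_graphml(global_net, outdir / "network_all.graphml")
    topo_rows = {"all": nw.topology(global_net)}
    type_nets = {}
    for ftype in pd.unique(meta["forest_type"]):
        sub = fungal.loc[meta.index[meta["forest_type"] == ftype]]
        sub_f = nw.filter_by_relative_abundance(sub, cfg.abundance_filter)
        net = nw.build_network(sub_f, cfg.fungal_edge_r, cfg.fungal_edge_p,
                               provenance={"subset": ftype})
        type_nets[ftype] = net
        write_network_graphml(net, outdir / f"network_{ftype}.graphml")
        topo_rows[ftype] = nw.topology(net)
    topo = pd.DataFrame(topo_rows).T.drop(columns="undefined")
    _write(topo, outdir / "topology.tsv")

    # per-sample subnetworks and the multi-complexity index
    if subnetwork_source == "global":
        subnet = nw.sample_subnetworks(global_net, fungal)
    elif subnetwork_source == "per_type":
        parts = []
        for ftype, net in type_nets.items():
            rows = meta.index[meta["forest_type"] == ftype]
            parts.append(nw.sample_subnetworks(net, fungal.loc[rows]))
        subnet = pd.concat(parts).loc[fungal.index]
    else:
        raise ValueError(f"unknown subnetwork_source {subnetwork_source!r}")
    subnet["multi_net"] = nw.multi_net(subnet)
    _write(subnet, outdir / "subnet_metrics.tsv")

    # node roles and keystone correlations on the all-sample network
    indicators = alpha.join(beta.summary).join(subnet)
    indicators["plant_richness"] = meta["plant_richness"].astype(float)
    if global_net.n_edges > 0:
        roles = nw.zi_pi(global_net, seed=cfg.seed,
                         zi_cut=cfg.zi_cut, pi_cut=cfg.pi_cut)
        _write(roles, outdir / "roles.tsv")
        keycorr = nw.keystone_diversity_correlations(roles, fungal, indicators)
        _write(keycorr, outdir / "keystone_correlations.tsv", index=False)
    else:
        roles = None
        keycorr = pd.DataFrame()
        logger.warning("all-sample fungal network is empty; skipping roles")

    # cross-kingdom network and per-sample biotic factors
    bact_f = nw.filter_by_relative_abundance(bacterial, cfg.abundance_filter)
    joint = nw.crosskingdom_table(filtered, bact_f)
    ck_net = nw.build_network(joint, cfg.crosskingdom_edge_r,
                              cfg.crosskingdom_edge_p,
                              provenance={"subset": "cross-kingdom"})
    write_network_graphml(ck_net, outdir / "network_crosskingdom.graphml")
    biotic = nw.biotic_factors(ck_net, filtered, bact_f)
    _write(biotic, outdir / "biotic_factors.tsv")

    # ------------------------------------------------------ response ratios
    metrics = alpha.join(beta.summary).join(subnet)
    respratio = rr.response_ratio_table(metrics, meta["forest_type"],
                                        control="PF")
    _write(respratio, outdir / "respratio.tsv", index=False)

    # ---------------------------------------------------------- regressions
    regressions = md.fit_diversity_regressions(metrics, meta)
    _write(regressions, outdir / "regressions.tsv", index=False)

    anova_rows = []
    for metric in metrics.columns:
        res = md.anova_duncan(metrics[metric].to_numpy(),
                              meta["forest_type"].to_numpy())
        for g, letter in res["letters"].items():
            anova_rows.append({"metric": metric, "group": g,
                               "mean": res["means"][g], "letters": letter,
                               "F": res["F"], "p": res["p"]})
    _write(pd.DataFrame(anova_rows), outdir / "anova.tsv", index=False)

    # --------------------------------------- collinearity screen and LMM
    abio_keep, abio_drop = md.collinearity_filter(
        meta[ABIOTIC_CANDIDATES], cut=cfg.collinearity_cut)
    bio_keep, bio_drop = md.collinearity_filter(
        biotic, cut=cfg.collinearity_cut)
    write_json({"abiotic_retained": abio_keep, "abiotic_dropped": abio_drop,
                "biotic_retained": bio_keep, "biotic_dropped": bio_drop},
               outdir / "collinearity.json")

    ln_plant = np.log(meta["plant_richness"].to_numpy(dtype=float))
    env_table = meta[abio_keep].join(biotic[bio_keep])
    lmm_rows = []
    for metric in ("shannon", "richness", "multi_net"):
        y = metrics[metric].to_numpy(dtype=float)
        resp = "log" if (y > 0).all() else "raw"
        for env_name in env_table.columns:
            try:
                res = md.fit_interaction_lmm(
                    y, ln_plant, env_table[env_name].to_numpy(),
                    meta["site"].to_numpy(), env_name=env_name,
                    response=resp)
            except (ValueError, RuntimeError) as exc:
                logger.warning("LMM %s ~ %s failed: %s", metric, env_name, exc)
                continue
            fe = res.fixed_effects
            lmm_rows.append({
                "metric": metric, "env": env_name,
                "intercept": fe.loc["Intercept", "estimate"],
                "plant_slope": fe.loc["plant", "estimate"],
                "env_effect": fe.loc["env", "estimate"],
                "interaction": fe.loc["plant:env", "estimate"],
                "interaction_p": fe.loc["plant:env", "p"],
                "site_var": res.site_variance,
                "resid_var": res.residual_variance,
                "method": res.method, "converged": res.converged})
    _write(pd.DataFrame(lmm_rows), outdir / "lmm_table.tsv", index=False)

    # ------------------------------------------------------- random forest
    rf_rows = []
    for label, cols in (("abiotic", abio_keep), ("biotic", bio_keep)):
        X = env_table[cols].copy()
        X["plant_richness"] = meta["plant_richness"].astype(float)
        res = md.rf_contributions(metrics["shannon"].to_numpy(), X,
                                  seed=cfg.seed, n_estimators=rf_trees,
                                  n_permutations=rf_permutations)
        for var, pct in res.contributions_pct.items():
            rf_rows.append({"set": label, "variable": var,
                            "contribution_pct": pct,
                            "explained_variance": res.explained_variance,
                            "p_model": res.p_model})
    _write(pd.DataFrame(rf_rows), outdir / "rf_importance.tsv", index=False)

    # -------------------------------------------------------------- PLS-PM
    axes = pm.pca_axes(pm.bray_curtis(fungal), k=2)
    ind = pd.DataFrame({
        "plant_richness": meta["plant_richness"].astype(float),
        "beta_axis1": axes["Axis1"], "beta_axis2": axes["Axis2"],
    }, index=meta.index)
    ind = ind.join(meta[["SOC", "TN", "LC", "LP"]]) \
             .join(biotic[["Assort", "Avgdist", "Ceneig"]]) \
             .join(alpha).join(subnet)
    blocks, paths = pm.default_path_spec()
    # indicators constant on this dataset cannot enter a latent block
    blocks = {l: [c for c in cols if ind[c].std() > 0]
              for l, cols in blocks.items()}
    model = pm.PLSPathModel(blocks=blocks, paths=paths,
                            bootstrap_n=cfg.bootstrap_n, seed=cfg.seed).fit(ind)
    _write(model.boot_ if model.boot_ is not None
           else model.path_coefficients_.stack().rename("estimate").reset_index(),
           outdir / "plspm_paths.tsv", index=False)
    _write(model.effects_, outdir / "plspm_effects.tsv", index=False)
    _write(model.scores_, outdir / "plspm_scores.tsv")
    write_json({"gof": model.gof_, "r_squared": model.r_squared_.to_dict(),
                "n": model.n_samples_}, outdir / "plspm_gof.json")

    return {"dataset": dataset, "alpha": alpha, "beta": beta,
            "topology": topo, "global_net": global_net,
            "type_nets": type_nets, "subnet": subnet, "roles": roles,
            "keystone_correlations": keycorr, "biotic": biotic,
            "respratio": respratio, "regressions": regressions,
            "lmm": pd.DataFrame(lmm_rows), "plspm": model}
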