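"""End-to-end pipeline orchestration from a single YAML/dict config.

Stage order mirrors the analysis workflow: simulate-or-ingest ->
filter -> ploidy -> kinship pruning -> diversity -> structure -> AMOVA
-> leaf morphometrics -> RDA.  Clustering/PCA runs on the filtered but
unpruned dataset; kinship pruning is applied before the diversity, FST
and AMOVA stages (related individuals bias those statistics, while
ordination merely displays them).  Any stage can be skipped by config.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div_mod
from . import filtering, kinship, morpho, ploidy, rda, sim, structure, vcfio
from .amova import amova_uncertainty

log = logging.getLogger(__name__)

DEFAULT_STAGES = [
    "simulate", "filter", "ploidy", "kinship", "diversity",
    "structure", "amova", "leaves", "rda",
]


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Run the configured stages; returns the machine-readable report.

    ``config`` is a dict or a path to a YAML file.  Recognised keys:
    ``seed``, ``stages`` (subset of the default order), ``simulation``
    (SimConfig fields), ``vcf`` (input path, alternative to simulation),
    ``filter`` (FilterConfig fields), ``kinship_cutoff``, ``amova_perm``,
    ``rda_perm``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", DEFAULT_STAGES)
    report: dict = {"config_hash": _config_hash(config), "seed": seed, "stages": []}

    def record(name: str, t0: float, **info) -> None:
        report["stages"].append(
            {"stage": name, "seconds": round(time.time() - t0, 3), **info}
        )

    ds = depths = None
    leaf = env = None

    if "simulate" in stages:
        t0 = time.time()
        sim_cfg = sim.SimConfig(**{**config.get("simulation", {}), "seed": seed})
        ds = sim.simulate_structured_genotypes(sim_cfg)
        rel = config.get("relatives", {})
        if rel:
            ds = sim.inject_relatives(ds, seed=seed + 1, **rel)
        depths = sim.simulate_read_depths(ds, mean_depth=sim_cfg.mean_depth, seed=seed + 2)
        leaf, env = sim.simulate_traits_and_environment(ds, seed=seed + 3)
        vcfio.write_vcf(ds, depths, out / "simulated.vcf")
        record("simulate", t0, n_individuals=ds.n_individuals, n_sites=ds.n_sites)
    elif "vcf" in config:
        t0 = time.time()
        ds, depths = vcfio.read_vcf(config["vcf"])
        meta = pd.read_csv(config["metadata"], sep="\t")
        order = pd.Index(meta["sample"]).get_indexer(ds.sample_ids)
        ds.locality_labels = meta["locality"].to_numpy()[order]
        if "group" in meta:
            ds.group_labels = meta["group"].to_numpy()[order]
        if {"x", "y"} <= set(meta.columns):
            ds.coordinates = meta[["x", "y"]].to_numpy(float)[order]
        record("ingest", t0, n_individuals=ds.n_individuals, n_sites=ds.n_sites)
    else:
        raise ValueError("config needs either a simulation block or a vcf path")

    if "filter" in stages:
        t0 = time.time()
        fcfg = filtering.FilterConfig(**config.get("filter", {}))
        ds, rep = filtering.apply_site_and_individual_filters(ds, depths, fcfg)
        if depths is not None:
            depths = depths.take_individuals(rep.individual_index).take_sites(rep.site_index)
        ds, _removed = filtering.ld_prune(ds, fcfg)
        ds, _neg, ftab = filtering.filter_negative_f(ds, fcfg, seed=seed + 4)
        rep.to_json(out / "filter_report.json")
        ftab.to_csv(out / "site_f.tsv", sep="\t", index=False)
        # realign depths to surviving sites
        if depths is not None:
            keep = pd.Index(ftab.loc[~ftab.removed, "site_id"])
            site_idx = pd.Index(ftab["site_id"]).get_indexer(keep)
            depths = depths.take_sites(site_idx)
        record("filter", t0, n_individuals=ds.n_individuals, n_sites=ds.n_sites)

    if "ploidy" in stages and depths is not None:
        t0 = time.time()
        calls = ploidy.classify_all(ds, depths)
        pd.DataFrame(
            [{"sample": c.individual_id, "call": c.call, "margin": c.margin} for c in calls]
        ).to_csv(out / "ploidy.tsv", sep="\t", index=False)
        record("ploidy", t0, n_diploid=sum(1 for c in calls if c.call == 2))

    pruned = ds
    if "kinship" in stages:
        t0 = time.time()
        km = kinship.king_kinship(ds)
        km.to_frame().to_csv(out / "kinship.tsv", sep="\t")
        kept, removed = kinship.prune_related(
            km, float(config.get("kinship_cutoff", kinship.KING_CUTOFF)),
            individual_missingness=ds.missing_mask().mean(axis=1),
        )
        keep_idx = np.flatnonzero(np.isin(ds.sample_ids, kept))
        pruned = ds.take_individuals(keep_idx)
        kinship.locality_mean_kinship(km, ds.locality_labels).to_csv(out / "locality_kinship.tsv", sep="\t")
        record("kinship", t0, n_removed=len(removed))

    if "diversity" in stages:
        t0 = time.time()
        stats = div_mod.locality_diversity(pruned)
        div_mod.diversity_frame(stats).to_csv(out / "diversity.tsv", sep="\t", index=False)
        record("diversity", t0, n_localities=len(stats))

    if "structure" in stages:
        t0 = time.time()
        fst = structure.pairwise_fst(pruned)
        fst.to_frame().to_csv(out / "fst.tsv", sep="\t")
        newick = structure.nj_tree(fst.clamped, fst.localities)
        (out / "nj.nwk").write_text(newick + "\n")
        scan = structure.kmeans_bic_scan(ds, seed=seed + 5)
        pd.DataFrame({"K": scan.k_values, "BIC": scan.bic}).to_csv(out / "bic.tsv", sep="\t", index=False)
        probs = structure.lda_assign(scan.pc_scores, scan.assignments) if scan.best_k > 1 else None
        record("structure", t0, best_k=scan.best_k)

    if "amova" in stages:
        t0 = time.time()
        res = amova_uncertainty(
            pruned,
            n_perm=int(config.get("amova_perm", 199)),
            n_bootstrap=int(config.get("amova_bootstrap", 200)),
            seed=seed + 6,
        )
        res.to_frame().to_csv(out / "amova.tsv", sep="\t", index=False)
        record("amova", t0, percent_var=[round(v, 2) for v in res.percent_var])

    if "leaves" in stages and leaf is not None:
        t0 = time.time()
        derived = morpho.leaf_metrics(leaf)
        derived.to_csv(out / "leaf_traits.tsv", sep="\t", index=False)
        pca = morpho.trait_pca_anova(derived)
        record("leaves", t0, pc1_var=float(pca["explained_variance_ratio"][0]))

    if "rda" in stages and env is not None:
        t0 = time.time()
        freqs, locs = rda.locality_allele_frequencies(pruned)
        env_df = env.table.set_index("locality").loc[locs]
        space = rda.spatial_polynomials(env_df[["x", "y"]].to_numpy())
        n_perm = int(config.get("rda_perm", 499))
        # forward-select spatial terms first so conditioning stays low-rank
        sel = rda.forward_select(freqs, space, None, n_perm=n_perm, seed=seed + 8)
        space_sel = space[sel] if sel else space[["x", "y"]]
        model = rda.rda_fit(
            freqs, env_df[env.env_columns].to_numpy(), space_sel.to_numpy(),
            n_perm=n_perm, seed=seed + 7,
        )
        part = rda.variance_partition(
            freqs, env_df[env.env_columns].to_numpy(), space_sel.to_numpy()
        )
        json_path = out / "rda.json"
        json_path.write_text(json.dumps({
            "r2": model.r2, "adj_r2": model.adj_r2, "pseudo_F": model.pseudo_f,
            "p": model.p_value,
            "varpart": {"a_env": part.a_env, "b_shared": part.b_shared,
                        "c_space": part.c_space, "d_resid": part.d_resid},
        }, indent=2))
        record("rda", t0, r2=round(model.r2, 4), p=model.p_value)

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
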