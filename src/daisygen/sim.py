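"""Synthetic genotype, read-depth, leaf-trait and environment generator.

Every downstream stage of the pipeline is tested against data produced
here, with the generating parameters recorded as ground truth.  The
population model is a two-level (groups > localities) Balding-Nichols
hierarchy: subpopulation allele frequencies are Beta-distributed around
the ancestral frequency with variance controlled by the configured FST,
and genotypes are drawn with a heterozygote deficit controlled by FIS.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, AlleleDepthTable, EnvTable, GenotypeDataset, LeafTable

# Allowed reference-allele dosages at a heterozygous site, per ploidy.
DOSAGE_SETS: dict[int, tuple[float, ...]] = {
    2: (1 / 2,),
    3: (1 / 3, 2 / 3),
    4: (1 / 4, 1 / 2, 3 / 4),
}


@dataclass
class SimConfig:
    """Parameters of the hierarchical population simulation.

    Defaults emulate a fragmented-plant study design: ~25 localities
    nested in 3 strongly diverged groups, 7 diploid individuals per
    locality (~175 total), ~10,000 biallelic SNPs, moderate within-
    locality inbreeding, and reduced-representation read depths around
    20x.
    """

    n_groups: int = 3
    n_localities_per_group: int = 8
    n_individuals_per_locality: int = 7
    n_snps: int = 10_000
    fst_between_groups: float = 0.3
    fst_between_localities: float = 0.05
    inbreeding_fis: float = 0.15
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    mean_depth: float = 20.0
    missing_rate: float = 0.05
    gea_n_cline_loci: int = 50
    gea_slope: float = 0.0
    env_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "n_localities_per_group", "n_individuals_per_locality", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("fst_between_groups", "fst_between_localities", "inbreeding_fis"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


def _beta_around(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Balding-Nichols draw: Beta with mean p and variance p(1-p)*fst.

    fst = 0 degenerates to a point mass at p.
    """
    if fst == 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    a = p * scale
    b = (1.0 - p) * scale
    out = rng.beta(a, b)
    # guard against numerically fixed frequencies
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def simulate_structured_genotypes(config: SimConfig) -> GenotypeDataset:
    """Draw genotypes from the nested Balding-Nichols model.

    Ancestral frequencies are Uniform over ``ancestral_maf_range``; group
    frequencies diverge with ``fst_between_groups``; locality frequencies
    diverge from their group with ``fst_between_localities``.  Within a
    locality with frequency p, genotype probabilities follow the
    inbreeding model P(het) = 2pq(1 - FIS).  Missing calls are injected
    uniformly at random at ``missing_rate``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_snps
    n_loc = cfg.n_groups * cfg.n_localities_per_group
    n_ind = n_loc * cfg.n_individuals_per_locality

    lo, hi = cfg.ancestral_maf_range
    p0 = rng.uniform(lo, hi, size=L)
    p_group = np.stack(
        [_beta_around(rng, p0, cfg.fst_between_groups) for _ in range(cfg.n_groups)]
    )  # (G, L)
    p_loc = np.empty((n_loc, L))
    loc_group = np.repeat(np.arange(cfg.n_groups), cfg.n_localities_per_group)
    for j in range(n_loc):
        p_loc[j] = _beta_around(rng, p_group[loc_group[j]], cfg.fst_between_localities)

    # locality coordinates on a unit grid, individuals jittered around them
    grid = int(np.ceil(np.sqrt(n_loc)))
    loc_xy = np.column_stack(
        [np.arange(n_loc) % grid, np.arange(n_loc) // grid]
    ).astype(float) / max(grid - 1, 1)

    ind_loc = np.repeat(np.arange(n_loc), cfg.n_individuals_per_locality)
    coords = loc_xy[ind_loc] + rng.normal(0.0, 0.01, size=(n_ind, 2))

    # Environment per locality: a gradient along x plus locality-level
    # variation that is NOT a function of the coordinates — without it a
    # planted cline would be fully absorbed by spatial conditioning.
    cline_loci = np.array([], dtype=int)
    env_at_loc = loc_xy[:, 0] + rng.normal(0.0, cfg.env_noise_sd, n_loc)
    p_ind = p_loc[ind_loc]  # (n_ind, L)
    if cfg.gea_n_cline_loci > 0 and cfg.gea_slope != 0.0:
        cline_loci = rng.choice(L, size=min(cfg.gea_n_cline_loci, L), replace=False)
        cline_loci.sort()
        shift = cfg.gea_slope * (env_at_loc[ind_loc] - env_at_loc.mean())
        pc = np.clip(p_ind[:, cline_loci], 1e-9, 1 - 1e-9)
        logit = np.log(pc / (1 - pc)) + shift[:, None]
        p_ind = p_ind.copy()
        p_ind[:, cline_loci] = 1.0 / (1.0 + np.exp(-logit))

    q = 1.0 - p_ind
    fis = cfg.inbreeding_fis
    pr_hom_alt = p_ind**2 + fis * p_ind * q
    pr_het = 2 * p_ind * q * (1 - fis)
    u = rng.random((n_ind, L))
    calls = np.where(u < pr_hom_alt, 2, np.where(u < pr_hom_alt + pr_het, 1, 0)).astype(np.int8)

    if cfg.missing_rate > 0:
        calls[rng.random((n_ind, L)) < cfg.missing_rate] = MISSING

    group_names = np.array([f"G{g + 1}" for g in range(cfg.n_groups)])
    loc_names = np.array(
        [f"L{loc_group[j] + 1}_{j % cfg.n_localities_per_group + 1}" for j in range(n_loc)]
    )
    ds = GenotypeDataset(
        calls=calls,
        sample_ids=np.array([f"ind{i:04d}" for i in range(n_ind)]),
        locality_labels=loc_names[ind_loc],
        group_labels=group_names[loc_group[ind_loc]],
        coordinates=coords,
        site_ids=np.array([f"snp{j:05d}" for j in range(L)]),
        truth={
            "config": dataclasses.asdict(cfg),
            "p_ancestral": p0,
            "p_group": p_group,
            "p_locality": p_loc,
            "cline_loci": cline_loci,
            "locality_names": loc_names,
            "env_at_locality": env_at_loc,
            "relative_pairs": [],
        },
    )
    return ds


def inject_relatives(
    ds: GenotypeDataset,
    n_clone_pairs: int = 0,
    n_parent_offspring_pairs: int = 0,
    n_fullsib_pairs: int = 0,
    seed: int = 0,
) -> GenotypeDataset:
    """Overwrite individuals within localities to create known related pairs.

    Clones copy the genotype row exactly; offspring draw one allele from
    each parent per locus (full sibs share the same two parents).  The
    planted pairs and their relationship labels are appended to the truth
    record.  Each relationship consumes individuals from a single
    locality; a capacity error is raised if a locality runs out.
    """
    rng = np.random.default_rng(seed)
    calls = ds.calls.copy()
    pairs: list[tuple[int, int, str]] = []
    # pool of per-locality unused indices
    free: dict[str, list[int]] = {}
    for i, loc in enumerate(ds.locality_labels):
        free.setdefault(str(loc), []).append(i)

    def take(loc_needed: int) -> list[int]:
        for loc in sorted(free):
            if len(free[loc]) >= loc_needed:
                out = [free[loc].pop(0) for _ in range(loc_needed)]
                return out
        raise ValueError("not enough unused individuals in any one locality")

    def mate(a: int, b: int) -> np.ndarray:
        """One offspring genotype: one allele from each parent per locus."""
        ga, gb = calls[a].astype(np.int16), calls[b].astype(np.int16)
        allele_a = (rng.random(ga.shape) < ga / 2.0).astype(np.int8)
        allele_b = (rng.random(gb.shape) < gb / 2.0).astype(np.int8)
        child = (allele_a + allele_b).astype(np.int8)
        child[(ga == MISSING) | (gb == MISSING)] = MISSING
        return child

    for _ in range(n_clone_pairs):
        a, b = take(2)
        calls[b] = calls[a]
        pairs.append((a, b, "clone"))
    for _ in range(n_parent_offspring_pairs):
        a, b, c = take(3)  # parents a, b; child written over c
        calls[c] = mate(a, b)
        pairs.append((a, c, "parent-offspring"))
    for _ in range(n_fullsib_pairs):
        a, b, c, d = take(4)
        calls[c] = mate(a, b)
        calls[d] = mate(a, b)
        pairs.append((c, d, "full-sib"))

    truth = dict(ds.truth or {})
    truth["relative_pairs"] = list(truth.get("relative_pairs", [])) + pairs
    return dataclasses.replace(ds, calls=calls, truth=truth)


def simulate_read_depths(
    ds: GenotypeDataset,
    ploidy_map: np.ndarray | None = None,
    mean_depth: float = 20.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> AlleleDepthTable:
    """Draw per-genotype read counts consistent with each individual's ploidy.

    Depth is Poisson(mean_depth) per genotype.  At GT-heterozygous sites
    the reference-read fraction is drawn uniformly from the ploidy's
    allowed dosage set — {1/2} for diploids, {1/3, 2/3} for triploids,
    {1/4, 1/2, 3/4} for tetraploids — then reference reads are
    Binomial(depth, fraction).  Homozygous sites use fraction 1 - eps or
    eps, modelling a small sequencing-error rate.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    n, L = ds.calls.shape
    if ploidy_map is None:
        ploidy_map = np.full(n, 2, dtype=int)
    ploidy_map = np.asarray(ploidy_map, dtype=int)
    bad = set(np.unique(ploidy_map)) - set(DOSAGE_SETS)
    if bad:
        raise ValueError(f"unsupported ploidy values: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=(n, L)).astype(np.int32)
    depth[ds.calls == MISSING] = 0

    frac = np.where(ds.calls == 0, 1.0 - error_rate, error_rate)
    het = ds.calls == 1
    for p, dosages in DOSAGE_SETS.items():
        rows = ploidy_map == p
        if not rows.any():
            continue
        idx = rng.integers(0, len(dosages), size=(int(rows.sum()), L))
        frac[rows] = np.where(het[rows], np.asarray(dosages)[idx], frac[rows])

    ref = rng.binomial(depth, frac).astype(np.int32)
    alt = depth - ref
    return AlleleDepthTable(ref_reads=ref, alt_reads=alt, ploidy_truth=ploidy_map)


def simulate_traits_and_environment(
    ds: GenotypeDataset,
    group_trait_means: dict[str, tuple[float, float, float]] | None = None,
    trait_cov: np.ndarray | None = None,
    env_gradient: float = 1.0,
    noise_sd: float = 0.1,
    leaves_per_individual: int = 5,
    seed: int = 0,
) -> tuple[LeafTable, EnvTable]:
    """Generate leaf measurements per individual and one environment variable.

    Leaf (L, W, WL) rows are drawn from a group-specific multivariate
    normal, truncated so that L, W > 0 and 0 < WL < L.  The environment
    variable is linear in the x coordinate (slope ``env_gradient``) plus
    Gaussian noise, evaluated at each locality.
    """
    rng = np.random.default_rng(seed)
    groups = np.unique(ds.group_labels)
    if group_trait_means is None:
        # distinct sizes, shared ovality ~0.45: group separation on the size axis
        base = {g: (60.0 + 25.0 * k, 30.0 + 12.0 * k) for k, g in enumerate(groups)}
        group_trait_means = {g: (l, w, 0.45 * l) for g, (l, w) in base.items()}
    if trait_cov is None:
        trait_cov = np.diag([25.0, 9.0, 9.0])
    trait_cov = np.asarray(trait_cov, dtype=float)
    try:
        np.linalg.cholesky(trait_cov + 1e-12 * np.eye(3))
    except np.linalg.LinAlgError as exc:
        raise ValueError("trait covariance must be positive (semi-)definite") from exc
    missing = set(map(str, groups)) - set(group_trait_means)
    if missing:
        raise ValueError(f"no trait means for groups: {sorted(missing)}")

    rows = []
    for i in range(ds.n_individuals):
        mu = np.asarray(group_trait_means[str(ds.group_labels[i])], dtype=float)
        for leaf in range(leaves_per_individual):
            for _ in range(100):
                l_, w_, wl_ = rng.multivariate_normal(mu, trait_cov)
                if l_ > 0 and w_ > 0 and 0 < wl_ < l_:
                    break
            else:  # pragma: no cover - pathological parameters
                l_, w_, wl_ = mu
            rows.append(
                {
                    "sample": ds.sample_ids[i],
                    "locality": ds.locality_labels[i],
                    "group": ds.group_labels[i],
                    "leaf": leaf + 1,
                    "L": l_,
                    "W": w_,
                    "WL": wl_,
                }
            )
    leaf = LeafTable(pd.DataFrame(rows))

    locs, first = np.unique(ds.locality_labels, return_index=True)
    # locality coordinate = mean of member individuals
    xy = np.vstack(
        [ds.coordinates[ds.locality_labels == loc].mean(axis=0) for loc in locs]
    )
    # reuse the environment the genotype simulation planted its cline on,
    # so the measured variable is the one the cline loci respond to
    if ds.truth is not None and "env_at_locality" in ds.truth:
        order = {str(l): i for i, l in enumerate(ds.truth["locality_names"])}
        base = np.asarray(ds.truth["env_at_locality"])[[order[str(l)] for l in locs]]
    else:
        base = xy[:, 0]
    env = env_gradient * base + rng.normal(0.0, noise_sd, size=len(locs))
    env_df = pd.DataFrame(
        {"locality": locs, "x": xy[:, 0], "y": xy[:, 1], "env1": env}
    )
    return leaf, EnvTable(env_df, env_columns=["env1"])
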