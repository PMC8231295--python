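"""SNP and individual filtering cascade.

Stages, in order: depth masking of individual genotypes, minor-allele-
frequency filter, per-site missingness, per-individual missingness, LD
pruning, and removal of SNPs with significantly negative inbreeding
coefficient (an excess-heterozygosity signature of stacked paralogs),
assessed by a permutation test that re-pairs allele copies.

Depth masking runs before the MAF filter: masking changes the set of
non-missing calls, so computing MAF afterwards keeps the cascade
self-consistent and idempotent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import MISSING, AlleleDepthTable, GenotypeDataset
from .vcfio import read_vcf, write_vcf  # noqa: F401  (re-exported; cascade input/output)


@dataclass
class FilterConfig:
    """Thresholds of the filtering cascade.

    Boundary conventions are strict as printed: a genotype is masked when
    depth < min_depth, a site dropped when MAF < min_maf, and sites or
    individuals dropped when missingness exceeds (>) the maximum.
    """

    min_maf: float = 0.1
    min_depth: int = 10
    max_site_missing: float = 0.25
    max_ind_missing: float = 0.25
    ld_r2_max: float = 0.8
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    negf_n_perm: int = 10_000
    negf_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_maf", "max_site_missing", "max_ind_missing", "ld_r2_max", "negf_alpha"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("min_depth", "ld_window_snps", "ld_step_snps", "negf_n_perm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FilterReport:
    """Per-stage removal counts plus surviving ids and index arrays."""

    stages: list[dict] = field(default_factory=list)
    surviving_sample_ids: np.ndarray | None = None
    surviving_site_ids: np.ndarray | None = None
    individual_index: np.ndarray | None = None  # into the input dataset
    site_index: np.ndarray | None = None

    def add(self, stage: str, sites_removed: int = 0, individuals_removed: int = 0,
            genotypes_masked: int = 0) -> None:
        self.stages.append(
            {
                "stage": stage,
                "sites_removed": int(sites_removed),
                "individuals_removed": int(individuals_removed),
                "genotypes_masked": int(genotypes_masked),
            }
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": self.stages,
            "surviving_sample_ids": [
                str(s) for s in (self.surviving_sample_ids if self.surviving_sample_ids is not None else [])
            ],
            "surviving_site_ids": [
                str(s) for s in (self.surviving_site_ids if self.surviving_site_ids is not None else [])
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _maf(calls: np.ndarray) -> np.ndarray:
    """Minor allele frequency per site over non-missing calls."""
    ok = calls != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def apply_site_and_individual_filters(
    ds: GenotypeDataset,
    depths: AlleleDepthTable | None,
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeDataset, FilterReport]:
    """Run depth masking, MAF, site- and individual-missingness filters.

    Returns the filtered dataset and a report whose ``individual_index``
    and ``site_index`` map survivors back to the input (use them to
    subset an aligned AlleleDepthTable).
    """
    cfg = cfg or FilterConfig()
    report = FilterReport()
    calls = ds.calls.copy()

    n_masked = 0
    if depths is not None:
        if depths.ref_reads.shape != calls.shape:
            raise ValueError("depth table shape does not match calls")
        low = (depths.depth < cfg.min_depth) & (calls != MISSING)
        n_masked = int(low.sum())
        calls[low] = MISSING
    report.add("depth_mask", genotypes_masked=n_masked)

    maf = _maf(calls)
    keep_sites = ~(np.isnan(maf) | (maf < cfg.min_maf))
    report.add("maf", sites_removed=int((~keep_sites).sum()))
    calls = calls[:, keep_sites]
    site_index = np.flatnonzero(keep_sites)

    if calls.shape[1]:
        site_miss = (calls == MISSING).mean(axis=0)
        ok = site_miss <= cfg.max_site_missing
        report.add("site_missingness", sites_removed=int((~ok).sum()))
        calls = calls[:, ok]
        site_index = site_index[ok]

    if calls.shape[1] == 0:
        raise ValueError("all sites removed by filters")

    ind_miss = (calls == MISSING).mean(axis=1)
    keep_ind = ind_miss <= cfg.max_ind_missing
    report.add("individual_missingness", individuals_removed=int((~keep_ind).sum()))
    if not keep_ind.any():
        raise ValueError("all individuals removed by filters")
    ind_index = np.flatnonzero(keep_ind)

    out = ds.take_sites(site_index).take_individuals(ind_index)
    out.calls = calls[keep_ind]
    report.surviving_sample_ids = out.sample_ids
    report.surviving_site_ids = out.site_ids
    report.individual_index = ind_index
    report.site_index = site_index
    return out, report


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosages over pairwise-complete rows.

    Zero-variance sites get r^2 = 0 against everything.
    """
    m = calls.shape[1]
    x = np.ma.masked_equal(calls.astype(float), MISSING)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.ma.corrcoef(x.T, allow_masked=True)
    r2 = np.asarray(c.filled(0.0)) ** 2
    np.fill_diagonal(r2, 0.0)
    return np.clip(r2, 0.0, 1.0)[:m, :m]


def ld_prune(
    ds: GenotypeDataset, cfg: FilterConfig | None = None, windowless: bool = False
) -> tuple[GenotypeDataset, np.ndarray]:
    """Sliding-window LD pruning of linked SNP pairs (r^2 > threshold).

    Within each window, while any retained pair exceeds ``ld_r2_max``,
    the member of the strongest pair with the higher missingness is
    removed (ties: the larger site index).  ``windowless=True`` compares
    all pairs at once.
    """
    cfg = cfg or FilterConfig()
    m = ds.n_sites
    if m < 2:
        return ds, np.array([], dtype=ds.site_ids.dtype)
    miss = (ds.calls == MISSING).mean(axis=0)
    removed = np.zeros(m, dtype=bool)

    if windowless:
        starts = [0]
        width = m
    else:
        width = cfg.ld_window_snps
        starts = list(range(0, max(m - 1, 1), cfg.ld_step_snps))

    for s in starts:
        idx = np.flatnonzero(~removed[s : s + width]) + s
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(ds.calls[:, idx])
        while True:
            i, j = np.unravel_index(np.argmax(r2), r2.shape)
            if r2[i, j] <= cfg.ld_r2_max:
                break
            a, b = idx[i], idx[j]
            # drop the worse-covered member; ties go to the later site
            if miss[a] > miss[b]:
                drop_local, drop = i, a
            elif miss[b] > miss[a]:
                drop_local, drop = j, b
            else:
                drop_local, drop = (i, a) if a > b else (j, b)
            removed[drop] = True
            r2[drop_local, :] = 0.0
            r2[:, drop_local] = 0.0

    keep = np.flatnonzero(~removed)
    return ds.take_sites(keep), ds.site_ids[removed]


def _het_pairing_pmf(n: int, n_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of the heterozygote count under allele re-pairing.

    2n allele copies carrying ``n_alt`` alternate alleles are randomly
    re-paired into n genotypes; returns the support and probabilities of
    the number of heterozygotes.  This is the null the permutation test
    samples from.
    """
    h_max = min(n_alt, 2 * n - n_alt)
    hs = np.arange(n_alt % 2, h_max + 1, 2)
    j = (n_alt - hs) / 2.0  # hom-alt genotype count
    logp = (
        gammaln(n + 1)
        - gammaln(j + 1)
        - gammaln(hs + 1)
        - gammaln(n - j - hs + 1)
        + hs * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(n_alt + 1) - gammaln(2 * n - n_alt + 1))
    )
    p = np.exp(logp - logp.max())
    return hs, p / p.sum()


def sample_het_counts(
    n: int, n_alt: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_perm`` heterozygote counts from the allele re-pairing null."""
    hs, p = _het_pairing_pmf(n, n_alt)
    if hs.size == 1:
        return np.full(n_perm, hs[0])
    cdf = np.cumsum(p)
    return hs[np.searchsorted(cdf, rng.random(n_perm), side="right").clip(0, hs.size - 1)]


def site_f_statistics(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (F, Ho, He) with Nei's unbiased He; NaN where undefined."""
    ok = calls != MISSING
    n = ok.sum(axis=0).astype(float)
    het = ((calls == 1) & ok).sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n)
        ho = het / n
        he = np.where(n > 1, (2 * n / (2 * n - 1)) * 2 * p * (1 - p), np.nan)
        f = np.where(he > 0, 1.0 - ho / he, np.nan)
    return f, ho, he


def filter_negative_f(
    ds: GenotypeDataset, cfg: FilterConfig | None = None, seed: int = 0
) -> tuple[GenotypeDataset, np.ndarray, pd.DataFrame]:
    """Remove SNPs with significantly negative inbreeding coefficient F.

    Per site F = 1 - Ho/He (He in Nei's unbiased form).  The null
    re-pairs the 2N observed allele copies into N genotypes at random;
    the one-tailed p-value is the proportion of permuted F values at or
    below the observed one.  Sites with F < 0 and p < alpha are removed;
    monomorphic sites (He = 0) are untested and retained.
    """
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(seed)
    f, ho, he = site_f_statistics(ds.calls)
    ok = ds.calls != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, ds.calls, 0).sum(axis=0)
    het = ((ds.calls == 1) & ok).sum(axis=0)

    m = ds.n_sites
    pvals = np.full(m, np.nan)
    remove = np.zeros(m, dtype=bool)
    testable = np.flatnonzero((he > 0) & (n >= 5))
    for j in testable:
        # F is monotone decreasing in the het count at fixed allele counts,
        # so compare het counts directly: P(F_perm <= F_obs) = P(H_perm >= H_obs)
        h_null = sample_het_counts(int(n[j]), int(alt[j]), cfg.negf_n_perm, rng)
        pvals[j] = (np.count_nonzero(h_null >= het[j]) + 1) / (cfg.negf_n_perm + 1)
        remove[j] = (f[j] < 0) and (pvals[j] < cfg.negf_alpha)

    table = pd.DataFrame(
        {"site_id": ds.site_ids, "F": f, "Ho": ho, "He": he, "p": pvals, "removed": remove}
    )
    keep = np.flatnonzero(~remove)
    return ds.take_sites(keep), ds.site_ids[remove], table
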