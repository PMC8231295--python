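"""Per-locality diversity statistics: Ho, He (Nei-unbiased), Gis.

Locality values are across-locus means; the inbreeding coefficient is
the ratio of averages, Gis = 1 - mean(Ho)/mean(He), matching the G-stats
convention, with an allele re-pairing permutation test for significance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset
from .filtering import sample_het_counts


@dataclass
class DiversityStats:
    locality: str
    ho: float
    he: float
    gis: float
    n_individuals: int
    n_polymorphic_sites: int
    p_value: float | None = None


def refilter_mac(
    ds: GenotypeDataset, group_labels: np.ndarray | None = None, min_mac: int = 1
) -> dict[str, GenotypeDataset]:
    """Split by group and drop sites below the minor-allele-count floor.

    With the default ``min_mac=1`` this removes sites monomorphic within
    the group (non-variants) while keeping them in groups where they
    still segregate.
    """
    labels = np.asarray(group_labels if group_labels is not None else ds.group_labels)
    out: dict[str, GenotypeDataset] = {}
    for g in pd.unique(pd.Series(labels)):
        sub = ds.take_individuals(np.flatnonzero(labels == g))
        ok = sub.calls != MISSING
        alt = np.where(ok, sub.calls, 0).sum(axis=0)
        total = 2 * ok.sum(axis=0)
        mac = np.minimum(alt, total - alt)
        keep = np.flatnonzero(mac >= min_mac)
        if keep.size == 0:
            raise ValueError(f"group {g!r} is monomorphic at every site")
        out[str(g)] = sub.take_sites(keep)
    return out


def _locus_ho_he(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Ho, unbiased He and non-missing n for one locality."""
    ok = calls != MISSING
    n = ok.sum(axis=0).astype(float)
    het = ((calls == 1) & ok).sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        ho = np.where(n > 0, het / n, np.nan)
        he = np.where(n > 1, (2 * n / (2 * n - 1)) * 2 * p * (1 - p), np.nan)
    return ho, he, n


def locality_diversity(
    ds: GenotypeDataset, locality_labels: np.ndarray | None = None, min_individuals: int = 2
) -> list[DiversityStats]:
    """Ho, He and Gis per locality (localities below min_individuals skipped)."""
    labels = np.asarray(locality_labels if locality_labels is not None else ds.locality_labels)
    stats = []
    for loc in pd.unique(pd.Series(labels)):
        idx = np.flatnonzero(labels == loc)
        if idx.size < min_individuals:
            continue
        ho_l, he_l, _ = _locus_ho_he(ds.calls[idx])
        use = ~np.isnan(he_l)
        mean_ho = float(np.nanmean(ho_l[use])) if use.any() else np.nan
        mean_he = float(np.nanmean(he_l[use])) if use.any() else np.nan
        gis = 1.0 - mean_ho / mean_he if mean_he and mean_he > 0 else np.nan
        stats.append(
            DiversityStats(
                locality=str(loc),
                ho=mean_ho,
                he=mean_he,
                gis=gis,
                n_individuals=int(idx.size),
                n_polymorphic_sites=int((he_l > 0).sum()),
            )
        )
    return stats


def diversity_frame(stats: list[DiversityStats]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in stats])


def gis_permutation_test(
    ds: GenotypeDataset,
    locality: str,
    locality_labels: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Two-tailed permutation p-value for the locality Gis.

    The null re-pairs the 2n allele copies at every locus independently
    (allele frequencies fixed, genotypes randomised), recomputes Gis and
    compares |Gis_perm| against |Gis_obs|.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives unstable p-values", stacklevel=2)
    labels = np.asarray(locality_labels if locality_labels is not None else ds.locality_labels)
    idx = np.flatnonzero(labels == locality)
    calls = ds.calls[idx]
    ok = calls != MISSING
    n = ok.sum(axis=0)
    het = ((calls == 1) & ok).sum(axis=0)
    alt = np.where(ok, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n)
        he = np.where(n > 1, (2 * n / (2 * n - 1)) * 2 * p * (1 - p), np.nan)
    use = np.flatnonzero(np.nan_to_num(he) > 0)
    if use.size == 0:
        raise ValueError("He = 0 at every locus; Gis undefined")
    mean_he = he[use].mean()
    obs = 1.0 - (het[use] / n[use]).mean() / mean_he

    rng = np.random.default_rng(seed)
    ho_null = np.empty((n_perm, use.size))
    for col, j in enumerate(use):
        ho_null[:, col] = sample_het_counts(int(n[j]), int(alt[j]), n_perm, rng) / n[j]
    gis_null = 1.0 - ho_null.mean(axis=1) / mean_he
    p_two = (np.count_nonzero(np.abs(gis_null) >= abs(obs)) + 1) / (n_perm + 1)
    return float(p_two)
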