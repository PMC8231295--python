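"""Ploidy inference from allelic read balance at heterozygous sites.

At a truly heterozygous site, the fraction of reads supporting the
reference allele concentrates near the allele dosage: 1/2 for diploids,
{1/3, 2/3} for triploids, {1/4, 1/2, 3/4} for tetraploids.  Each ploidy
hypothesis is scored as an equal-weight binomial mixture over its dosage
set and the call is the maximum-likelihood hypothesis, subject to a
log-likelihood margin; histogram inspection is replaced by this
formal comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .datatypes import AlleleDepthTable, GenotypeDataset
from .sim import DOSAGE_SETS

#: mixture components are clamped away from 0/1 because sequencing error
#: pushes a small mass of read fractions toward the extremes
_CLAMP = (0.02, 0.98)


@dataclass
class DosageProfile:
    """Reference-read fractions of one individual at usable het sites."""

    individual_id: str
    fractions: np.ndarray  # in (0,1)
    ref_reads: np.ndarray
    depths: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.fractions.size


@dataclass
class PloidyCall:
    individual_id: str
    call: int | str  # 2, 3, 4 or "ambiguous" / "no-call"
    log_likelihoods: dict[int, float]
    margin: float


def extract_dosage_profile(
    individual: int | str,
    ds: GenotypeDataset,
    depths: AlleleDepthTable,
    min_depth: int = 10,
) -> DosageProfile:
    """Collect reference-read fractions at het sites with depth >= min_depth."""
    if isinstance(individual, str):
        hits = np.flatnonzero(ds.sample_ids == individual)
        if hits.size != 1:
            raise KeyError(f"unknown individual {individual!r}")
        i = int(hits[0])
    else:
        i = int(individual)
    het = ds.calls[i] == 1
    dp = depths.depth[i]
    use = het & (dp >= min_depth)
    ref = depths.ref_reads[i][use]
    d = dp[use]
    frac = ref / d
    inside = (frac > 0) & (frac < 1)
    return DosageProfile(
        individual_id=str(ds.sample_ids[i]),
        fractions=frac[inside],
        ref_reads=ref[inside],
        depths=d[inside],
    )


def classify_ploidy(
    profile: DosageProfile, min_sites: int = 100, margin_threshold: float = 10.0
) -> PloidyCall:
    """Maximum-likelihood ploidy call from a dosage profile.

    Per-site likelihood under ploidy k is the equal-weight mixture of
    Binomial(depth, pi) over pi in the dosage set of k (components
    clamped to [0.02, 0.98]).  The call is argmax of the summed
    log-likelihood; if the winning margin over the runner-up is below
    ``margin_threshold`` log-units the call is "ambiguous", and profiles
    with fewer than ``min_sites`` sites yield "no-call".
    """
    if profile.n_sites < min_sites:
        return PloidyCall(profile.individual_id, "no-call", {}, float("nan"))
    lls: dict[int, float] = {}
    for k, dosages in DOSAGE_SETS.items():
        comps = np.clip(np.asarray(dosages), *_CLAMP)
        # (n_sites, n_components) likelihoods
        lik = binom.pmf(
            profile.ref_reads[:, None], profile.depths[:, None], comps[None, :]
        ).mean(axis=1)
        lls[k] = float(np.log(np.maximum(lik, 1e-300)).sum())
    order = sorted(lls, key=lls.get, reverse=True)
    margin = lls[order[0]] - lls[order[1]]
    call: int | str = order[0] if margin >= margin_threshold else "ambiguous"
    return PloidyCall(profile.individual_id, call, lls, float(margin))


def classify_all(
    ds: GenotypeDataset,
    depths: AlleleDepthTable,
    min_depth: int = 10,
    min_sites: int = 100,
    margin_threshold: float = 10.0,
) -> list[PloidyCall]:
    """Ploidy calls for every individual in the dataset."""
    return [
        classify_ploidy(
            extract_dosage_profile(i, ds, depths, min_depth), min_sites, margin_threshold
        )
        for i in range(ds.n_individuals)
    ]
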