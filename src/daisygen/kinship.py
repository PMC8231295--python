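"""KING-robust pairwise kinship, relatedness pruning, locality means.

The between-individual estimator is robust to population structure
because it uses only allele-sharing counts of the pair itself:

    phi_hat = (N_het,het - 2 * N_opposing_hom) / (N_het(i) + N_het(j))

over loci where both calls are present.  phi = 0.5 for identical
genotypes, ~0.25 for first-degree relatives, ~0 for unrelated pairs from
the same population; negative values indicate divergent ancestry and are
retained as informative.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset

#: default pruning cutoff: midpoint between first- and second-degree
#: expected kinship on the log2 scale, 2^(-5/2)
KING_CUTOFF: float = 0.177


@dataclass
class KinshipMatrix:
    phi: np.ndarray  # symmetric, diagonal 0.5; NaN where undefined
    n_shared_loci: np.ndarray
    sample_ids: np.ndarray
    min_confident_loci: int = 50

    @property
    def low_confidence(self) -> np.ndarray:
        return self.n_shared_loci < self.min_confident_loci

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.sample_ids, columns=self.sample_ids)


def king_kinship(ds: GenotypeDataset) -> KinshipMatrix:
    """Pairwise KING-robust kinship over pairwise-complete loci."""
    if ds.n_individuals < 2:
        raise ValueError("need at least two individuals")
    g = ds.calls
    ok = (g != MISSING).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom0 = (g == 0).astype(np.float64)
    hom2 = (g == 2).astype(np.float64)

    # all pairwise counts via matrix products over loci
    n_shared = ok @ ok.T
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    n_het_i = het @ ok.T  # het count of i over loci shared with j

    denom = n_het_i + n_het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hethet - 2.0 * n_opp) / denom, np.nan)
    phi[n_shared == 0] = np.nan
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(
        phi=phi, n_shared_loci=n_shared.astype(int), sample_ids=ds.sample_ids
    )


def prune_related(
    k: KinshipMatrix,
    threshold: float = KING_CUTOFF,
    individual_missingness: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy removal until no pair has kinship >= threshold.

    At each step the individual participating in the most over-threshold
    pairs is removed; ties are broken by higher missingness (when
    given), then by larger sample index.  Returns (kept_ids, removed_ids).
    """
    n = k.phi.shape[0]
    over = np.nan_to_num(k.phi, nan=-np.inf) >= threshold
    np.fill_diagonal(over, False)
    active = np.ones(n, dtype=bool)
    removed: list[int] = []
    miss = individual_missingness if individual_missingness is not None else np.zeros(n)
    while True:
        deg = (over & active[None, :] & active[:, None]).sum(axis=1)
        deg[~active] = 0
        if deg.max() == 0:
            break
        top = deg == deg.max()
        cand = np.flatnonzero(top)
        cand = cand[miss[cand] == miss[cand].max()]
        drop = int(cand.max())
        active[drop] = False
        removed.append(drop)
    return k.sample_ids[active], k.sample_ids[np.array(removed, dtype=int)] if removed else np.array([], dtype=k.sample_ids.dtype)


def locality_mean_kinship(
    k: KinshipMatrix, locality_labels: np.ndarray
) -> pd.Series:
    """Mean off-diagonal kinship within each locality.

    Localities with fewer than two individuals are reported as NaN.
    """
    out = {}
    for loc in pd.unique(pd.Series(locality_labels)):
        idx = np.flatnonzero(np.asarray(locality_labels) == loc)
        if idx.size < 2:
            out[loc] = np.nan
            continue
        sub = k.phi[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(idx.size, k=1)]
        out[loc] = float(np.nanmean(vals))
    return pd.Series(out, name="mean_kinship")
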