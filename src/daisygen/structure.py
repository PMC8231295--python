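"""Population structure and divergence: Weir-Cockerham FST, NJ tree,
genotype PCA, k-means/BIC cluster-number scan, and LDA assignment.

The FST estimator is the variance-components form: per locus the
among-population (a), among-individual (b) and within-individual (c)
components are computed from sample sizes, allele frequencies and
observed heterozygosity, and theta is the ratio of sums across loci.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .datatypes import MISSING, GenotypeDataset


@dataclass
class FstMatrix:
    theta: np.ndarray  # raw pairwise estimates (may be slightly negative)
    n_loci: np.ndarray
    localities: np.ndarray

    @property
    def clamped(self) -> np.ndarray:
        """Estimates clamped to [0, 1] for reporting / distance input."""
        out = np.clip(self.theta, 0.0, 1.0)
        np.fill_diagonal(out, 0.0)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.localities, columns=self.localities)


def _wc_components(
    calls_by_pop: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir-Cockerham a, b, c components for r populations.

    Loci where fewer than two populations have data (or nc <= 0)
    contribute zeros.
    """
    r = len(calls_by_pop)
    L = calls_by_pop[0].shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for k, calls in enumerate(calls_by_pop):
        ok = calls != MISSING
        nk = ok.sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pk = np.where(ok, calls, 0).sum(axis=0) / (2 * nk)
            hk = ((calls == 1) & ok).sum(axis=0) / nk
        n[k] = nk
        p[k] = np.nan_to_num(pk)
        h[k] = np.nan_to_num(hk)

    has = n > 0
    r_eff = has.sum(axis=0).astype(float)
    n_tot = n.sum(axis=0)
    valid = (r_eff >= 2) & (n_tot > r_eff)
    nbar = n_tot / np.maximum(r_eff, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n**2).sum(axis=0) / n_tot) / np.maximum(r_eff - 1, 1)
        pbar = (n * p).sum(axis=0) / n_tot
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / (np.maximum(r_eff - 1, 1) * nbar)
        hbar = (n * h).sum(axis=0) / n_tot

        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r_eff - 1) / r_eff) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r_eff - 1) / r_eff) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2

    valid &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (nc > 0)
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c


def weir_cockerham_fst(ds: GenotypeDataset, labels: np.ndarray) -> float:
    """Multi-population theta over all loci (ratio of summed components)."""
    labels = np.asarray(labels)
    pops = pd.unique(pd.Series(labels))
    calls_by_pop = [ds.calls[labels == popn] for popn in pops]
    a, b, c = _wc_components(calls_by_pop)
    denom = (a + b + c).sum()
    if denom == 0:
        raise ValueError("no informative loci for FST")
    return float(a.sum() / denom)


def pairwise_fst(
    ds: GenotypeDataset, locality_labels: np.ndarray | None = None
) -> FstMatrix:
    """Pairwise Weir-Cockerham theta between all localities."""
    labels = np.asarray(
        locality_labels if locality_labels is not None else ds.locality_labels
    )
    locs = pd.unique(pd.Series(labels))
    k = len(locs)
    theta = np.zeros((k, k))
    n_loci = np.zeros((k, k), dtype=int)
    calls = {loc: ds.calls[labels == loc] for loc in locs}
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c = _wc_components([calls[locs[i]], calls[locs[j]]])
            used = (a + b + c) != 0
            denom = (a + b + c).sum()
            if denom == 0:
                theta[i, j] = theta[j, i] = np.nan
            else:
                theta[i, j] = theta[j, i] = a.sum() / denom
            n_loci[i, j] = n_loci[j, i] = int(used.sum())
    return FstMatrix(theta=theta, n_loci=n_loci, localities=np.asarray(locs))


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(dist: np.ndarray, labels: np.ndarray | list[str]) -> str:
    """Saitou-Nei neighbour joining; returns an unrooted Newick string.

    Negative branch lengths are clamped to zero with the deficit
    transferred to the sister branch, preserving the pairwise path
    length of the joined pair.
    """
    d = np.array(dist, dtype=float)
    names = [str(x) for x in labels]
    n = d.shape[0]
    if n < 3:
        if n == 2:
            return f"({names[0]}:{d[0, 1] / 2:.6g},{names[1]}:{d[0, 1] / 2:.6g});"
        return f"({names[0]}:0);"
    nodes = list(names)
    while len(nodes) > 3:
        m = len(nodes)
        total = d.sum(axis=1)
        q = (m - 2) * d - total[:, None] - total[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (total[i] - total[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li  # transfer to sister so the pair's path length is kept
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.6g},{nodes[j]}:{lj:.6g})"
        du = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        d_new = np.zeros((m - 1, m - 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        nodes = [nodes[x] for x in keep] + [new]
    # final 3-star join
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    ls = []
    for x, node in zip((la, lb, lc), nodes):
        ls.append(f"{node}:{max(x, 0.0):.6g}")
    return "(" + ",".join(ls) + ");"


# ---------------------------------------------------------------------------
# PCA + k-means/BIC + LDA


@dataclass
class ClusterScan:
    k_values: np.ndarray
    bic: np.ndarray
    best_k: int
    assignments: np.ndarray
    pc_scores: np.ndarray
    explained_variance_ratio: np.ndarray


def genotype_pca(ds: GenotypeDataset, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the centred dosage matrix, missing imputed by locus mean."""
    x = ds.calls.astype(float)
    x[x == MISSING] = np.nan
    mu = np.nanmean(x, axis=0)
    mu = np.nan_to_num(mu)
    inds = np.where(np.isnan(x))
    x[inds] = mu[inds[1]]
    n_components = n_components or min(x.shape[0] - 1, x.shape[1], 100)
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(x)
    keep = pca.explained_variance_ > 1e-12
    return scores[:, keep], pca.explained_variance_ratio_[keep]


def kmeans_bic_scan(
    ds: GenotypeDataset,
    k_max: int = 20,
    n_pcs: int | None = None,
    seed: int = 0,
    var_explained: float = 0.9,
) -> ClusterScan:
    """Scan K = 1..k_max with k-means on PC scores, scoring by BIC.

    BIC(K) = n * ln(WSS_K / n) + K * ln(n); the best K minimises it.
    By default the number of PCs retained is the smallest explaining
    ``var_explained`` of the variance.
    """
    scores, evr = genotype_pca(ds)
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(evr), var_explained) + 1)
    n_pcs = min(n_pcs, scores.shape[1])
    x = scores[:, :n_pcs]
    n = x.shape[0]
    k_max = min(k_max, n - 1)
    ks = np.arange(1, k_max + 1)
    bics = np.empty(len(ks))
    labels_by_k = {}
    for idx, k in enumerate(ks):
        if k == 1:
            wss = float(((x - x.mean(axis=0)) ** 2).sum())
            labels_by_k[1] = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=int(k), n_init=20, random_state=seed).fit(x)
            wss = float(km.inertia_)
            labels_by_k[int(k)] = km.labels_
        wss = max(wss, 1e-12)
        bics[idx] = n * np.log(wss / n) + k * np.log(n)
    best = int(ks[np.argmin(bics)])
    return ClusterScan(
        k_values=ks,
        bic=bics,
        best_k=best,
        assignments=labels_by_k[best],
        pc_scores=scores,
        explained_variance_ratio=evr,
    )


def lda_assign(
    scores: np.ndarray, assignments: np.ndarray, n_pcs: int = 80
) -> np.ndarray:
    """Posterior cluster-membership probabilities from LDA on PC scores.

    Uses the first min(n_pcs, n - K) components so the within-cluster
    scatter stays well conditioned.
    """
    k = len(np.unique(assignments))
    n = scores.shape[0]
    use = min(n_pcs, scores.shape[1], max(n - k, 1))
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(scores[:, :use], assignments)
    return lda.predict_proba(scores[:, :use])
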