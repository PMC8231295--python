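"""Redundancy analysis (RDA) with spatial conditioning, forward selection
and variance partitioning.

RDA regresses a multivariate, column-centred response (locality allele
frequencies or leaf traits) on explanatory variables by least squares;
the constrained fraction of variance plays the role of a multivariate
r-squared.  Partial RDA first residualises both response and explanatory
variables on a conditioning set (here: centred third-degree spatial
polynomials), so the reported fraction is the variance explained by
environment beyond space.  Significance comes from an ANOVA-like
permutation test that permutes rows of the residualised response
(reduced-model scheme).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset


@dataclass
class RdaModel:
    r2: float
    adj_r2: float
    pseudo_f: float
    p_value: float | None
    n: int
    q: int  # explanatory columns (after rank reduction)
    n_cond: int  # conditioning columns
    retained_terms: list[str] | None = None


@dataclass
class VariancePartition:
    a_env: float  # unique to environment
    b_shared: float
    c_space: float  # unique to space
    d_resid: float


def spatial_polynomials(coords: np.ndarray, degree: int = 3) -> pd.DataFrame:
    """Centred coordinate monomials up to the given total degree.

    Degree 3 yields the nine columns x, y, x2, xy, y2, x3, x2y, xy2, y3.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be (n, 2)")
    x = coords[:, 0] - coords[:, 0].mean()
    y = coords[:, 1] - coords[:, 1].mean()
    cols: dict[str, np.ndarray] = {}
    for total in range(1, degree + 1):
        for i in range(total, -1, -1):
            j = total - i
            name = ("x" + (str(i) if i > 1 else "") if i else "") + (
                "y" + (str(j) if j > 1 else "") if j else ""
            )
            cols[name] = x**i * y**j
    df = pd.DataFrame(cols)
    if (df.std(axis=0) == 0).any():
        raise ValueError("constant spatial polynomial column (degenerate coordinates)")
    return df


def _centre(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def _drop_collinear(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Keep a maximal independent subset of columns (QR pivots)."""
    if x.shape[1] == 0:
        return x
    q, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(x, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    rank = int((diag > tol * max(diag[0], 1.0)).sum()) if diag.size else 0
    keep = np.sort(piv[:rank])
    return x[:, keep]


def _residualise(a: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Residuals of each column of a on [1, z]."""
    zz = np.column_stack([np.ones(a.shape[0]), z]) if z.size else np.ones((a.shape[0], 1))
    beta, *_ = np.linalg.lstsq(zz, a, rcond=None)
    return a - zz @ beta


def rda_fit(
    response: np.ndarray,
    explanatory: np.ndarray,
    conditioning: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> RdaModel:
    """(Partial) redundancy analysis by least squares.

    r2 is the constrained share of the (conditioning-residualised)
    response variance; pseudo-F = (constrained/q) / (residual/(n-q-c-1));
    the p-value permutes rows of the residualised response.
    """
    y = _centre(np.asarray(response, dtype=float))
    x = _centre(np.asarray(explanatory, dtype=float))
    n = y.shape[0]
    z = np.zeros((n, 0))
    if conditioning is not None and np.size(conditioning):
        z = _drop_collinear(_centre(np.asarray(conditioning, dtype=float)))
        y = _residualise(y, z)
        x = _residualise(x, z)
    x = _drop_collinear(x)
    q = x.shape[1]
    c = z.shape[1]
    if n <= q + c + 1:
        raise ValueError("need more rows than explanatory + conditioning columns")
    if q == 0:
        # explanatory space vanished (e.g., collinear with conditioning)
        return RdaModel(r2=0.0, adj_r2=0.0, pseudo_f=0.0, p_value=1.0, n=n, q=0, n_cond=c)

    # orthonormal bases: ss_fit = ||U'y||^2; permuted copies of y must be
    # re-residualised on the conditioning space (reduced-model scheme),
    # handled via ||Qz'y||^2 since row permutation breaks orthogonality to z
    u, _ = np.linalg.qr(x)
    qz = np.linalg.qr(np.column_stack([np.ones(n) / np.sqrt(n), z]))[0] if c else None

    def stats(yy: np.ndarray) -> tuple[float, float]:
        ss_all = float((yy**2).sum())
        if qz is not None:
            ss_all -= float(((qz.T @ yy) ** 2).sum())
        if ss_all <= 0:
            return 0.0, 0.0
        ss_fit = float(((u.T @ yy) ** 2).sum())
        ss_res = ss_all - ss_fit
        r2 = min(ss_fit / ss_all, 1.0)
        fstat = (ss_fit / q) / (ss_res / (n - q - c - 1)) if ss_res > 1e-12 * ss_all else np.inf
        return r2, fstat

    r2, fstat = stats(y)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1) if n > q + 1 else np.nan

    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            _, f_p = stats(y[rng.permutation(n)])
            count += f_p >= fstat
        p = (count + 1) / (n_perm + 1)
    return RdaModel(
        r2=float(r2), adj_r2=float(adj), pseudo_f=float(fstat), p_value=p,
        n=n, q=q, n_cond=c,
    )


def forward_select(
    response: np.ndarray,
    candidates: pd.DataFrame,
    conditioning: np.ndarray | None = None,
    alpha: float = 0.05,
    n_perm: int = 499,
    seed: int = 0,
) -> list[str]:
    """Forward stepwise term selection by permutation p-value.

    At each step the candidate whose single-term addition has the
    smallest permutation p (ties: larger pseudo-F) joins the model if
    p < alpha; selection stops when no candidate qualifies.
    """
    retained: list[str] = []
    remaining = list(candidates.columns)
    rng = np.random.default_rng(seed)
    base_cond = (
        np.asarray(conditioning, dtype=float)
        if conditioning is not None and np.size(conditioning)
        else np.zeros((np.asarray(response).shape[0], 0))
    )
    while remaining:
        best = None
        for term in remaining:
            cond = np.column_stack([base_cond] + [candidates[t].to_numpy()[:, None] for t in retained]) if retained or base_cond.size else None
            x = candidates[term].to_numpy()[:, None]
            try:
                model = rda_fit(response, x, cond, n_perm=n_perm, seed=int(rng.integers(2**31)))
            except ValueError:
                continue
            if model.r2 <= 1e-12:
                continue
            key = (model.p_value, -model.pseudo_f)
            if best is None or key < best[0]:
                best = (key, term)
        if best is None or best[0][0] >= alpha:
            break
        retained.append(best[1])
        remaining.remove(best[1])
    return retained


def variance_partition(
    response: np.ndarray, env: np.ndarray, space: np.ndarray
) -> VariancePartition:
    """Partition explained variance into unique and shared fractions.

    Uses adjusted r2 of the models [env], [space] and [env+space]:
    a = R2(env+space) - R2(space), c = R2(env+space) - R2(env),
    b = R2(env) - a, d = 1 - R2(env+space).  Fractions may be slightly
    negative (adjusted-r2 artefact) and are reported raw.
    """
    env = np.asarray(env, dtype=float)
    space = np.asarray(space, dtype=float)
    both = np.column_stack([env, space])
    r2 = {}
    for name, x in (("env", env), ("space", space), ("both", both)):
        model = rda_fit(response, x, None, n_perm=0)
        r2[name] = model.adj_r2
    a = r2["both"] - r2["space"]
    c = r2["both"] - r2["env"]
    b = r2["env"] - a
    d = 1.0 - r2["both"]
    return VariancePartition(a_env=a, b_shared=b, c_space=c, d_resid=d)


def collinearity_screen(env: pd.DataFrame, max_abs_r: float = 0.7) -> list[str]:
    """Greedy subset of environment columns with pairwise |r| below cutoff."""
    keep: list[str] = []
    corr = env.corr().abs()
    for col in env.columns:
        if all(corr.loc[col, k] < max_abs_r for k in keep):
            keep.append(col)
    return keep


def locality_allele_frequencies(
    ds: GenotypeDataset, localities: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Locality x SNP alternate-allele frequency matrix (column-centred later).

    Returns (frequencies, locality order).  Missing calls are excluded
    per locus; a locality with no data at a locus gets that locus's
    overall mean frequency.
    """
    labels = ds.locality_labels
    locs = np.asarray(localities) if localities is not None else np.asarray(pd.unique(pd.Series(labels)))
    out = np.empty((len(locs), ds.n_sites))
    for i, loc in enumerate(locs):
        calls = ds.calls[labels == loc]
        ok = calls != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[i] = np.where(n > 0, np.where(ok, calls, 0).sum(axis=0) / (2 * n), np.nan)
    col_mean = np.nanmean(out, axis=0)
    inds = np.where(np.isnan(out))
    out[inds] = np.take(col_mean, inds[1])
    return out, locs
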