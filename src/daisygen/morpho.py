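"""Leaf morphometrics: derived shape traits, PCA, group ANOVA/Tukey.

Three raw measurements per leaf — length L (base to apex), width W at
the widest point, and width location WL (distance along the midrib from
base to the widest point), all in mm.  Derived traits:

* leaf area LA = (L * W / 2) + ((L - WL) * 2 / 2)   (verbatim formula)
* ovality = WL / L   (~0.5 oval, <0.5 heart-shaped, >0.5 ginkgo-shaped)
* length/width ratio = L / W
* sqrt(LA), used in place of LA for normality of residuals

The second term of the verbatim area formula reduces algebraically to
(L - WL); a width-corrected variant (L - WL) * W / 2 is available via
``formula="width-corrected"`` for users who read the printed form as a
typo for a triangle area.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from sklearn.decomposition import PCA
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .datatypes import LeafTable

TRAIT_COLUMNS = ["L", "W", "WL", "sqrt_LA", "ovality", "lw_ratio"]


def leaf_area(l: np.ndarray, w: np.ndarray, wl: np.ndarray, formula: str = "verbatim") -> np.ndarray:
    """Estimated leaf area from L, W, WL."""
    if formula == "verbatim":
        return (l * w / 2.0) + ((l - wl) * 2.0 / 2.0)
    if formula == "width-corrected":
        return (l * w / 2.0) + ((l - wl) * w / 2.0)
    raise ValueError("formula must be 'verbatim' or 'width-corrected'")


def leaf_metrics(
    table: pd.DataFrame | LeafTable,
    half_width_flag: str | None = "half_width",
    formula: str = "verbatim",
) -> pd.DataFrame:
    """Add derived trait columns (LA, sqrt_LA, ovality, lw_ratio).

    Rows flagged in the ``half_width`` column had only the half-width
    measured (folded or damaged leaves) and are doubled first.  Raises on
    invalid measurements (non-positive L or W, WL outside [0, L]).
    """
    df = (table.table if isinstance(table, LeafTable) else table).copy()
    if half_width_flag and half_width_flag in df.columns:
        flag = df[half_width_flag].astype(bool)
        df.loc[flag, "W"] = 2.0 * df.loc[flag, "W"]
    l, w, wl = (df[c].to_numpy(float) for c in ("L", "W", "WL"))
    if (l <= 0).any() or (w <= 0).any():
        raise ValueError("L and W must be positive")
    if ((wl < 0) | (wl > l)).any():
        raise ValueError("WL must lie in [0, L]")
    df["LA"] = leaf_area(l, w, wl, formula)
    df["sqrt_LA"] = np.sqrt(df["LA"])
    df["ovality"] = wl / l
    df["lw_ratio"] = l / w
    return df


def trait_pca_anova(
    table: pd.DataFrame | LeafTable,
    group_col: str = "group",
    traits: list[str] | None = None,
) -> dict:
    """Centred/scaled PCA of leaf traits plus group ANOVA and Tukey HSD.

    Returns a dict with PC scores, loadings, variance explained, and
    one-way ANOVA F/p plus Tukey pairwise adjusted p-values for PC1 and
    PC2 across groups.  Constant trait columns are dropped.
    """
    df = table.table if isinstance(table, LeafTable) else table
    if "sqrt_LA" not in df.columns:
        df = leaf_metrics(df)
    traits = traits or TRAIT_COLUMNS
    x = df[traits].to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        import warnings

        dropped = [t for t, k in zip(traits, keep) if not k]
        warnings.warn(f"dropping constant traits: {dropped}", stacklevel=2)
    traits = [t for t, k in zip(traits, keep) if k]
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    groups = df[group_col].to_numpy()
    if min(np.bincount(pd.factorize(groups)[0])) < 3:
        raise ValueError("need at least 3 leaves per group")

    pca = PCA()
    scores = pca.fit_transform(x)
    out = {
        "scores": scores,
        "loadings": pd.DataFrame(
            pca.components_.T, index=traits,
            columns=[f"PC{i + 1}" for i in range(pca.components_.shape[0])],
        ),
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "groups": groups,
        "anova": {},
        "tukey": {},
    }
    if len(pd.unique(pd.Series(groups))) < 2:
        return out
    for axis in (0, 1):
        by_group = [scores[groups == g0, axis] for g0 in pd.unique(pd.Series(groups))]
        stat = f_oneway(*by_group)
        out["anova"][f"PC{axis + 1}"] = {"F": float(stat.statistic), "p": float(stat.pvalue)}
        tk = pairwise_tukeyhsd(scores[:, axis], groups)
        out["tukey"][f"PC{axis + 1}"] = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    return out
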