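"""Hierarchical analysis of molecular variance (AMOVA) over allele copies.

Each biallelic locus contributes a nested random-effects ANOVA on the 2N
allele copies (coded 0/1): groups > localities within groups >
individuals within localities > copies within individuals.  Sums of
squares are converted to variance components with expected-mean-square
coefficients valid for unbalanced designs, components are summed over
loci, and F-statistic analogues (F_CT, F_SC, F_IS, F_IT) are formed from
the summed components.  Uncertainty comes from delete-one-locus
jackknifing, bootstrap over loci, and stratified permutation tests.

Missing genotypes are handled per locus: an individual with a missing
call contributes no copies at that locus, and the expected-mean-square
coefficients shrink accordingly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset
from .filtering import sample_het_counts


@dataclass
class AmovaResult:
    """Variance components and F-analogues, one row per hierarchy level."""

    levels: list[str]
    components: np.ndarray  # raw per-level variance components (may be negative)
    percent_var: np.ndarray  # floored at 0 and renormalised to sum to 100
    f_stats: dict[str, float]
    per_locus: np.ndarray | None = None  # (L, 4) raw components [a, b, c, d]
    jackknife_sd: dict[str, float] = field(default_factory=dict)
    bootstrap_ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    permutation_p: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fnames = self._level_fnames()
        for i, lev in enumerate(self.levels):
            fname = fnames[i]
            rows.append(
                {
                    "level": lev,
                    "sigma2": self.components[i],
                    "percent_var": self.percent_var[i],
                    "F": self.f_stats.get(fname, np.nan),
                    "F_name": fname,
                    "jackknife_sd": self.jackknife_sd.get(fname, np.nan),
                    "ci_2.5": self.bootstrap_ci.get(fname, (np.nan, np.nan))[0],
                    "ci_97.5": self.bootstrap_ci.get(fname, (np.nan, np.nan))[1],
                    "p": self.permutation_p.get(fname, np.nan),
                }
            )
        return pd.DataFrame(rows)

    def _level_fnames(self) -> list[str]:
        if len(self.levels) == 4:
            return ["F_IT", "F_IS", "F_SC", "F_CT"]
        return ["F_IT", "F_IS", "F_ST"]


def _codes(labels: np.ndarray) -> tuple[np.ndarray, int]:
    cats = pd.unique(pd.Series(np.asarray(labels)))
    lookup = {c: i for i, c in enumerate(cats)}
    return np.array([lookup[x] for x in np.asarray(labels)]), len(cats)


@dataclass
class _LocalitySummaries:
    """Per-(locality, locus) sufficient statistics for the nested ANOVA."""

    s_l: np.ndarray  # alternate-allele copy sums (n_loc, L)
    m_l: np.ndarray  # allele-copy counts (n_loc, L)
    het_l: np.ndarray  # heterozygote counts (n_loc, L)
    n_copies: np.ndarray  # N per locus
    n_ind: np.ndarray  # individuals with data per locus


def _summarise(calls: np.ndarray, loc_codes: np.ndarray, n_loc: int) -> _LocalitySummaries:
    n = calls.shape[0]
    ok = (calls != MISSING).astype(np.float64)
    g = np.where(calls == MISSING, 0, calls).astype(np.float64)
    loc_onehot = np.zeros((n_loc, n))
    loc_onehot[loc_codes, np.arange(n)] = 1.0
    s_l = loc_onehot @ g
    m_l = 2.0 * (loc_onehot @ ok)
    het_l = loc_onehot @ (calls == 1).astype(np.float64)
    return _LocalitySummaries(
        s_l=s_l, m_l=m_l, het_l=het_l, n_copies=m_l.sum(axis=0), n_ind=ok.sum(axis=0)
    )


def _components_from_summaries(
    sm: _LocalitySummaries, grp_of_loc: np.ndarray | None, n_grp: int
) -> np.ndarray:
    """Raw per-locus components [a, b, c, d] (a = 0 when ungrouped)."""
    s_l, m_l, het_l = sm.s_l, sm.m_l, sm.het_l
    n_copies, n_ind = sm.n_copies, sm.n_ind
    L = s_l.shape[1]

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_sl = np.where(m_l > 0, s_l**2 / m_l, 0.0)
    # sum over individuals of g^2/2 given per-locality het count h and
    # allele sum s:  sum g^2 = h + 4*(s-h)/2 = 2s - h
    ss_c = ((2.0 * s_l - het_l) / 2.0 - ratio_sl).sum(axis=0)
    ss_e = 0.5 * het_l.sum(axis=0)
    l_eff = (m_l > 0).sum(axis=0).astype(float)

    comps = np.zeros((L, 4))
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(n_copies > n_ind, ss_e / (n_copies - n_ind), 0.0)
        denom_c = n_copies - 2.0 * l_eff
        c = np.where(denom_c > 0, (ss_c - d * (n_ind - l_eff)) / denom_c, 0.0)
    comps[:, 3] = d
    comps[:, 2] = c

    tot_s = s_l.sum(axis=0)
    if grp_of_loc is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            ss_b = ratio_sl.sum(axis=0) - np.where(n_copies > 0, tot_s**2 / n_copies, 0.0)
            coef_b = n_copies - (m_l**2).sum(axis=0) / np.maximum(n_copies, 1)
            b = np.where(
                (coef_b > 0) & (l_eff > 1),
                (ss_b - d * (l_eff - 1) - 2.0 * c * (l_eff - 1)) / coef_b,
                0.0,
            )
        comps[:, 1] = b
        return comps

    grp_onehot = np.zeros((n_grp, grp_of_loc.size))
    grp_onehot[grp_of_loc, np.arange(grp_of_loc.size)] = 1.0
    t_g = grp_onehot @ s_l
    m_g = grp_onehot @ m_l
    g_eff = (m_g > 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_tg = np.where(m_g > 0, t_g**2 / m_g, 0.0)
        ml2_over_mg = np.where(
            m_g[grp_of_loc] > 0, m_l**2 / np.maximum(m_g[grp_of_loc], 1e-300), 0.0
        ).sum(axis=0)
        ml2_over_n = (m_l**2).sum(axis=0) / np.maximum(n_copies, 1)
        mg2_over_n = (m_g**2).sum(axis=0) / np.maximum(n_copies, 1)

        ss_b = ratio_sl.sum(axis=0) - ratio_tg.sum(axis=0)
        ss_a = ratio_tg.sum(axis=0) - np.where(n_copies > 0, tot_s**2 / n_copies, 0.0)

        coef_b_in_b = n_copies - ml2_over_mg
        b = np.where(
            (coef_b_in_b > 0) & (l_eff > g_eff),
            (ss_b - d * (l_eff - g_eff) - 2.0 * c * (l_eff - g_eff)) / coef_b_in_b,
            0.0,
        )
        coef_a = n_copies - mg2_over_n
        a = np.where(
            (coef_a > 0) & (g_eff > 1),
            (
                ss_a
                - d * (g_eff - 1)
                - 2.0 * c * (g_eff - 1)
                - b * (ml2_over_mg - ml2_over_n)
            )
            / coef_a,
            0.0,
        )
    comps[:, 1] = b
    comps[:, 0] = a
    return comps


def _fstats_from_sums(sums: np.ndarray, grouped: bool) -> dict[str, float]:
    a, b, c, d = sums
    total = a + b + c + d
    names = ("F_IT", "F_IS", "F_SC", "F_CT") if grouped else ("F_IT", "F_IS", "F_ST")
    if total <= 0:
        return {k: np.nan for k in names}
    out: dict[str, float] = {}
    if grouped:
        out["F_CT"] = a / total
        out["F_SC"] = b / (b + c + d) if (b + c + d) > 0 else np.nan
        out["F_IS"] = c / (c + d) if (c + d) > 0 else np.nan
        out["F_IT"] = (a + b + c) / total
    else:
        out["F_ST"] = b / total
        out["F_IS"] = c / (c + d) if (c + d) > 0 else np.nan
        out["F_IT"] = (b + c) / total
    return out


def _design(
    ds: GenotypeDataset,
    locality_labels: np.ndarray | None,
    group_labels,
) -> tuple[np.ndarray, int, np.ndarray | None, int, bool]:
    loc = np.asarray(locality_labels if locality_labels is not None else ds.locality_labels)
    loc_codes, n_loc = _codes(loc)
    if n_loc < 2:
        raise ValueError("need at least two localities")
    if isinstance(group_labels, str) and group_labels == "auto":
        group_labels = ds.group_labels if ds.group_labels.size else None
        if group_labels is not None and len(pd.unique(pd.Series(group_labels))) < 2:
            group_labels = None  # a single group carries no top stratum
    grouped = group_labels is not None
    grp_of_loc = None
    n_grp = 0
    if grouped:
        grp = np.asarray(group_labels)
        grp_codes, n_grp = _codes(grp)
        if n_grp < 2:
            raise ValueError("need at least two groups for the grouped design")
        grp_of_loc = np.zeros(n_loc, dtype=int)
        for j in range(n_loc):
            members = grp_codes[loc_codes == j]
            if np.unique(members).size > 1:
                raise ValueError("localities must nest within groups")
            grp_of_loc[j] = members[0]
    return loc_codes, n_loc, grp_of_loc, n_grp, grouped


def amova(
    ds: GenotypeDataset,
    locality_labels: np.ndarray | None = None,
    group_labels="auto",
) -> AmovaResult:
    """Two- or three-stratum AMOVA (three when group labels are given).

    ``group_labels="auto"`` uses the dataset's own group labels when
    present; pass ``None`` to force the two-stratum (ungrouped) design.

    Percent variance is computed after flooring negative components at
    zero and renormalising; the raw (possibly negative) components are
    kept alongside.  The within-individual row's F follows the table
    convention 1 - %var(within)/100 (an F_IT analogue).
    """
    loc_codes, n_loc, grp_of_loc, n_grp, grouped = _design(ds, locality_labels, group_labels)
    sm = _summarise(ds.calls, loc_codes, n_loc)
    per_locus = _components_from_summaries(sm, grp_of_loc, n_grp)
    sums = per_locus.sum(axis=0)
    fstats = _fstats_from_sums(sums, grouped)

    if grouped:
        levels = [
            "within_individuals",
            "among_individuals_within_localities",
            "among_localities_within_groups",
            "among_groups",
        ]
        comps = sums[::-1].copy()  # d, c, b, a
    else:
        levels = [
            "within_individuals",
            "among_individuals_within_localities",
            "among_localities",
        ]
        comps = sums[[3, 2, 1]].copy()
    floored = np.maximum(comps, 0.0)
    pct = 100.0 * floored / floored.sum() if floored.sum() > 0 else np.full_like(floored, np.nan)
    fstats["F_IT"] = float(1.0 - pct[0] / 100.0) if np.isfinite(pct[0]) else np.nan
    return AmovaResult(
        levels=levels, components=comps, percent_var=pct, f_stats=fstats, per_locus=per_locus
    )


def amova_uncertainty(
    ds: GenotypeDataset,
    locality_labels: np.ndarray | None = None,
    group_labels="auto",
    n_bootstrap: int = 1000,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA plus jackknife SDs, bootstrap CIs and permutation p-values.

    Permutation schemes are stratified per level: allele copies re-paired
    within localities (F_IS), individuals shuffled among localities
    within groups (F_SC; among localities for the two-stratum F_ST),
    whole localities shuffled among groups (F_CT).
    """
    res = amova(ds, locality_labels, group_labels)
    loc_codes, n_loc, grp_of_loc, n_grp, grouped = _design(ds, locality_labels, group_labels)
    sm = _summarise(ds.calls, loc_codes, n_loc)

    per_locus = res.per_locus
    L = per_locus.shape[0]
    if L < 20:
        raise ValueError("need at least 20 loci for resampling uncertainty")
    rng = np.random.default_rng(seed)
    sums = per_locus.sum(axis=0)
    fnames = [k for k in res.f_stats if k != "F_IT"]

    # delete-one-locus jackknife of each F
    for k in fnames:
        vals = np.array(
            [_fstats_from_sums(sums - per_locus[i], grouped)[k] for i in range(L)]
        )
        v = vals[np.isfinite(vals)]
        res.jackknife_sd[k] = float(
            np.sqrt((len(v) - 1) / len(v) * ((v - v.mean()) ** 2).sum())
        )

    # bootstrap over loci (percentile CI)
    boot = {k: np.empty(n_bootstrap) for k in fnames}
    for b in range(n_bootstrap):
        w = rng.multinomial(L, np.full(L, 1.0 / L))
        f_b = _fstats_from_sums(w @ per_locus, grouped)
        for k in fnames:
            boot[k][b] = f_b[k]
    for k in fnames:
        v = boot[k][np.isfinite(boot[k])]
        res.bootstrap_ci[k] = (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    def pval(null: np.ndarray, observed: float) -> float:
        null = null[np.isfinite(null)]
        return float((np.count_nonzero(null >= observed) + 1) / (null.size + 1))

    # --- F_IS: re-pair allele copies within localities ---------------------
    # The re-pairing null changes the components only through the total
    # heterozygote count per locus, so sample per-locality het counts and
    # recompute c and d in closed form (a and b are unaffected).
    n_l = (sm.m_l / 2).astype(int)
    alt_l = sm.s_l.astype(int)
    h_tot = np.zeros((n_perm, L))
    for j in range(n_loc):
        for s in range(L):
            if n_l[j, s] > 0:
                h_tot[:, s] += sample_het_counts(n_l[j, s], alt_l[j, s], n_perm, rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio_sl = np.where(sm.m_l > 0, sm.s_l**2 / sm.m_l, 0.0)
    c0 = (sm.s_l - ratio_sl).sum(axis=0)  # ss_c + H/2, fixed under the null
    l_eff = (sm.m_l > 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_null = np.where(
            sm.n_copies > sm.n_ind, (h_tot / 2.0) / (sm.n_copies - sm.n_ind), 0.0
        )
        denom_c = sm.n_copies - 2.0 * l_eff
        c_null = np.where(
            denom_c > 0,
            (c0 - h_tot / 2.0 - d_null * (sm.n_ind - l_eff)) / denom_c,
            0.0,
        )
    sum_c = c_null.sum(axis=1)
    sum_d = d_null.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_fis = np.where(sum_c + sum_d > 0, sum_c / (sum_c + sum_d), np.nan)
    res.permutation_p["F_IS"] = pval(null_fis, res.f_stats["F_IS"])

    # --- F_SC / F_ST: shuffle individuals among localities -----------------
    key = "F_SC" if grouped else "F_ST"
    null_mid = np.empty(n_perm)
    for p in range(n_perm):
        perm_codes = loc_codes.copy()
        if grouped:
            for g0 in range(n_grp):
                members = np.flatnonzero(grp_of_loc[loc_codes] == g0)
                perm_codes[members] = loc_codes[members][rng.permutation(members.size)]
        else:
            perm_codes = loc_codes[rng.permutation(loc_codes.size)]
        sm_p = _summarise(ds.calls, perm_codes, n_loc)
        comps_p = _components_from_summaries(sm_p, grp_of_loc, n_grp)
        null_mid[p] = _fstats_from_sums(comps_p.sum(axis=0), grouped)[key]
    res.permutation_p[key] = pval(null_mid, res.f_stats[key])

    # --- F_CT: shuffle whole localities among groups -----------------------
    if grouped:
        n_units = n_loc
        null_fct = np.empty(n_perm)
        for p in range(n_perm):
            perm_map = grp_of_loc[rng.permutation(n_units)]
            comps_p = _components_from_summaries(sm, perm_map, n_grp)
            null_fct[p] = _fstats_from_sums(comps_p.sum(axis=0), True)["F_CT"]
        res.permutation_p["F_CT"] = pval(null_fct, res.f_stats["F_CT"])
    return res
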