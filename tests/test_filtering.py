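"""Filtering cascade: thresholds as printed, LD pruning determinism,
negative-F permutation calibration, idempotence."""
import numpy as np
import pytest

import daisygen as dg
from daisygen.datatypes import MISSING
from daisygen.filtering import _het_pairing_pmf, sample_het_counts
from .conftest import make_dataset


def test_read_vcf_handcrafted(tmp_path):
    """Direct parse of a tiny VCF, including a skipped multiallelic record."""
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=1>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "1\t1\ts1\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "1\t2\ts2\tA\tT,C\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2\n"
        "1\t3\ts3\tA\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1\n"
    )
    ds, depths = dg.read_vcf(vcf)
    assert ds.calls.shape == (3, 2)  # multiallelic record skipped
    assert list(ds.calls[:, 0]) == [0, 1, 2]
    assert list(ds.calls[:, 1]) == [MISSING, 0, 1]
    assert depths is None


def test_maf_boundary_strictly_less_than():
    """Alt frequency 0.05 is removed; exactly 0.1 is retained."""
    n = 20
    col_low = np.zeros(n, dtype=np.int8)
    col_low[0] = 2  # freq 0.05
    col_edge = np.zeros(n, dtype=np.int8)
    col_edge[:4] = 1  # freq 0.1
    col_mid = np.ones(n, dtype=np.int8)
    ds = make_dataset(np.column_stack([col_low, col_edge, col_mid]))
    out, report = dg.apply_site_and_individual_filters(ds, None, dg.FilterConfig())
    assert list(out.site_ids) == ["m1", "m2"]
    assert report.stages[1]["sites_removed"] == 1


def test_depth_masking_boundary():
    """DP = 9 masks the genotype; DP = 10 keeps it."""
    calls = np.ones((2, 2), dtype=np.int8)
    ref = np.array([[4, 5], [5, 10]])
    alt = np.array([[5, 5], [5, 10]])
    ds = make_dataset(calls)
    depths = dg.AlleleDepthTable(ref, alt)
    cfg = dg.FilterConfig(min_maf=0.0, max_site_missing=1.0, max_ind_missing=1.0)
    out, report = dg.apply_site_and_individual_filters(ds, depths, cfg)
    assert report.stages[0]["genotypes_masked"] == 1  # only DP=9
    assert out.calls[0, 0] == MISSING
    assert out.calls[0, 1] == 1


def test_high_missingness_individual_dropped():
    calls = np.ones((4, 4), dtype=np.int8)
    calls[0, :2] = MISSING  # 50% missing
    ds = make_dataset(calls)
    cfg = dg.FilterConfig(min_maf=0.0, max_site_missing=0.6, max_ind_missing=0.25)
    out, report = dg.apply_site_and_individual_filters(ds, None, cfg)
    assert out.n_individuals == 3
    assert "s0" not in out.sample_ids


def test_cascade_idempotent(structured_ds):
    depths = dg.simulate_read_depths(structured_ds, mean_depth=25, seed=30)
    cfg = dg.FilterConfig(negf_n_perm=300)
    once, rep1 = dg.apply_site_and_individual_filters(structured_ds, depths, cfg)
    twice, rep2 = dg.apply_site_and_individual_filters(once, None, cfg)
    assert twice.n_sites == once.n_sites
    assert twice.n_individuals == once.n_individuals
    total_removed = sum(s["sites_removed"] + s["individuals_removed"] for s in rep2.stages)
    assert total_removed == 0


def test_ld_prune_duplicate_column_removes_exactly_one(panmictic_ds):
    calls = panmictic_ds.calls.copy()
    calls[:, 1] = calls[:, 0]
    ds = make_dataset(calls)
    out, removed = dg.ld_prune(ds)
    assert len(removed) == 1
    assert removed[0] in ("m0", "m1")


def test_ld_prune_triplicate_keeps_one(panmictic_ds):
    """Three mutually identical columns: two removed, one kept (the
    minimum removal set for a clique of size 3 under any order)."""
    calls = panmictic_ds.calls[:, :10].copy()
    calls[:, 1] = calls[:, 0]
    calls[:, 2] = calls[:, 0]
    ds = make_dataset(calls)
    out, removed = dg.ld_prune(ds)
    survivors = {"m0", "m1", "m2"} - set(map(str, removed))
    assert len(survivors) == 1


def test_ld_prune_independent_sites_retained(panmictic_ds):
    out, removed = dg.ld_prune(panmictic_ds)
    assert len(removed) < 0.02 * panmictic_ds.n_sites


def test_ld_prune_deterministic(structured_ds):
    _, r1 = dg.ld_prune(structured_ds)
    _, r2 = dg.ld_prune(structured_ds)
    assert np.array_equal(r1, r2)


def test_zero_variance_site_not_linked(panmictic_ds):
    calls = panmictic_ds.calls[:, :5].copy()
    calls[:, 0] = 1  # constant
    ds = make_dataset(calls)
    _, removed = dg.ld_prune(ds)
    assert "m0" not in set(map(str, removed))


def test_all_heterozygous_site_removed_as_paralog_signature():
    """Ho = 1 with He ~ 0.5 gives strongly negative F: removed."""
    rng = np.random.default_rng(0)
    calls = rng.binomial(1, 0.5, size=(40, 30)) + rng.binomial(1, 0.5, size=(40, 30))
    calls = calls.astype(np.int8)
    calls[:, 0] = 1  # every individual heterozygous
    ds = make_dataset(calls)
    out, removed, table = dg.filter_negative_f(ds, dg.FilterConfig(negf_n_perm=2000), seed=1)
    assert "m0" in set(map(str, removed))
    assert table.loc[table.site_id == "m0", "F"].iloc[0] < -0.8


def test_monomorphic_site_untested_and_retained():
    calls = np.zeros((10, 2), dtype=np.int8)
    calls[:, 1] = np.array([0, 0, 0, 1, 1, 1, 2, 2, 0, 1], dtype=np.int8)
    ds = make_dataset(calls)
    out, removed, table = dg.filter_negative_f(ds, dg.FilterConfig(negf_n_perm=200), seed=2)
    assert "m0" in set(map(str, out.site_ids))
    assert np.isnan(table.loc[table.site_id == "m0", "p"].iloc[0])


def test_negative_f_type_one_error_controlled():
    """HWE-null sites: flagged fraction at alpha=0.05 stays at or below 6%."""
    cfg = dg.SimConfig(
        n_groups=1, n_localities_per_group=1, n_individuals_per_locality=60,
        n_snps=2000, fst_between_groups=0, fst_between_localities=0,
        inbreeding_fis=0, missing_rate=0, seed=50,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    out, removed, table = dg.filter_negative_f(
        ds, dg.FilterConfig(negf_n_perm=2000), seed=51
    )
    assert len(removed) / table.p.notna().sum() <= 0.06


def test_pairing_null_is_exact_hypergeometric_pairing():
    """The sampled het-count null matches brute-force enumeration of all
    re-pairings for a small configuration."""
    import itertools

    n, n_alt = 4, 3
    alleles = [1] * n_alt + [0] * (2 * n - n_alt)
    counts = {}
    for perm in itertools.permutations(range(2 * n)):
        h = sum(alleles[perm[2 * i]] != alleles[perm[2 * i + 1]] for i in range(n))
        counts[h] = counts.get(h, 0) + 1
    total = sum(counts.values())
    brute = {h: c / total for h, c in counts.items()}
    hs, p = _het_pairing_pmf(n, n_alt)
    for h, prob in zip(hs, p):
        assert abs(brute.get(int(h), 0.0) - prob) < 1e-12


def test_permutation_p_calibration():
    """Null p-values are conservative (ECDF(a) <= a + slack) and their
    mid-p version is approximately uniform despite discreteness."""
    from scipy.stats import kstest

    cfg = dg.SimConfig(
        n_groups=1, n_localities_per_group=1, n_individuals_per_locality=60,
        n_snps=1500, fst_between_groups=0, fst_between_localities=0,
        inbreeding_fis=0, missing_rate=0, seed=60,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    _, _, table = dg.filter_negative_f(ds, dg.FilterConfig(negf_n_perm=2000), seed=61)
    p = table.p.dropna().to_numpy()
    for alpha in (0.01, 0.05, 0.1, 0.25):
        assert (p <= alpha).mean() <= alpha + 0.02

    rng = np.random.default_rng(62)
    calls = ds.calls
    ok = calls != MISSING
    n = ok.sum(0)
    alt = np.where(ok, calls, 0).sum(0)
    het = ((calls == 1) & ok).sum(0)
    mid = np.empty(calls.shape[1])
    for j in range(calls.shape[1]):
        h0 = sample_het_counts(int(n[j]), int(alt[j]), 1000, rng)
        mid[j] = (np.count_nonzero(h0 > het[j]) + 0.5 * np.count_nonzero(h0 == het[j])) / 1000
    assert kstest(mid, "uniform").statistic < 0.1


def test_every_removed_site_in_exactly_one_stage(structured_ds):
    depths = dg.simulate_read_depths(structured_ds, mean_depth=25, seed=70)
    cfg = dg.FilterConfig(negf_n_perm=300)
    filtered, report = dg.apply_site_and_individual_filters(structured_ds, depths, cfg)
    removed_total = sum(s["sites_removed"] for s in report.stages)
    assert removed_total == structured_ds.n_sites - filtered.n_sites


def test_empty_result_raises():
    calls = np.zeros((5, 3), dtype=np.int8)  # all monomorphic -> MAF 0
    ds = make_dataset(calls)
    with pytest.raises(ValueError, match="all sites"):
        dg.apply_site_and_individual_filters(ds, None, dg.FilterConfig())
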