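"""Generator sanity: HWE limits, parameter recovery, planted relatives,
read-depth dosage behaviour, trait separation, VCF round trip."""
import numpy as np
import pytest
from scipy.stats import chi2

import daisygen as dg
from daisygen.datatypes import MISSING


def test_seed_reproducibility():
    cfg = dg.SimConfig(n_snps=200, seed=42)
    a = dg.simulate_structured_genotypes(cfg)
    b = dg.simulate_structured_genotypes(cfg)
    assert np.array_equal(a.calls, b.calls)
    da = dg.simulate_read_depths(a, mean_depth=20, seed=7)
    db = dg.simulate_read_depths(b, mean_depth=20, seed=7)
    assert np.array_equal(da.ref_reads, db.ref_reads)


def test_config_validation():
    with pytest.raises(ValueError):
        dg.SimConfig(fst_between_groups=1.0)
    with pytest.raises(ValueError):
        dg.SimConfig(n_groups=0)
    with pytest.raises(ValueError):
        dg.SimConfig(ancestral_maf_range=(0.5, 0.1))


def test_no_structure_limit_is_hwe():
    """fst = fis = 0 everywhere: genotype frequencies pass a per-locus HWE
    chi-square test at >95% of loci."""
    cfg = dg.SimConfig(
        n_groups=2, n_localities_per_group=2, n_individuals_per_locality=50,
        n_snps=500, fst_between_groups=0.0, fst_between_localities=0.0,
        inbreeding_fis=0.0, missing_rate=0.0, seed=1,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    g = ds.calls
    n = g.shape[0]
    counts = np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)])
    p = (2 * counts[2] + counts[1]) / (2 * n)
    expected = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.nansum((counts - expected) ** 2 / np.maximum(expected, 1e-12), axis=0)
    pvals = chi2.sf(stat, df=1)
    assert (pvals > 0.05).mean() > 0.90


def test_fst_recovery():
    """Weir-Cockerham theta on simulated data recovers the configured FST."""
    thetas = []
    for seed in range(3):
        cfg = dg.SimConfig(
            n_groups=2, n_localities_per_group=1, n_individuals_per_locality=100,
            n_snps=3000, fst_between_groups=0.2, fst_between_localities=0.0,
            inbreeding_fis=0.0, missing_rate=0.02, seed=seed,
        )
        ds = dg.simulate_structured_genotypes(cfg)
        thetas.append(dg.weir_cockerham_fst(ds, ds.group_labels))
    assert abs(np.mean(thetas) - 0.2) < 0.02


def test_fis_recovery():
    cfg = dg.SimConfig(
        n_groups=1, n_localities_per_group=1, n_individuals_per_locality=50,
        n_snps=4000, fst_between_groups=0.0, fst_between_localities=0.0,
        inbreeding_fis=0.3, missing_rate=0.02, seed=9,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    stats = dg.locality_diversity(ds)
    assert abs(stats[0].gis - 0.3) < 0.03


def test_injected_clone_is_exact_copy(structured_ds):
    ds = dg.inject_relatives(structured_ds, n_clone_pairs=1, seed=3)
    (a, b, rel) = ds.truth["relative_pairs"][0]
    assert rel == "clone"
    assert np.array_equal(ds.calls[a], ds.calls[b])


def test_parent_offspring_has_no_opposing_homozygotes(structured_ds):
    ds = dg.inject_relatives(structured_ds, n_parent_offspring_pairs=2, seed=4)
    for a, b, rel in ds.truth["relative_pairs"]:
        ga, gb = ds.calls[a], ds.calls[b]
        ok = (ga != MISSING) & (gb != MISSING)
        opposing = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
        assert not (opposing & ok).any()


def test_fullsib_mean_kinship():
    cfg = dg.SimConfig(
        n_groups=1, n_localities_per_group=1, n_individuals_per_locality=90,
        n_snps=3000, fst_between_groups=0.0, fst_between_localities=0.0,
        inbreeding_fis=0.0, ancestral_maf_range=(0.05, 0.95),
        missing_rate=0.0, seed=5,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    ds = dg.inject_relatives(ds, n_fullsib_pairs=20, seed=6)
    km = dg.king_kinship(ds)
    sib_phi = [km.phi[a, b] for a, b, r in ds.truth["relative_pairs"]]
    assert abs(np.mean(sib_phi) - 0.25) < 0.03


def test_inject_relatives_capacity_error(panmictic_ds):
    with pytest.raises(ValueError, match="not enough"):
        dg.inject_relatives(panmictic_ds, n_clone_pairs=100)


def test_diploid_reference_fraction_centred_at_half():
    """Mean reference-read fraction at diploid het sites is 1/2."""
    cfg = dg.SimConfig(
        n_groups=1, n_localities_per_group=1, n_individuals_per_locality=2,
        n_snps=5000, fst_between_groups=0, fst_between_localities=0,
        inbreeding_fis=0, ancestral_maf_range=(0.4, 0.5), missing_rate=0, seed=11,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    depths = dg.simulate_read_depths(ds, mean_depth=30, seed=12)
    prof = dg.extract_dosage_profile(0, ds, depths, min_depth=10)
    assert prof.n_sites > 2000
    assert abs(prof.fractions.mean() - 0.5) < 0.01


def test_zero_depth_sites_excluded():
    calls = np.array([[1, 1]], dtype=np.int8)
    ds = dg.GenotypeDataset(
        calls=calls, sample_ids=np.array(["a"]), locality_labels=np.array(["l"]),
        group_labels=np.array([], dtype=str), coordinates=np.zeros((1, 2)),
        site_ids=np.array(["m0", "m1"]),
    )
    depths = dg.AlleleDepthTable(np.array([[0, 15]]), np.array([[0, 15]]))
    prof = dg.extract_dosage_profile(0, ds, depths, min_depth=10)
    assert prof.n_sites == 1


def test_triploid_dosage_bimodal():
    cfg = dg.SimConfig(
        n_groups=1, n_localities_per_group=1, n_individuals_per_locality=2,
        n_snps=4000, fst_between_groups=0, fst_between_localities=0,
        inbreeding_fis=0, ancestral_maf_range=(0.4, 0.5), missing_rate=0, seed=13,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    depths = dg.simulate_read_depths(ds, ploidy_map=np.array([3, 3]), mean_depth=30, seed=14)
    prof = dg.extract_dosage_profile(0, ds, depths)
    hist, edges = np.histogram(prof.fractions, bins=50, range=(0, 1))
    centres = (edges[:-1] + edges[1:]) / 2
    lower_mode = centres[np.argmax(np.where(centres < 0.5, hist, 0))]
    upper_mode = centres[np.argmax(np.where(centres > 0.5, hist, 0))]
    assert abs(lower_mode - 1 / 3) < 0.03
    assert abs(upper_mode - 2 / 3) < 0.03


def test_unsupported_ploidy_rejected(panmictic_ds):
    with pytest.raises(ValueError, match="ploidy"):
        dg.simulate_read_depths(panmictic_ds, ploidy_map=np.full(60, 5))


def test_traits_separate_groups_by_nearest_neighbour(structured_ds):
    """Distinct group trait means: 1-NN on the six-trait vector assigns
    leaves to their own group with >90% accuracy."""
    leaf, _ = dg.simulate_traits_and_environment(structured_ds, seed=20)
    df = dg.leaf_metrics(leaf)
    from daisygen.morpho import TRAIT_COLUMNS

    x = df[TRAIT_COLUMNS].to_numpy()
    x = (x - x.mean(0)) / x.std(0)
    groups = df["group"].to_numpy()
    from scipy.spatial.distance import cdist

    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    assert (groups[d.argmin(axis=1)] == groups).mean() > 0.9


def test_env_gradient_linear_in_x():
    cfg = dg.SimConfig(
        n_groups=2, n_localities_per_group=4, n_individuals_per_locality=5,
        n_snps=50, env_noise_sd=0.0, seed=23,
    )
    ds = dg.simulate_structured_genotypes(cfg)
    _, env = dg.simulate_traits_and_environment(
        ds, env_gradient=2.0, noise_sd=1e-6, seed=21
    )
    t = env.table
    fit = np.polyfit(t["x"], t["env1"], 1)
    assert abs(fit[0] - 2.0) < 0.01


def test_vcf_round_trip(tmp_path, structured_ds):
    depths = dg.simulate_read_depths(structured_ds, mean_depth=15, seed=22)
    path = tmp_path / "sim.vcf"
    dg.write_vcf(structured_ds, depths, path)
    ds2, d2 = dg.read_vcf(path)
    assert np.array_equal(structured_ds.calls, ds2.calls)
    assert np.array_equal(depths.ref_reads, d2.ref_reads)
    assert np.array_equal(depths.alt_reads, d2.alt_reads)
    # format rules: missing call serialised as ./.
    text = path.read_text()
    if (structured_ds.calls == MISSING).any():
        assert "./." in text
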