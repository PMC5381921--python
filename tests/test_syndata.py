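"""The synthetic dairy-genotype / multi-trait phenotype generator."""

import numpy as np
import pytest

from rhmap.syndata import (
    BTA_ARRAY_SNP_COUNTS,
    ConfigError,
    SimConfig,
    antagonistic_cattle_small,
    cattle_small,
    scaled_chromosome_counts,
    simulate_dataset,
    simulate_genotypes,
    simulate_traits,
    write_dataset,
)


def _one_trait_config(**kw):
    base = dict(
        n_individuals=4,
        chromosome_snp_counts=(10,),
        trait_names=("Y",),
        whole_var=(1.0,),
        resid_var=(1.0,),
        regional_var=(0.0,),
        seed=0,
    )
    base.update(kw)
    return SimConfig(**base)


def test_genotype_shape_coding_and_map():
    gm = simulate_genotypes(_one_trait_config())
    assert gm.values.shape == (4, 10)
    assert not np.isnan(gm.values).any()
    assert np.isin(gm.values, [0.0, 0.5, 1.0]).all()
    assert gm.snp_map["bp"].is_monotonic_increasing
    assert gm.snp_map["name"].is_unique


def test_genotype_frequencies_follow_hardy_weinberg():
    cfg = _one_trait_config(n_individuals=10_000, chromosome_snp_counts=(1,),
                            allele_freq_range=(0.5, 0.5), seed=2)
    gm = simulate_genotypes(cfg)
    col = gm.values[:, 0]
    n = col.size
    for code, expected in [(0.0, 0.25), (0.5, 0.5), (1.0, 0.25)]:
        prop = (col == code).mean()
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(prop - expected) < 3 * se


def test_same_seed_is_bit_identical():
    cfg = _one_trait_config(n_individuals=30, chromosome_snp_counts=(20, 20),
                            missing_rate=0.1, seed=5)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(cfg)
    np.testing.assert_array_equal(a.values, b.values)
    pa, ta = simulate_traits(a, cfg)
    pb, tb = simulate_traits(b, cfg)
    np.testing.assert_array_equal(pa["Y"], pb["Y"])


def test_missingness_rate_respected():
    cfg = _one_trait_config(n_individuals=500, chromosome_snp_counts=(200,),
                            missing_rate=0.05, seed=6)
    gm = simulate_genotypes(cfg)
    assert np.isnan(gm.values).mean() == pytest.approx(0.05, abs=0.01)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        _one_trait_config(n_individuals=0)
    with pytest.raises(ConfigError):
        _one_trait_config(allele_freq_range=(0.0, 0.5))
    with pytest.raises(ConfigError):
        _one_trait_config(regional_window=(0, 8, 5))  # overruns the chromosome
    with pytest.raises(ConfigError):
        _one_trait_config(regional_window=(3, 0, 5))  # no such chromosome


def test_null_mode_regional_effects_identically_zero():
    cfg = _one_trait_config(n_individuals=100, chromosome_snp_counts=(50,),
                            regional_window=(0, 10, 10), regional_var=(0.0,))
    gm, pheno, truth = simulate_dataset(cfg)
    assert (truth.regional_effects.to_numpy() == 0).all()


def test_phenotype_decomposition_is_exact():
    cfg = antagonistic_cattle_small(seed=3, n_individuals=150, total_snps=800)
    gm, pheno, truth = simulate_dataset(cfg)
    recon = (
        truth.mean
        + truth.whole_effects.to_numpy()
        + truth.regional_effects.to_numpy()
        + truth.residuals.to_numpy()
    )
    np.testing.assert_allclose(pheno[list(cfg.trait_names)].to_numpy(), recon, atol=1e-12)


def test_realized_genetic_variances_match_targets_exactly():
    cfg = antagonistic_cattle_small(seed=4, n_individuals=300, total_snps=800)
    _, _, truth = simulate_dataset(cfg)
    np.testing.assert_allclose(
        truth.realized.loc["whole"].to_numpy(), cfg.whole_var, rtol=1e-10
    )
    np.testing.assert_allclose(
        truth.realized.loc["regional"].to_numpy(), cfg.regional_var, rtol=1e-10
    )


def test_phenotypic_variance_is_sum_of_components():
    cfg = cattle_small(seed=7, n_individuals=2000, total_snps=500)
    _, pheno, _ = simulate_dataset(cfg)
    for i, trait in enumerate(cfg.trait_names):
        total = cfg.whole_var[i] + cfg.regional_var[i] + cfg.resid_var[i]
        assert pheno[trait].var() == pytest.approx(total, rel=0.15)


def test_polygenic_correlation_recovered_in_truth():
    cfg = cattle_small(seed=8, n_individuals=2000, total_snps=600)
    _, _, truth = simulate_dataset(cfg)
    w = truth.whole_effects.to_numpy()
    c = np.corrcoef(w.T)
    off = c[np.triu_indices(3, 1)]
    np.testing.assert_allclose(off, 0.85, atol=0.05)


def test_antagonistic_regional_truth_correlations_negative():
    cfg = antagonistic_cattle_small(seed=9, n_individuals=1000, total_snps=800)
    _, _, truth = simulate_dataset(cfg)
    r = truth.regional_effects
    assert np.corrcoef(r["FAT"], r["MLK"])[0, 1] < 0
    assert np.corrcoef(r["FAT"], r["PRT"])[0, 1] < 0
    assert np.corrcoef(r["MLK"], r["PRT"])[0, 1] > 0


def test_ld_option_induces_adjacent_dosage_correlation():
    cfg = _one_trait_config(n_individuals=2000, chromosome_snp_counts=(50,),
                            ld_rho=0.7, seed=10)
    gm = simulate_genotypes(cfg)
    adj = [
        np.corrcoef(gm.values[:, k], gm.values[:, k + 1])[0, 1] for k in range(49)
    ]
    assert np.mean(adj) > 0.2


def test_scaled_counts_preserve_layout():
    counts = scaled_chromosome_counts(2000)
    assert len(counts) == 29
    assert abs(sum(counts) - 2000) < 30
    # ordering follows the array layout: chromosome 1 has the most SNPs
    assert counts[0] == max(counts)
    assert sum(BTA_ARRAY_SNP_COUNTS) == 40646


def test_write_dataset_round_trips(tmp_path):
    from rhmap.genio import read_genotypes, read_phenotypes

    cfg = _one_trait_config(n_individuals=20, chromosome_snp_counts=(15,), seed=11)
    gm, pheno, _ = write_dataset(cfg, tmp_path)
    back = read_genotypes(tmp_path / "genotypes", "tsv")
    assert back.values.shape == gm.values.shape
    pheno_back = read_phenotypes(tmp_path / "phenotypes.tsv")
    np.testing.assert_allclose(pheno_back["Y"], pheno["Y"])
    assert (tmp_path / "manifest.json").exists()
    assert (tmp_path / "genotypes.bed").exists()
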