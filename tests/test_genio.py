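"""Genotype IO, allele frequencies, exact HWE test, and marker QC."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhmap.genio import (
    FormatError,
    QcError,
    allele_freqs,
    hwe_chisq_pvalue,
    hwe_exact_pvalue,
    qc_filter,
    read_genotypes,
    write_genotypes_tsv,
    write_plink,
)
from rhmap.syndata import SimConfig, simulate_genotypes

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# readers


def test_tsv_round_trip(tmp_path):
    gm = make_genotypes([[1, 0.5, 0], [1, np.nan, 0.5]])
    write_genotypes_tsv(gm, tmp_path / "toy")
    back = read_genotypes(tmp_path / "toy", "tsv")
    assert back.values.shape == (2, 3)
    # column 2 has mean 0.25 < 0.5 and is flipped on read
    expected = gm.values.copy()
    expected[:, 2] = 1 - expected[:, 2]
    np.testing.assert_array_equal(back.values, expected)
    assert back.ids == gm.ids


def test_plink_trio_matches_tsv(tmp_path):
    cfg = SimConfig(n_individuals=37, chromosome_snp_counts=(25, 14),
                    trait_names=("Y",), whole_var=(1.0,), resid_var=(1.0,),
                    regional_var=(0.0,), missing_rate=0.05, seed=4)
    gm = simulate_genotypes(cfg)
    write_genotypes_tsv(gm, tmp_path / "d")
    write_plink(gm, tmp_path / "d")
    via_tsv = read_genotypes(tmp_path / "d", "tsv")
    via_bed = read_genotypes(tmp_path / "d", "plink-bed")
    np.testing.assert_array_equal(via_tsv.values, via_bed.values)
    assert via_tsv.ids == via_bed.ids
    pd.testing.assert_frame_equal(
        via_tsv.snp_map, via_bed.snp_map.astype(via_tsv.snp_map.dtypes)
    )


def test_dimension_mismatch_is_a_format_error(tmp_path):
    gm = make_genotypes([[1, 0.5, 0], [1, 1, 0.5]])
    write_genotypes_tsv(gm, tmp_path / "bad")
    map_path = tmp_path / "bad.map.tsv"
    snp_map = pd.read_csv(map_path, sep="\t").iloc[:2]
    snp_map.to_csv(map_path, sep="\t", index=False)
    with pytest.raises(FormatError):
        read_genotypes(tmp_path / "bad", "tsv")


def test_bad_genotype_code_rejected():
    with pytest.raises(FormatError):
        make_genotypes([[1, 0.3]])


# ---------------------------------------------------------------------------
# allele frequencies


@pytest.mark.parametrize(
    "column, expected",
    [
        ([1, 0.5, 0], 0.5),
        ([1, 1, 0.5, 1], 0.875),
        ([1, 1, 1], 1.0),
    ],
)
def test_allele_freq_examples(column, expected):
    gm = make_genotypes(np.array(column, float)[:, None])
    assert allele_freqs(gm)[0] == pytest.approx(expected)


def test_allele_freq_requires_observations():
    gm = make_genotypes([[np.nan], [np.nan]])
    with pytest.raises(QcError):
        allele_freqs(gm)


def test_orientation_is_idempotent():
    cfg = SimConfig(n_individuals=50, chromosome_snp_counts=(30,),
                    trait_names=("Y",), whole_var=(1.0,), resid_var=(1.0,),
                    regional_var=(0.0,), seed=9)
    gm = simulate_genotypes(cfg)
    from rhmap.genio import _orient_major

    once = _orient_major(gm.values)
    np.testing.assert_array_equal(once, _orient_major(once))
    assert (np.nanmean(once, axis=0) >= 0.5).all()


# ---------------------------------------------------------------------------
# exact HWE test


def _hwe_enumeration(n_aa, n_ab, n_bb):
    """Independent oracle: enumerate every heterozygote configuration and
    weight by the exact conditional probability (integer combinatorics)."""
    n = n_aa + n_ab + n_bb
    rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (rare - h) // 2
        b = n - a - h
        weights[h] = (
            math.factorial(n)
            // (math.factorial(a) * math.factorial(h) * math.factorial(b))
            * 2**h
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= obs) / total


@pytest.mark.parametrize(
    "counts",
    [(5, 0, 0), (3, 4, 3), (8, 1, 1), (0, 10, 0), (2, 5, 13), (7, 7, 6), (1, 1, 18)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_pvalue(*counts) == pytest.approx(_hwe_enumeration(*counts), rel=1e-10)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_pvalue(5, 0, 0) == 1.0


@given(
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
    st.integers(min_value=0, max_value=30),
)
@settings(max_examples=60, derandomize=True)
def test_hwe_symmetric_in_homozygotes(a, h, b):
    if a + h + b == 0:
        return
    assert hwe_exact_pvalue(a, h, b) == pytest.approx(hwe_exact_pvalue(b, h, a))


def test_hwe_rejects_negative_counts():
    with pytest.raises(ValueError):
        hwe_exact_pvalue(-1, 2, 3)


def test_hwe_chisq_agrees_roughly_at_large_counts():
    exact = hwe_exact_pvalue(400, 120, 80)
    chisq = hwe_chisq_pvalue(400, 120, 80)
    assert (exact < 1e-4) == (chisq < 1e-4)


# ---------------------------------------------------------------------------
# QC filter


def _qc_fixture():
    """Five SNPs: one monomorphic (MAF), one 80%-call-rate, three clean."""
    rng = np.random.default_rng(5)
    n = 40
    clean = rng.binomial(2, 0.3, size=(n, 3)) / 2.0
    mono = np.ones((n, 1))
    low_cr = rng.binomial(2, 0.4, size=(n, 1)) / 2.0
    low_cr[: n // 5] = np.nan  # call rate 0.8
    return make_genotypes(np.hstack([clean, mono, low_cr]))


def test_qc_filter_removes_exactly_the_violators():
    gm = _qc_fixture()
    kept, report = qc_filter(gm)
    assert report.n_surviving == 3
    assert kept.n_snps == 3
    assert report.n_removed_maf == 1
    assert report.n_removed_call_rate == 1
    assert report.n_input - report.n_removed_total == report.n_surviving


def test_qc_vacuous_thresholds_keep_everything():
    gm = _qc_fixture()
    kept, report = qc_filter(gm, maf_min=0.0, call_rate_min=0.0, hwe_p_min=0.0)
    assert report.n_surviving == gm.n_snps
    assert kept.n_snps == gm.n_snps


def test_qc_boundary_maf_retained():
    # 100 individuals, minor-allele count 2 -> MAF exactly 0.01
    col = np.ones(100)
    col[0] = 0.0
    gm = make_genotypes(col[:, None])
    _, report = qc_filter(gm, maf_min=0.01, call_rate_min=0.0, hwe_p_min=0.0)
    assert report.n_surviving == 1


def test_qc_filter_is_idempotent():
    gm = _qc_fixture()
    kept, _ = qc_filter(gm)
    again, report = qc_filter(kept)
    assert report.n_removed_total == 0
    np.testing.assert_array_equal(kept.values, again.values)
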