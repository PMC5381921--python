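"""Synthetic genotypes and multi-trait pseudo-phenotypes.

Emulates the statistical structure of a progeny-tested dairy-sire dataset:
~29 autosomes of array SNPs in Hardy-Weinberg proportions, a polygenic
background that induces strongly positive between-trait correlations of the
whole-genome genetic values, and (optionally) one small window of
consecutive SNPs carrying a pleiotropic QTL whose effects have opposite
signs between one trait and the others — the antagonistic pattern the scan
and the effect-correlation analysis are built to detect.  Phenotypes stand
in for de-regressed breeding values with homoskedastic residual noise.

Genotypes are drawn in linkage equilibrium by default; ``ld_rho`` adds a
first-order Markov correlation between adjacent SNPs on a chromosome via a
Gaussian copula on the haplotypes, letting a regional signal spread over
neighbouring markers as in real data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .genio import GenotypeMatrix, write_genotypes_tsv, write_phenotypes, write_plink

__all__ = [
    "SimConfig",
    "TruthRecord",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_dataset",
    "write_dataset",
    "cattle_small",
    "antagonistic_cattle_small",
    "BTA_ARRAY_SNP_COUNTS",
    "scaled_chromosome_counts",
]

# Post-QC SNP counts per autosome of the 50K bovine array dataset the
# default configurations are scaled from (BTA1..BTA29, total 40,646).
BTA_ARRAY_SNP_COUNTS: tuple[int, ...] = (
    2630, 2126, 1999, 1967, 1714, 2002, 1749, 1860, 1621, 1699,
    1762, 1344, 1391, 1418, 1342, 1278, 1262, 1060, 1086, 1268,
    1113, 1013, 868, 1003, 796, 873, 786, 771, 845,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _check_corr(mat: np.ndarray, label: str, n_traits: int) -> np.ndarray:
    mat = np.asarray(mat, float)
    if mat.shape != (n_traits, n_traits):
        raise ConfigError(f"{label} must be {n_traits}x{n_traits}")
    if not np.allclose(mat, mat.T):
        raise ConfigError(f"{label} must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ConfigError(f"{label} must have a unit diagonal")
    if np.linalg.eigvalsh(mat).min() < -1e-10:
        raise ConfigError(f"{label} must be positive semi-definite")
    return mat


@dataclasses.dataclass
class SimConfig:
    """Generator settings; defaults are desk-scale but structurally faithful.

    ``regional_window`` is (chromosome ordinal 0-based, first SNP ordinal
    within that chromosome, window size) or None for a null dataset.
    Variances are in squared trait units; ``allele_freq_range`` bounds the
    minor-allele frequency.
    """

    n_individuals: int = 1000
    chromosome_snp_counts: tuple[int, ...] = ()
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    trait_names: tuple[str, ...] = ("MLK", "FAT", "PRT")
    # residual default reflects de-regressed proofs of reliability ~0.9
    # (sires averaging >50 daughters): residual ~ genetic/9
    whole_var: tuple[float, ...] = (5009.6, 485.6, 393.2)
    resid_var: tuple[float, ...] = (583.4, 58.7, 44.4)
    polygenic_corr: np.ndarray | None = None
    regional_window: tuple[int, int, int] | None = None
    regional_var: tuple[float, ...] = (0.0, 0.0, 0.0)
    regional_corr: np.ndarray | None = None
    missing_rate: float = 0.0
    ld_rho: float = 0.0
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chromosome_snp_counts:
            self.chromosome_snp_counts = tuple(scaled_chromosome_counts(2000))
        if self.n_individuals <= 0 or min(self.chromosome_snp_counts) <= 0:
            raise ConfigError("individual and SNP counts must be positive")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("allele_freq_range must satisfy 0 < lo <= hi <= 0.5")
        t = self.n_traits
        if not (len(self.whole_var) == len(self.resid_var) == len(self.regional_var) == t):
            raise ConfigError("per-trait variance tuples must match trait_names")
        if min(self.whole_var) < 0 or min(self.resid_var) < 0 or min(self.regional_var) < 0:
            raise ConfigError("variances must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must be in [0, 1)")
        if not -1 < self.ld_rho < 1:
            raise ConfigError("ld_rho must be in (-1, 1)")
        if self.polygenic_corr is None:
            self.polygenic_corr = np.eye(t)
        if self.regional_corr is None:
            self.regional_corr = np.eye(t)
        self.polygenic_corr = _check_corr(self.polygenic_corr, "polygenic_corr", t)
        self.regional_corr = _check_corr(self.regional_corr, "regional_corr", t)
        if self.regional_window is not None:
            c, first, size = self.regional_window
            if not 0 <= c < len(self.chromosome_snp_counts):
                raise ConfigError("regional_window chromosome out of range")
            if size <= 0 or first < 0 or first + size > self.chromosome_snp_counts[c]:
                raise ConfigError("regional_window does not fit on its chromosome")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_snps(self) -> int:
        return int(sum(self.chromosome_snp_counts))

    def window_global_index(self) -> np.ndarray:
        """Global ordinal SNP indices of the regional window (empty if none)."""
        if self.regional_window is None:
            return np.empty(0, dtype=int)
        c, first, size = self.regional_window
        offset = int(sum(self.chromosome_snp_counts[:c]))
        return np.arange(offset + first, offset + first + size)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["polygenic_corr"] = np.asarray(self.polygenic_corr).tolist()
        d["regional_corr"] = np.asarray(self.regional_corr).tolist()
        return d


@dataclasses.dataclass
class TruthRecord:
    """Ground truth: per-individual genetic values and realized components."""

    whole_effects: pd.DataFrame  # n x traits
    regional_effects: pd.DataFrame
    residuals: pd.DataFrame
    mean: float
    realized: pd.DataFrame  # rows: whole/regional/resid variance per trait


def scaled_chromosome_counts(total: int) -> list[int]:
    """Per-chromosome counts proportional to the 29-autosome array layout."""
    raw = np.array(BTA_ARRAY_SNP_COUNTS, float)
    counts = np.maximum(np.rint(raw / raw.sum() * total).astype(int), 10)
    return counts.tolist()


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes on the {0, 0.5, 1} coding with a SNP map."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.allele_freq_range
    maf = rng.uniform(lo, hi, size=m)

    if config.ld_rho == 0.0:
        minor_count = rng.binomial(2, maf, size=(n, m)).astype(float)
    else:
        minor_count = np.empty((n, m))
        rho = config.ld_rho
        col = 0
        for c in config.chromosome_snp_counts:
            z = np.empty((2 * n, c))
            z[:, 0] = rng.standard_normal(2 * n)
            eps = rng.standard_normal((2 * n, c - 1)) if c > 1 else None
            for k in range(1, c):
                z[:, k] = rho * z[:, k - 1] + np.sqrt(1 - rho * rho) * eps[:, k - 1]
            thr = ndtri(maf[col : col + c])
            hap = (z < thr).astype(float)
            minor_count[:, col : col + c] = hap[:n] + hap[n:]
            col += c

    values = 1.0 - minor_count / 2.0  # 1 = major homozygote
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        values[mask] = np.nan

    chroms = np.repeat(
        np.arange(1, len(config.chromosome_snp_counts) + 1),
        config.chromosome_snp_counts,
    )
    bp = np.concatenate(
        [np.arange(1, c + 1) * 50_000 for c in config.chromosome_snp_counts]
    )
    names = [f"snp_c{c}_{i}" for c, i in zip(chroms, bp // 50_000)]
    snp_map = pd.DataFrame({"name": names, "chrom": chroms, "bp": bp})
    ids = [f"ind{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(values=values, snp_map=snp_map, ids=ids)


def _genetic_values(
    gm: GenotypeMatrix,
    snp_index: np.ndarray,
    corr: np.ndarray,
    target_var: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Correlated per-SNP effects -> genetic values, rescaled so the realized
    per-trait variance equals ``target_var`` exactly."""
    n, t = gm.n_individuals, corr.shape[0]
    out = np.zeros((n, t))
    if snp_index.size == 0 or np.all(target_var == 0):
        return out
    x = gm.values[:, snp_index]
    p = np.nanmean(x, axis=0)
    centred = np.where(np.isnan(x), 0.0, x - p)
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(t))
    effects = rng.standard_normal((snp_index.size, t)) @ chol.T
    raw = centred @ effects
    raw -= raw.mean(axis=0)
    sd = raw.std(axis=0)
    for j in range(t):
        if target_var[j] == 0:
            continue
        if sd[j] == 0:
            raise ConfigError("degenerate genetic values: window SNPs are monomorphic")
        out[:, j] = raw[:, j] * np.sqrt(target_var[j]) / sd[j]
    return out


def simulate_traits(gm: GenotypeMatrix, config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Phenotypes = mean + whole effect + regional effect + residual.

    Whole effects come from per-SNP effects over all non-window SNPs with
    between-trait correlation ``polygenic_corr``; regional effects from the
    window SNPs with ``regional_corr``; both are rescaled so the realized
    per-trait variances equal the configured values exactly.
    """
    if gm.n_snps != config.n_snps:
        raise ConfigError("genotype matrix does not match the configured map")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    window = config.window_global_index()
    nonwindow = np.setdiff1d(np.arange(gm.n_snps), window)
    t = config.n_traits
    whole = _genetic_values(gm, nonwindow, config.polygenic_corr,
                            np.asarray(config.whole_var, float), rng)
    regional = _genetic_values(gm, window, config.regional_corr,
                               np.asarray(config.regional_var, float), rng)
    resid = rng.standard_normal((gm.n_individuals, t)) * np.sqrt(
        np.asarray(config.resid_var, float)
    )
    y = config.mean + whole + regional + resid
    pheno = pd.DataFrame(y, columns=list(config.trait_names))
    pheno.insert(0, "id", gm.ids)
    traits = list(config.trait_names)
    truth = TruthRecord(
        whole_effects=pd.DataFrame(whole, columns=traits, index=gm.ids),
        regional_effects=pd.DataFrame(regional, columns=traits, index=gm.ids),
        residuals=pd.DataFrame(resid, columns=traits, index=gm.ids),
        mean=config.mean,
        realized=pd.DataFrame(
            {
                "whole": whole.var(axis=0),
                "regional": regional.var(axis=0),
                "residual": resid.var(axis=0),
            },
            index=traits,
        ).T,
    )
    return pheno, truth


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    gm = simulate_genotypes(config)
    pheno, truth = simulate_traits(gm, config)
    return gm, pheno, truth


def write_dataset(
    config: SimConfig, out_dir: str | Path, plink: bool = True
) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord]:
    """Simulate and write genotype TSV (+ PLINK trio), phenotypes, truth
    tables and a run manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gm, pheno, truth = simulate_dataset(config)
    write_genotypes_tsv(gm, out / "genotypes")
    if plink:
        write_plink(gm, out / "genotypes")
    write_phenotypes(pheno, out / "phenotypes.tsv")
    truth.whole_effects.to_csv(out / "truth_whole_effects.tsv", sep="\t")
    truth.regional_effects.to_csv(out / "truth_regional_effects.tsv", sep="\t")
    truth.realized.to_csv(out / "truth_realized_variances.tsv", sep="\t")
    manifest = {"seed": config.seed, "config": config.to_dict()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return gm, pheno, truth


def cattle_small(seed: int = 0, n_individuals: int = 1000, total_snps: int = 2000,
                 **overrides) -> SimConfig:
    """Null-mode desk-scale default: 29 chromosomes scaled proportionally to
    the array layout (~2,000 SNPs), no regional window."""
    kwargs = dict(
        n_individuals=n_individuals,
        chromosome_snp_counts=tuple(scaled_chromosome_counts(total_snps)),
        seed=seed,
        polygenic_corr=_uniform_corr(3, 0.85),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def antagonistic_cattle_small(seed: int = 0, n_individuals: int = 1000,
                              total_snps: int = 2000, window_size: int = 20,
                              **overrides) -> SimConfig:
    """Desk-scale dataset with the antagonistic pleiotropic window.

    One window on chromosome 14 (ordinal 13) carries a regional QTL whose
    effect is negatively correlated (-0.9) between FAT and the other two
    traits while the polygenic background is positively correlated (+0.85),
    with regional variances at the magnitudes of the mapped dairy window.
    """
    kwargs = dict(
        n_individuals=n_individuals,
        chromosome_snp_counts=tuple(scaled_chromosome_counts(total_snps)),
        seed=seed,
        polygenic_corr=_uniform_corr(3, 0.85),
        regional_window=(13, 0, window_size),
        regional_var=(240.9, 42.7, 6.0),
        regional_corr=_signed_corr([1.0, -1.0, 1.0], 0.9),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def _uniform_corr(t: int, rho: float) -> np.ndarray:
    m = np.full((t, t), rho)
    np.fill_diagonal(m, 1.0)
    return m


def _signed_corr(signs, rho: float) -> np.ndarray:
    s = np.asarray(signs, float)
    m = rho * np.outer(s, s)
    np.fill_diagonal(m, 1.0)
    return m
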