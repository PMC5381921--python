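"""Genotype and phenotype input, allele frequencies, and marker quality control.

Genotypes live on the half-dosage coding used throughout the package:
``0`` = rare-allele homozygote, ``0.5`` = heterozygote, ``1`` = common
(major-allele) homozygote, ``NaN`` = missing.  On this coding the per-SNP
mean of the non-missing values equals the major-allele frequency, which is
what the kinship formula in :mod:`rhmap.grm` centres on.

Two on-disk dialects are supported:

* a plain TSV pair ``<prefix>.geno.tsv`` (rows = individuals, first column
  ``id``, one column per SNP with codes ``{0, 0.5, 1, NA}``) plus
  ``<prefix>.map.tsv`` (columns ``name``, ``chrom``, ``bp``);
* the PLINK binary trio ``<prefix>.bed/.bim/.fam`` (SNP-major .bed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "GenotypeMatrix",
    "QcReport",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_plink",
    "read_phenotypes",
    "write_phenotypes",
    "allele_freqs",
    "hwe_exact_pvalue",
    "hwe_chisq_pvalue",
    "qc_filter",
]

MAP_COLUMNS = ["name", "chrom", "bp"]


def _ext(prefix: "str | Path", ext: str) -> "Path":
    return Path(str(prefix) + ext)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK .bed header


class FormatError(ValueError):
    """Inconsistent or unparseable genotype input."""


class QcError(ValueError):
    """A computation requires QC (e.g. an all-missing SNP) first."""


@dataclasses.dataclass
class GenotypeMatrix:
    """n individuals x m SNPs on the {0, 0.5, 1} coding with NaN for missing.

    ``snp_map`` is a DataFrame with columns ``name``, ``chrom``, ``bp`` in
    matrix column order; SNPs are sorted by (chromosome, bp) and names are
    unique.
    """

    values: np.ndarray
    snp_map: pd.DataFrame
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("genotype values must be a 2-D array")
        if self.values.shape != (len(self.ids), len(self.snp_map)):
            raise FormatError(
                f"genotype matrix is {self.values.shape} but there are "
                f"{len(self.ids)} ids and {len(self.snp_map)} mapped SNPs"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, (0.0, 0.5, 1.0)).all():
            raise FormatError("genotype codes must be in {0, 0.5, 1, NaN}")
        if self.snp_map["name"].duplicated().any():
            raise FormatError("SNP names must be unique")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, index].copy(),
            snp_map=self.snp_map.iloc[index].reset_index(drop=True),
            ids=list(self.ids),
        )

    def snp_index(self, name: str) -> int:
        hits = np.flatnonzero((self.snp_map["name"] == name).to_numpy())
        if hits.size == 0:
            raise KeyError(f"unknown SNP name: {name!r}")
        return int(hits[0])


@dataclasses.dataclass
class QcReport:
    """Per-SNP QC metrics and the bookkeeping of a filtering pass."""

    per_snp: pd.DataFrame  # name, maf, call_rate, hwe_p, kept
    n_input: int
    n_removed_maf: int
    n_removed_call_rate: int
    n_removed_hwe: int
    n_removed_total: int
    n_surviving: int

    def to_tsv(self, path: str | Path) -> None:
        self.per_snp.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers


def _orient_major(values: np.ndarray) -> np.ndarray:
    """Flip SNP columns so that 1 codes the sample-major homozygote.

    A column whose mean dosage is below 0.5 is recoded g -> 1 - g; exact
    ties keep the orientation of the input (the allele listed first in the
    map wins).
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(values, axis=0)
    flip = freq < 0.5
    values = values.copy()
    values[:, flip] = 1.0 - values[:, flip]
    return values


def read_genotypes(prefix: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix and normalise allele orientation.

    ``format`` is ``"tsv"`` or ``"plink-bed"``; ``prefix`` is the path
    without the dialect-specific extensions.
    """
    if format == "tsv":
        gm = _read_tsv(Path(prefix))
    elif format == "plink-bed":
        gm = _read_plink(Path(prefix))
    else:
        raise FormatError(f"unknown genotype format: {format!r}")
    gm.values = _orient_major(gm.values)
    return gm


def _read_tsv(prefix: Path) -> GenotypeMatrix:
    geno_path = _ext(prefix, ".geno.tsv")
    map_path = _ext(prefix, ".map.tsv")
    table = pd.read_csv(geno_path, sep="\t", dtype={"id": str})
    if table.columns[0] != "id":
        raise FormatError("genotype TSV must start with an 'id' column")
    snp_map = pd.read_csv(map_path, sep="\t")
    missing_cols = [c for c in MAP_COLUMNS if c not in snp_map.columns]
    if missing_cols:
        raise FormatError(f"map TSV lacks columns {missing_cols}")
    values = table.iloc[:, 1:].to_numpy(dtype=float)
    if values.shape[1] != len(snp_map):
        raise FormatError(
            f"map lists {len(snp_map)} SNPs but matrix has {values.shape[1]} columns"
        )
    if list(table.columns[1:]) != list(snp_map["name"]):
        raise FormatError("genotype column order disagrees with the map")
    return GenotypeMatrix(values=values, snp_map=snp_map[MAP_COLUMNS], ids=list(table["id"]))


def write_genotypes_tsv(gm: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    table = pd.DataFrame(gm.values, columns=gm.snp_map["name"])
    table.insert(0, "id", gm.ids)
    table.to_csv(_ext(prefix, ".geno.tsv"), sep="\t", index=False, na_rep="NA")
    gm.snp_map[MAP_COLUMNS].to_csv(
        _ext(prefix, ".map.tsv"), sep="\t", index=False
    )


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        _ext(prefix, ".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "name", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(
        _ext(prefix, ".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = _ext(prefix, ".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(".bed magic bytes missing or not SNP-major")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise FormatError(".bed payload size disagrees with .bim/.fam dimensions")
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, individual-fastest within each SNP record
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n].T  # n x m
    # 00 = hom A1, 10 = het, 11 = hom A2, 01 = missing; A1 counted as rare
    lut = np.array([0.0, np.nan, 0.5, 1.0])
    values = lut[codes]
    snp_map = bim[["name", "chrom", "bp"]].copy()
    return GenotypeMatrix(values=values, snp_map=snp_map, ids=list(fam["iid"]))


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write the PLINK trio; allele A1 is the rare allele (code 0 = hom A1)."""
    prefix = Path(prefix)
    bim = pd.DataFrame(
        {
            "chrom": gm.snp_map["chrom"],
            "name": gm.snp_map["name"],
            "cm": 0,
            "bp": gm.snp_map["bp"],
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(_ext(prefix, ".bim"), sep="\t", index=False, header=False)
    fam = pd.DataFrame(
        {"fid": gm.ids, "iid": gm.ids, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(_ext(prefix, ".fam"), sep="\t", index=False, header=False)
    n, m = gm.values.shape
    # map {0, 0.5, 1, NaN} -> 2-bit codes {00, 10, 11, 01}
    codes = np.full((m, n), 0b01, dtype=np.uint8)
    vals = gm.values.T
    codes[vals == 0.0] = 0b00
    codes[vals == 0.5] = 0b10
    codes[vals == 1.0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.full((m, pad), 0b01, np.uint8)], axis=1)
    packed = (
        codes.reshape(m, -1, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint32).astype(np.uint8)
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: column ``id`` then one numeric column per trait."""
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    if table.columns[0] != "id":
        raise FormatError("phenotype TSV must start with an 'id' column")
    return table


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# frequencies and QC


def allele_freqs(gm: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Per-SNP major-allele frequency p_k = mean of non-missing dosages."""
    values = gm.values if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)
    n_obs = (~np.isnan(values)).sum(axis=0)
    if (n_obs == 0).any():
        bad = int(np.flatnonzero(n_obs == 0)[0])
        raise QcError(f"SNP column {bad} is entirely missing; run qc_filter first")
    with np.errstate(invalid="ignore"):
        return np.nanmean(values, axis=0)


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums the probabilities of all heterozygote counts compatible with the
    observed allele counts whose conditional probability does not exceed the
    observed table's (two-sided exact test).
    """
    counts = (int(n_hom_major), int(n_het), int(n_hom_minor))
    if min(counts) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype is required")
    rare = 2 * counts[2] + counts[1]
    common = 2 * counts[0] + counts[1]
    rare, common = min(rare, common), max(rare, common)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = (common - hets) // 2
    # P(h | allele counts) proportional to 2^h * n! / (hom_r! h! hom_c!)
    logp = hets * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1) - gammaln(hom_c + 1)
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[np.flatnonzero(hets == counts[1])[0]]
    return float(prob[prob <= observed * (1 + 1e-12)].sum())


def hwe_chisq_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """One-df chi-square HWE test (provided as an alternative to the exact test)."""
    n = n_hom_major + n_het + n_hom_minor
    if n == 0:
        raise ValueError("at least one genotype is required")
    p = (2 * n_hom_major + n_het) / (2 * n)
    q = 1 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_major, n_het, n_hom_minor], float)
    if (expected == 0).any():
        return 1.0
    stat = ((observed - expected) ** 2 / expected).sum()
    return float(chi2.sf(stat, df=1))


def _snp_qc_metrics(values: np.ndarray) -> pd.DataFrame:
    n = values.shape[0]
    obs = ~np.isnan(values)
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / n
    maf = np.full(values.shape[1], np.nan)
    hwe_p = np.full(values.shape[1], np.nan)
    for k in range(values.shape[1]):
        col = values[obs[:, k], k]
        if col.size == 0:
            continue
        p = col.mean()
        maf[k] = min(p, 1 - p)
        n_mm = int((col == 1.0).sum())
        n_het = int((col == 0.5).sum())
        n_mm_minor = int((col == 0.0).sum())
        hwe_p[k] = hwe_exact_pvalue(n_mm, n_het, n_mm_minor)
    return pd.DataFrame({"call_rate": call_rate, "maf": maf, "hwe_p": hwe_p})


def qc_filter(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing any of the MAF / call-rate / HWE criteria.

    A SNP is removed when its MAF, call rate, or exact HWE p-value is
    *strictly below* the corresponding threshold; values at the threshold
    are retained.  All-missing SNPs always fail the call-rate rule.
    """
    for name, t in (("maf_min", maf_min), ("call_rate_min", call_rate_min), ("hwe_p_min", hwe_p_min)):
        if not 0 <= t <= 1:
            raise ValueError(f"{name} must be in [0, 1]")
    metrics = _snp_qc_metrics(gm.values)
    fail_maf = metrics["maf"].fillna(0).to_numpy() < maf_min
    fail_cr = metrics["call_rate"].to_numpy() < call_rate_min
    fail_hwe = metrics["hwe_p"].fillna(1).to_numpy() < hwe_p_min
    kept = ~(fail_maf | fail_cr | fail_hwe)
    per_snp = pd.concat([gm.snp_map[["name"]].reset_index(drop=True), metrics], axis=1)
    per_snp["kept"] = kept
    report = QcReport(
        per_snp=per_snp,
        n_input=gm.n_snps,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_call_rate=int(fail_cr.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_removed_total=int((~kept).sum()),
        n_surviving=int(kept.sum()),
    )
    return gm.subset_snps(np.flatnonzero(kept)), report
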