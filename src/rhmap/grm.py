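"""Genomic relationship matrices and the 50%-overlap window scheme.

The IBS kinship between individuals i and j over n SNPs is

    f_ij = (1/n) * sum_k (g_ik - p_k)(g_jk - p_k) / (p_k (1 - p_k)),

with genotypes on the half-dosage coding (0 / 0.5 / 1) and p_k the
major-allele frequency.  The relationship matrix used in the mixed model
carries 2 f_ij off the diagonal and 2 f_ii on the diagonal; under
Hardy-Weinberg the coding's variance is p(1-p)/2, so E[2 f_ii] = 1 + F and
the diagonal is "one plus the inbreeding coefficient" without an external
estimator.  On the 0/1/2 dosage scale the same matrix is the VanRaden-style
standardised cross-product (x - 2p)(x' - 2p) / (2p(1-p)) averaged over SNPs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, allele_freqs

__all__ = [
    "KinshipMatrix",
    "Window",
    "kinship_pair",
    "build_grm",
    "make_windows",
    "write_grm_text",
    "read_grm_text",
    "windows_to_frame",
]


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric n x n relationship matrix (whole-genome G or regional Q)."""

    matrix: np.ndarray
    snp_count: int
    snp_index: np.ndarray
    kind: str = "whole"  # "whole" | "regional"
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.isfinite(self.matrix).all():
            raise ValueError("kinship matrix has non-finite entries")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def with_ridge(self, ridge: float) -> "KinshipMatrix":
        if ridge == 0:
            return self
        return dataclasses.replace(
            self, matrix=self.matrix + ridge * np.eye(self.n)
        )


@dataclasses.dataclass
class Window:
    """A contiguous run of SNPs on one chromosome defining a regional GRM.

    ``start``/``stop`` are inclusive global ordinal SNP indices (0-based).
    """

    window_id: int
    chrom: object
    start: int
    stop: int
    first_name: str
    last_name: str
    first_bp: int
    last_bp: int

    @property
    def size(self) -> int:
        return self.stop - self.start + 1

    @property
    def index(self) -> np.ndarray:
        return np.arange(self.start, self.stop + 1)


def kinship_pair(g_i: np.ndarray, g_j: np.ndarray, p: np.ndarray) -> float:
    """IBS kinship f_ij between two genotype vectors.

    Missing entries in either vector are dropped; n is the number of SNPs
    actually used.  Frequencies must be strictly inside (0, 1).
    """
    g_i = np.asarray(g_i, float)
    g_j = np.asarray(g_j, float)
    p = np.asarray(p, float)
    if not g_i.shape == g_j.shape == p.shape:
        raise ValueError("genotype and frequency vectors must share a shape")
    use = ~(np.isnan(g_i) | np.isnan(g_j))
    use &= (p > 0) & (p < 1)
    if not use.any():
        raise ValueError("no usable SNPs for this pair (all missing or monomorphic)")
    num = (g_i[use] - p[use]) * (g_j[use] - p[use]) / (p[use] * (1 - p[use]))
    return float(num.mean())


def build_grm(
    gm: GenotypeMatrix,
    snp_subset: Sequence[int] | np.ndarray | None = None,
    freqs: np.ndarray | None = None,
    kind: str = "whole",
) -> KinshipMatrix:
    """Relationship matrix 2f over a SNP subset (default: all SNPs).

    Missing genotypes are mean-imputed with p_k before the cross-product
    (their centred contribution is zero).  SNPs monomorphic in-sample are
    dropped from n.  ``freqs``, if given, must be whole-matrix per-SNP
    frequencies; by default they are computed from ``gm`` itself, so a
    regional matrix built on a subset still centres on the whole-sample
    frequencies.
    """
    if snp_subset is None:
        snp_subset = np.arange(gm.n_snps)
    snp_subset = np.asarray(snp_subset, dtype=int)
    if snp_subset.size == 0:
        raise ValueError("empty SNP subset")
    if freqs is None:
        freqs = allele_freqs(gm)
    p = np.asarray(freqs, float)[snp_subset]
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs in the subset are monomorphic")
    keep = snp_subset[poly]
    p = p[poly]
    x = gm.values[:, keep]
    centred = x - p
    centred[np.isnan(x)] = 0.0  # mean imputation
    w = centred / np.sqrt(p * (1 - p))
    a = (2.0 / keep.size) * (w @ w.T)
    a = (a + a.T) / 2.0
    return KinshipMatrix(matrix=a, snp_count=int(keep.size), snp_index=keep, kind=kind, ids=list(gm.ids))


def make_windows(
    snp_map: pd.DataFrame | Iterable[int],
    size: int,
    shift: int | None = None,
) -> list[Window]:
    """Sliding windows of ``size`` SNPs shifted by ``shift`` (default size/2).

    Per chromosome, windows start at ordinal 0, shift, 2*shift, ... while a
    full window fits; if the regular grid does not end at the last SNP one
    end-anchored window covering the final ``size`` SNPs is appended.  A
    chromosome with fewer than ``size`` SNPs yields a single window of all
    its SNPs.  Windows never span chromosomes.
    """
    if size < 2:
        raise ValueError("window size must be at least 2")
    shift = size // 2 if shift is None else shift
    if shift < 1:
        raise ValueError("shift must be at least 1")

    if isinstance(snp_map, pd.DataFrame):
        chroms = snp_map["chrom"].to_numpy()
        names = snp_map["name"].to_numpy()
        bps = snp_map["bp"].to_numpy()
        labels = list(pd.unique(chroms))
        counts = [int((chroms == c).sum()) for c in labels]
    else:
        counts = [int(c) for c in snp_map]
        labels = list(range(1, len(counts) + 1))
        names = bps = None

    windows: list[Window] = []
    offset = 0
    wid = 0
    for label, c in zip(labels, counts):
        if c <= 0:
            raise ValueError(f"chromosome {label!r} has no SNPs")
        if c < size:
            spans = [(0, c - 1)]
        else:
            spans = []
            start = 0
            while start + size <= c:
                spans.append((start, start + size - 1))
                start += shift
            if spans[-1][1] != c - 1:
                spans.append((c - size, c - 1))
        for lo, hi in spans:
            a, b = offset + lo, offset + hi
            windows.append(
                Window(
                    window_id=wid,
                    chrom=label,
                    start=a,
                    stop=b,
                    first_name=str(names[a]) if names is not None else f"snp{a}",
                    last_name=str(names[b]) if names is not None else f"snp{b}",
                    first_bp=int(bps[a]) if bps is not None else lo + 1,
                    last_bp=int(bps[b]) if bps is not None else hi + 1,
                )
            )
            wid += 1
        offset += c
    return windows


def windows_to_frame(windows: Sequence[Window]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "stop": [w.stop for w in windows],
            "first_name": [w.first_name for w in windows],
            "last_name": [w.last_name for w in windows],
            "first_bp": [w.first_bp for w in windows],
            "last_bp": [w.last_bp for w in windows],
            "size": [w.size for w in windows],
        }
    )


def write_grm_text(km: KinshipMatrix, prefix: str | Path) -> None:
    """GCTA-style text GRM: lower triangle as (i, j, snp_count, value) rows
    in ``<prefix>.grm.tsv`` plus ids in ``<prefix>.grm.id``."""
    prefix = Path(str(prefix))
    ids = km.ids or [str(i + 1) for i in range(km.n)]
    with open(str(prefix) + ".grm.tsv", "w") as fh:
        for i in range(km.n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{km.snp_count}\t{km.matrix[i, j]:.10g}\n")
    with open(str(prefix) + ".grm.id", "w") as fh:
        for s in ids:
            fh.write(f"{s}\t{s}\n")


def read_grm_text(prefix: str | Path, kind: str = "whole") -> KinshipMatrix:
    tab = pd.read_csv(
        str(prefix) + ".grm.tsv", sep="\t", header=None, names=["i", "j", "m", "value"]
    )
    ids = pd.read_csv(str(prefix) + ".grm.id", sep="\t", header=None)[1].astype(str).tolist()
    n = int(tab["i"].max())
    a = np.zeros((n, n))
    a[tab["i"] - 1, tab["j"] - 1] = tab["value"]
    a = a + np.tril(a, -1).T
    return KinshipMatrix(
        matrix=a,
        snp_count=int(tab["m"].iloc[0]),
        snp_index=np.arange(int(tab["m"].iloc[0])),
        kind=kind,
        ids=ids,
    )
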