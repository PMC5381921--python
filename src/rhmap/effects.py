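"""Correlations among whole-genome and regional BLUPs, and genotype-class
partitioning of regional effects.

The antagonism analysis correlates, across individuals, the predicted
whole-genome effects u-hat and regional effects w-hat of each trait fitted
at a common window: a positively correlated whole-genome block together
with negative regional correlations between one trait and the others is
the signature of an antagonistic pleiotropic locus.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix

__all__ = ["EffectCorrelations", "GenotypePartition", "effect_correlations", "genotype_partition"]

_CLASS_BY_CODE = {1.0: "MM", 0.5: "Mm", 0.0: "mm"}


@dataclasses.dataclass
class EffectCorrelations:
    """(2T x 2T) Pearson correlation matrix over {whole, regional} x traits."""

    corr: pd.DataFrame
    pvalues: pd.DataFrame
    n: int

    def to_tsv(self, prefix) -> None:
        self.corr.to_csv(str(prefix) + ".corr.tsv", sep="\t")
        self.pvalues.to_csv(str(prefix) + ".pvalues.tsv", sep="\t")


@dataclasses.dataclass
class GenotypePartition:
    """Individuals classed MM / Mm / mm / missing at one SNP, with their
    regional-effect values attached for plotting."""

    table: pd.DataFrame  # id, gclass, one column per trait
    snp_name: str
    class_means: pd.DataFrame  # gclass x traits

    def counts(self) -> pd.Series:
        return self.table["gclass"].value_counts()


def effect_correlations(
    effects: dict[str, dict[str, np.ndarray]],
) -> EffectCorrelations:
    """Pearson correlations among all u-hat and w-hat vectors.

    ``effects`` maps trait name -> {"whole": u-hat, "regional": w-hat}.
    Vectors with zero variance (e.g. w-hat from a boundary fit) yield NaN
    entries rather than zeros, so masked components stay visible.
    P-values are the two-sided t-test with n - 2 df.
    """
    labels: list[tuple[str, str]] = []
    vectors: list[np.ndarray] = []
    for kind in ("whole", "regional"):
        for trait, d in effects.items():
            if kind in d:
                labels.append((kind, trait))
                vectors.append(np.asarray(d[kind], float).ravel())
    if not vectors:
        raise ValueError("no effect vectors supplied")
    n = vectors[0].size
    if any(v.size != n for v in vectors):
        raise ValueError("effect vectors must share the same individuals")
    k = len(vectors)
    corr = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    sds = [v.std() for v in vectors]
    for i in range(k):
        for j in range(i, k):
            if i == j:
                corr[i, j] = 1.0 if sds[i] > 0 else np.nan
                pval[i, j] = 0.0 if sds[i] > 0 else np.nan
                continue
            if sds[i] == 0 or sds[j] == 0:
                continue
            r = float(np.corrcoef(vectors[i], vectors[j])[0, 1])
            corr[i, j] = corr[j, i] = r
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            pval[i, j] = pval[j, i] = p
    idx = pd.MultiIndex.from_tuples(labels, names=["component", "trait"])
    return EffectCorrelations(
        corr=pd.DataFrame(corr, index=idx, columns=idx),
        pvalues=pd.DataFrame(pval, index=idx, columns=idx),
        n=n,
    )


def genotype_partition(
    genotypes: GenotypeMatrix,
    snp_name: str,
    regional_effects: dict[str, np.ndarray],
) -> GenotypePartition:
    """Class individuals by genotype at ``snp_name`` (MM = major homozygote,
    Mm = heterozygote, mm = minor homozygote) and attach per-trait regional
    effects; per-class means are computed for the scatter export."""
    k = genotypes.snp_index(snp_name)
    col = genotypes.values[:, k]
    gclass = np.array(
        ["missing" if np.isnan(g) else _CLASS_BY_CODE[g] for g in col], dtype=object
    )
    table = pd.DataFrame({"id": genotypes.ids, "gclass": gclass})
    for trait, vec in regional_effects.items():
        vec = np.asarray(vec, float).ravel()
        if vec.size != genotypes.n_individuals:
            raise ValueError(f"effect vector for {trait!r} has the wrong length")
        table[trait] = vec
    traits = list(regional_effects)
    means = table[table["gclass"] != "missing"].groupby("gclass")[traits].mean()
    return GenotypePartition(table=table, snp_name=snp_name, class_means=means)
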