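"""GRAMMAR-style single-SNP association.

Two steps: (1) fit the whole-genome mixed model once and take the residuals
e-hat = y - 1*mu-hat - u-hat, which are adjusted for genomic relatedness;
(2) regress those residuals on each SNP's dosage by ordinary least squares
and test the slope with an F statistic on (1, n_complete - 2) df.  The
residuals are not re-scaled (no GRAMMAR-gamma correction), so the tests are
mildly conservative — documented behaviour of the original procedure.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import f as f_dist

from .genio import GenotypeMatrix
from .grm import KinshipMatrix
from .varcomp import MixedModelSpec, VarCompFit, reml_fit

__all__ = [
    "GrammarResult",
    "grammar_residuals",
    "snp_ftest",
    "bonferroni_neglog10",
    "run_grammar",
]

_LN10 = float(np.log(10.0))
_F_CAP = 1e12  # cap for a numerically perfect fit


@dataclasses.dataclass
class GrammarResult:
    """Per-SNP association table with genome-wide Bonferroni flags."""

    table: pd.DataFrame
    n_snps_tested: int
    thresholds: dict[float, float]  # alpha -> -log10 p cutoff
    null_fit: VarCompFit

    def top_hits(self, n: int = 10) -> pd.DataFrame:
        tab = self.table.dropna(subset=["f_value"])
        return tab.sort_values("f_value", ascending=False).head(n).reset_index(drop=True)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_snps_tested={self.n_snps_tested}\n")
            for alpha, cut in sorted(self.thresholds.items(), reverse=True):
                fh.write(f"# neglog10p_threshold alpha={alpha} cutoff={cut:.4f}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def grammar_residuals(
    y: np.ndarray,
    G: KinshipMatrix | np.ndarray,
    null_fit: VarCompFit | None = None,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, VarCompFit]:
    """Mixed-model residuals e-hat = y - 1*mu-hat - u-hat from the G + I fit."""
    y = np.asarray(y, float).ravel()
    if isinstance(G, KinshipMatrix):
        G = G.with_ridge(ridge)
    spec = MixedModelSpec(y=y, components=[("whole", G)])
    if null_fit is None:
        null_fit = reml_fit(spec)
    resid = y - null_fit.mu - null_fit.blups["whole"]
    return resid, null_fit


def _neglog10_f_sf(f_value: np.ndarray, dfd: np.ndarray) -> np.ndarray:
    """-log10 of the F(1, dfd) upper tail, switching to the log-space normal
    tail (z = sqrt(F), exact as dfd -> inf) where the survival function
    underflows."""
    p = f_dist.sf(f_value, 1, dfd)
    out = np.empty_like(p)
    ok = p > 1e-290
    out[ok] = -np.log10(p[ok])
    if (~ok).any():
        z = np.sqrt(f_value[~ok])
        out[~ok] = -(np.log(2.0) + log_ndtr(-z)) / _LN10
    return out


def snp_ftest(residuals: np.ndarray, snp: np.ndarray) -> tuple[float, float, float]:
    """OLS regression of residuals on one SNP's dosage.

    Returns (slope, F, -log10 p); missing genotypes are dropped.  Raises on
    a constant SNP or fewer than 3 complete pairs.
    """
    residuals = np.asarray(residuals, float)
    snp = np.asarray(snp, float)
    ok = ~np.isnan(snp)
    x, r = snp[ok], residuals[ok]
    if x.size < 3:
        raise ValueError("fewer than 3 complete pairs")
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx == 0:
        raise ValueError("SNP is constant among complete cases")
    sxy = float(((x - x.mean()) * (r - r.mean())).sum())
    syy = float(((r - r.mean()) ** 2).sum())
    slope = sxy / sxx
    ssr = slope * sxy
    sse = max(syy - ssr, 0.0)
    dfd = x.size - 2
    if sse == 0:
        return slope, _F_CAP, _neglog10_f_sf(np.array([_F_CAP]), np.array([dfd]))[0]
    f_value = ssr / (sse / dfd)
    neglog = _neglog10_f_sf(np.array([f_value]), np.array([dfd]))[0]
    return slope, float(f_value), float(neglog)


def bonferroni_neglog10(alpha: float, n_snps: int) -> float:
    """Genome-wide -log10 p cutoff: -log10(alpha / n_snps)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be at least 1")
    return float(-np.log10(alpha / n_snps))


def run_grammar(
    y: np.ndarray,
    G: KinshipMatrix,
    genotypes: GenotypeMatrix,
    alphas: tuple[float, ...] = (0.05, 0.01),
    bonferroni_n: int | None = None,
    ridge: float = 1e-6,
    null_fit: VarCompFit | None = None,
) -> GrammarResult:
    """Residuals once, then a vectorised per-SNP F-test over all SNPs."""
    resid, null_fit = grammar_residuals(y, G, null_fit=null_fit, ridge=ridge)
    vals = genotypes.values
    n, m = vals.shape
    obs = ~np.isnan(vals)
    n_obs = obs.sum(axis=0)
    x = np.where(obs, vals, 0.0)
    r = resid
    sx = x.sum(axis=0)
    sr = obs.T @ r
    sxx = (x * x).sum(axis=0) - sx * sx / np.maximum(n_obs, 1)
    sxy = x.T @ r - sx * sr / np.maximum(n_obs, 1)
    srr = obs.T @ (r * r) - sr * sr / np.maximum(n_obs, 1)

    testable = (n_obs >= 3) & (sxx > 0)
    slope = np.full(m, np.nan)
    f_value = np.full(m, np.nan)
    neglog = np.full(m, np.nan)
    t = testable
    slope[t] = sxy[t] / sxx[t]
    ssr = slope[t] * sxy[t]
    sse = np.maximum(srr[t] - ssr, 0.0)
    dfd = n_obs[t] - 2
    with np.errstate(divide="ignore"):
        fv = np.where(sse > 0, ssr / np.maximum(sse, 1e-300) * dfd, _F_CAP)
    fv = np.minimum(fv, _F_CAP)
    f_value[t] = fv
    neglog[t] = _neglog10_f_sf(fv, dfd.astype(float))

    n_tested = bonferroni_n if bonferroni_n is not None else int(testable.sum())
    thresholds = {a: bonferroni_neglog10(a, n_tested) for a in alphas}
    table = pd.DataFrame(
        {
            "name": genotypes.snp_map["name"],
            "chrom": genotypes.snp_map["chrom"],
            "bp": genotypes.snp_map["bp"],
            "n_complete": n_obs,
            "slope": slope,
            "f_value": f_value,
            "neglog10p": neglog,
        }
    )
    for alpha in alphas:
        table[f"sig_{int(alpha * 100)}pct"] = table["neglog10p"] > thresholds[alpha]
    return GrammarResult(
        table=table, n_snps_tested=n_tested, thresholds=thresholds, null_fit=null_fit
    )
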