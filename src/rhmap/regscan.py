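"""Window scan: boundary-mixture LRT, genome-wide thresholds, variance ratios.

Because the regional variance is tested on the boundary of its parameter
space (sigma_w^2 = 0), the null distribution of LRT = -2 ln(L0/L1) is a
50:50 mixture of a point mass at zero and chi-square with 1 df.  The
mixture survival function simplifies neatly: 0.5 * Pr(chi2_1 > x) =
Phi(-sqrt(x)), which both keeps the threshold inversion closed-form and,
via the log of the normal tail, lets genome-wide -log10 P stay accurate for
statistics whose raw p-values are far below double-precision underflow.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from .genio import GenotypeMatrix
from .grm import KinshipMatrix, Window, build_grm
from .varcomp import MixedModelSpec, VarCompFit, reml_fit

__all__ = [
    "ScanResult",
    "mixture_pvalue",
    "lrt_threshold",
    "genomewide_neglog10p",
    "regional_ratio",
    "scan",
]

logger = logging.getLogger(__name__)

_LN10 = float(np.log(10.0))
_LRT_ZERO = 1e-8  # below this a statistic is the boundary point mass


@dataclasses.dataclass
class ScanResult:
    """Per-window scan table plus metadata and thresholds."""

    table: pd.DataFrame
    trait: str
    window_size: int
    shift: int
    n_windows: int  # Bonferroni N actually used
    thresholds: dict[float, float]  # alpha -> LRT cutoff
    null_fit: VarCompFit

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# trait={self.trait} window_size={self.window_size} "
                     f"shift={self.shift} bonferroni_n={self.n_windows}\n")
            for alpha, cut in sorted(self.thresholds.items(), reverse=True):
                fh.write(f"# lrt_threshold alpha={alpha} cutoff={cut:.4f}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def mixture_pvalue(lrt: float) -> float:
    """P-value under the 50:50 point-mass / chi-square(1) mixture null."""
    if lrt < 0:
        raise ValueError("LRT must be non-negative")
    if lrt < _LRT_ZERO:
        return 1.0
    # 0.5 * chi2_1 survival = standard normal tail at sqrt(lrt)
    return float(ndtr(-np.sqrt(lrt)))


def lrt_threshold(alpha: float, n_windows: int) -> float:
    """LRT cutoff x solving 0.5 * Pr(chi2_1 > x) = alpha / n_windows."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_windows < 1:
        raise ValueError("n_windows must be at least 1")
    return float(ndtri(alpha / n_windows) ** 2)


def genomewide_neglog10p(lrt: float, n_windows: int) -> float:
    """-log10 of the Bonferroni-adjusted mixture p, computed in log space."""
    if lrt < 0:
        raise ValueError("LRT must be non-negative")
    if lrt < _LRT_ZERO:
        return 0.0
    log_p = np.log(n_windows) + log_ndtr(-np.sqrt(lrt))
    return float(max(0.0, -log_p / _LN10))


def regional_ratio(sigma_u2: float, sigma_w2: float) -> float:
    """Regional share of total genomic variance, in percent."""
    if sigma_u2 < 0 or sigma_w2 < 0:
        raise ValueError("variances must be non-negative")
    total = sigma_u2 + sigma_w2
    if total == 0:
        raise ZeroDivisionError("both genomic variances are zero; ratio undefined")
    return 100.0 * sigma_w2 / total


def scan(
    y: np.ndarray,
    G: KinshipMatrix,
    windows: list[Window],
    genotypes: GenotypeMatrix,
    trait: str = "trait",
    alphas: tuple[float, ...] = (0.05, 0.01),
    bonferroni_n: int | None = None,
    ridge: float = 1e-6,
    freqs: np.ndarray | None = None,
    null_fit: VarCompFit | None = None,
) -> ScanResult:
    """Fit the two-component model at every window and test the regional
    variance against the G-only null.

    The null fit is computed once (or supplied) and its likelihood is, by
    construction, the alternative likelihood at sigma_w^2 = 0, so
    LRT = 2 (logL1 - logL0) clamped at zero is exact under boundary
    handling.  Windows whose SNPs are all monomorphic are skipped with a
    row of missing statistics.
    """
    y = np.asarray(y, float).ravel()
    g_ridge = G.with_ridge(ridge)
    spec0 = MixedModelSpec(y=y, components=[("whole", g_ridge)])
    if null_fit is None:
        null_fit = reml_fit(spec0)
    ll0 = null_fit.loglik
    s2u0 = null_fit.variances["whole"]
    s2e0 = null_fit.variances["residual"]
    n_bonf = bonferroni_n if bonferroni_n is not None else len(windows)
    thresholds = {a: lrt_threshold(a, n_bonf) for a in alphas}

    rows = []
    for w in windows:
        try:
            q = build_grm(genotypes, w.index, freqs=freqs, kind="regional")
        except ValueError as exc:
            logger.warning("window %d skipped: %s", w.window_id, exc)
            rows.append(_row(w, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        spec1 = MixedModelSpec(
            y=y, components=[("whole", g_ridge), ("regional", q.with_ridge(ridge))]
        )
        start = np.array([s2u0, max(0.05 * s2u0, 1e-4 * np.var(y)), s2e0])
        fit1 = reml_fit(spec1, start=start)
        lrt = 2.0 * (fit1.loglik - ll0)
        if lrt < 0:
            if lrt < -1e-6:
                logger.warning(
                    "window %d: alternative logL below null by %.3g; clamped",
                    w.window_id, -lrt,
                )
            lrt = 0.0
        if lrt < _LRT_ZERO:
            lrt = 0.0
        s2u = fit1.variances["whole"]
        s2w = fit1.variances["regional"]
        s2e = fit1.variances["residual"]
        ratio = regional_ratio(s2u, s2w) if (s2u + s2w) > 0 else np.nan
        rows.append(
            _row(
                w, lrt, mixture_pvalue(lrt), genomewide_neglog10p(lrt, n_bonf),
                s2u, s2w, s2e, ratio,
            )
        )
        logger.info(
            "window %d chrom %s [%d-%d]: LRT=%.3f ratio=%.2f%%",
            w.window_id, w.chrom, w.start, w.stop, lrt, 0.0 if np.isnan(ratio) else ratio,
        )

    table = pd.DataFrame(rows)
    for alpha in alphas:
        table[f"sig_{int(alpha * 100)}pct"] = table["lrt"] > thresholds[alpha]
    size = windows[0].size if windows else 0
    shift = (windows[1].start - windows[0].start) if len(windows) > 1 else size
    return ScanResult(
        table=table,
        trait=trait,
        window_size=size,
        shift=shift,
        n_windows=n_bonf,
        thresholds=thresholds,
        null_fit=null_fit,
    )


def _row(w: Window, lrt, p, neglog10p, s2u, s2w, s2e, ratio) -> dict:
    return {
        "window_id": w.window_id,
        "chrom": w.chrom,
        "start": w.start,
        "stop": w.stop,
        "first_name": w.first_name,
        "last_name": w.last_name,
        "first_bp": w.first_bp,
        "last_bp": w.last_bp,
        "lrt": lrt,
        "mixture_p": p,
        "gw_neglog10p": neglog10p,
        "sigma_u2": s2u,
        "sigma_w2": s2w,
        "sigma_e2": s2e,
        "regional_pct": ratio,
    }
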