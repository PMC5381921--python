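"""REML variance-component estimation and BLUP for genomic mixed models.

The model is y = 1*mu + Z*u (+ Z*w) + e with Var(u) = G*sigma_u^2,
Var(w) = Q*sigma_w^2, Var(e) = I*sigma_e^2, so V = sigma_u^2 G + sigma_w^2 Q
+ sigma_e^2 I.  The restricted log-likelihood, with the intercept profiled
out, is

    logL_R = -1/2 [ (n - p) log(2*pi) + log|V| + log|X'V^-1 X| + y'Py ],

P = V^-1 - V^-1 X (X'V^-1 X)^-1 X'V^-1.  All constants are kept so that
differences between nested fits are valid likelihood-ratio statistics.

Optimisation is average-information (AI) REML with step halving and an
EM-REML fallback when the AI matrix is not positive definite.  Variance
proposals that go negative are projected onto the boundary (fixed at zero
and the remaining components re-optimised), which is what makes the 50:50
chi-square mixture the correct null for the boundary likelihood-ratio test.
Single-genomic-component models (the null G + I fit) take a fast exact path
through the eigendecomposition of G, profiling the residual variance and
optimising only the variance ratio.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .grm import KinshipMatrix

__all__ = ["MixedModelSpec", "VarCompFit", "reml_loglik", "reml_fit", "blup"]

_LOG2PI = float(np.log(2.0 * np.pi))


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    """V was not positive definite; increase the GRM ridge."""


@dataclasses.dataclass
class MixedModelSpec:
    """Phenotype plus the list of genomic covariance structures.

    ``components`` maps component names (e.g. ``"whole"``, ``"regional"``)
    to relationship matrices; the residual identity component is implicit.
    The fixed part is an intercept only.
    """

    y: np.ndarray
    components: list[tuple[str, np.ndarray]]
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        comps = []
        for name, k in self.components:
            mat = k.matrix if isinstance(k, KinshipMatrix) else np.asarray(k, float)
            if mat.shape != (self.y.size, self.y.size):
                raise ValueError(
                    f"component {name!r} is {mat.shape}, y has length {self.y.size}"
                )
            comps.append((name, mat))
        self.components = comps
        if self.y.size < 3:
            raise ValueError("need at least 3 records")
        if np.var(self.y) == 0:
            raise ValueError("phenotype has zero variance; nothing to fit")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.components] + ["residual"]


@dataclasses.dataclass
class VarCompFit:
    """REML estimates, restricted log-likelihood, intercept and BLUPs."""

    variances: dict[str, float]  # component name -> estimate (incl. "residual")
    loglik: float
    mu: float
    blups: dict[str, np.ndarray]  # component name -> BLUP vector
    residuals: np.ndarray  # e-hat = y - mu - sum of BLUPs
    converged: bool
    n_iter: int
    boundary: dict[str, bool]

    def variance(self, name: str) -> float:
        return self.variances[name]

    def blup_vector(self, name: str) -> np.ndarray:
        if name not in self.blups:
            raise KeyError(
                f"component {name!r} was not in the fitted model"
            )
        return self.blups[name]


# ---------------------------------------------------------------------------
# restricted likelihood


def _v_matrix(spec: MixedModelSpec, variances: Sequence[float]) -> np.ndarray:
    variances = np.asarray(variances, float)
    v = variances[-1] * np.eye(spec.n)
    for (name, k), s in zip(spec.components, variances[:-1]):
        if s != 0:
            v = v + s * k
    return v


def _reml_parts(spec: MixedModelSpec, variances: Sequence[float]):
    """Return (loglik, P, Py) for the given variance vector."""
    n = spec.n
    v = _v_matrix(spec, variances)
    try:
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    except np.linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            "V is not positive definite; increase the GRM ridge or check inputs"
        ) from exc
    logdet_v = 2.0 * float(np.log(np.diag(c)).sum())
    vinv = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    vi1 = vinv.sum(axis=1)  # V^-1 X with X = 1
    xtvix = float(vi1.sum())
    p = vinv - np.outer(vi1, vi1) / xtvix
    py = p @ spec.y
    ypy = float(spec.y @ py)
    ll = -0.5 * ((n - 1) * _LOG2PI + logdet_v + np.log(xtvix) + ypy)
    return ll, p, py, vinv, vi1, xtvix


def reml_loglik(spec: MixedModelSpec, variances: Sequence[float]) -> float:
    """Restricted log-likelihood at a variance vector (components..., residual)."""
    variances = np.asarray(variances, float)
    if variances.size != len(spec.components) + 1:
        raise ValueError("one variance per genomic component plus the residual")
    if (variances < 0).any():
        raise ValueError("variances must be non-negative")
    return _reml_parts(spec, variances)[0]


# ---------------------------------------------------------------------------
# single-component exact path (null model G + I)


def _fit_single_eig(spec: MixedModelSpec) -> tuple[np.ndarray, float]:
    """Exact REML for one genomic component via eigendecomposition.

    V = sigma_e^2 (gamma * G + I); the residual variance is profiled out and
    the likelihood maximised over log(gamma), with the gamma = 0 boundary
    checked explicitly.
    """
    y = spec.y
    n = spec.n
    g = spec.components[0][1]
    lam, u = np.linalg.eigh(g)
    lam = np.clip(lam, 0.0, None)
    yt = u.T @ y
    xt = u.T @ np.ones(n)

    def neg_profile(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        d = gamma * lam + 1.0
        xtvx = float((xt * xt / d).sum())
        beta = float((xt * yt / d).sum()) / xtvx
        r = yt - beta * xt
        ypy = float((r * r / d).sum())
        s2e = ypy / (n - 1)
        ll = -0.5 * (
            (n - 1) * _LOG2PI
            + float(np.log(d).sum())
            + (n - 1) * np.log(s2e)
            + np.log(xtvx)
            + (n - 1)
        )
        return -ll

    grid = np.linspace(-12.0, 12.0, 49)
    vals = [neg_profile(g_) for g_ in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(neg_profile, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    best_lg = float(res.x)
    best = -neg_profile(best_lg)

    # boundary gamma -> 0: plain intercept model
    r0 = y - y.mean()
    s2e0 = float(r0 @ r0) / (n - 1)
    ll0 = -0.5 * ((n - 1) * _LOG2PI + (n - 1) * np.log(s2e0) + np.log(float(n)) + (n - 1))
    if ll0 >= best:
        return np.array([0.0, s2e0]), ll0
    gamma = np.exp(best_lg)
    d = gamma * lam + 1.0
    xtvx = float((xt * xt / d).sum())
    beta = float((xt * yt / d).sum()) / xtvx
    r = yt - beta * xt
    s2e = float((r * r / d).sum()) / (n - 1)
    return np.array([gamma * s2e, s2e]), best


# ---------------------------------------------------------------------------
# AI-REML


def _em_step(spec, variances, p, py, active):
    n = spec.n
    new = variances.copy()
    mats = [k for _, k in spec.components] + [None]
    for i in np.flatnonzero(active):
        s = variances[i]
        if s == 0:
            continue
        ki = mats[i]
        if ki is None:
            tr = float(np.trace(p))
            quad = float(py @ py)
        else:
            tr = float((p * ki).sum())
            quad = float(py @ (ki @ py))
        new[i] = max(s + (s * s) * (quad - tr) / n, 0.0)
    return new


def reml_fit(
    spec: MixedModelSpec,
    start: Sequence[float] | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-6,
    tol_param: float = 1e-8,
    min_resid_frac: float = 1e-8,
) -> VarCompFit:
    """Maximise the restricted likelihood over the non-negative orthant.

    Starting values default to half the phenotypic variance for the
    residual with the remainder split equally among genomic components.
    Components driven to zero are fixed at the boundary and the rest
    re-optimised; the returned fit flags them.
    """
    n_comp = len(spec.components)
    vary = float(np.var(spec.y, ddof=1))

    if n_comp == 1 and start is None:
        variances, ll = _fit_single_eig(spec)
        fit = _finalise(spec, variances, ll, converged=True, n_iter=0)
        return fit

    if start is None:
        variances = np.full(n_comp + 1, vary / 2.0)
        variances[:-1] /= n_comp
    else:
        variances = np.asarray(start, float).copy()
        if variances.size != n_comp + 1:
            raise ValueError("start must have one entry per component plus residual")
        variances = np.clip(variances, 0.0, None)
    floor = min_resid_frac * vary
    variances[-1] = max(variances[-1], floor)

    ll, p, py, *_ = _reml_parts(spec, variances)
    mats = [k for _, k in spec.components] + [None]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        active = np.ones(n_comp + 1, bool)
        # scores
        scores = np.empty(n_comp + 1)
        t_vecs = []
        for i, ki in enumerate(mats):
            if ki is None:
                tr = float(np.trace(p))
                kpy = py
            else:
                tr = float((p * ki).sum())
                kpy = ki @ py
            scores[i] = -0.5 * (tr - float(py @ kpy))
            t_vecs.append(kpy)
        # components pinned at zero with downhill score stay fixed
        for i in range(n_comp):
            if variances[i] == 0.0 and scores[i] <= 0:
                active[i] = False
        idx = np.flatnonzero(active)
        pt = [p @ t_vecs[i] for i in idx]
        ai = 0.5 * np.array([[float(t_vecs[i] @ pt[jj]) for jj, j in enumerate(idx)] for i in idx])

        step = None
        try:
            delta = np.linalg.solve(ai + 1e-12 * np.eye(idx.size), scores[idx])
            step = np.zeros(n_comp + 1)
            step[idx] = delta
        except np.linalg.LinAlgError:
            step = None

        improved = False
        if step is not None:
            scale = 1.0
            for _ in range(25):
                prop = variances + scale * step
                prop = np.clip(prop, 0.0, None)
                prop[-1] = max(prop[-1], floor)
                try:
                    ll_new, p_new, py_new, *_ = _reml_parts(spec, prop)
                except NotPositiveDefiniteError:
                    scale /= 2.0
                    continue
                if ll_new >= ll - 1e-12:
                    improved = True
                    break
                scale /= 2.0
        if not improved:
            prop = _em_step(spec, variances, p, py, active)
            prop[-1] = max(prop[-1], floor)
            try:
                ll_new, p_new, py_new, *_ = _reml_parts(spec, prop)
            except NotPositiveDefiniteError:
                break
            if ll_new < ll - 1e-10:
                # neither AI nor EM improves: converged as far as we can go
                converged = True
                break

        rel = np.abs(prop - variances) / np.maximum(np.abs(variances), 1e-12 + vary * 1e-12)
        d_ll = ll_new - ll
        variances, ll, p, py = prop, ll_new, p_new, py_new
        if abs(d_ll) < tol_loglik and (rel.max() < tol_param or abs(d_ll) < tol_loglik * 1e-2):
            converged = True
            break

    return _finalise(spec, variances, ll, converged=converged, n_iter=it)


def _finalise(spec: MixedModelSpec, variances: np.ndarray, ll: float,
              converged: bool, n_iter: int) -> VarCompFit:
    ll_check, p, py, vinv, vi1, xtvix = _reml_parts(spec, variances)
    vi_y = vinv @ spec.y
    mu = float(vi1 @ spec.y) / xtvix
    blups: dict[str, np.ndarray] = {}
    for (name, k), s in zip(spec.components, variances[:-1]):
        blups[name] = s * (k @ py)
    resid = variances[-1] * py
    names = spec.names
    vdict = {name: float(s) for name, s in zip(names, variances)}
    boundary = {name: bool(s == 0.0) for name, s in zip(names, variances)}
    return VarCompFit(
        variances=vdict,
        loglik=float(ll_check),
        mu=mu,
        blups=blups,
        residuals=resid,
        converged=converged,
        n_iter=n_iter,
        boundary=boundary,
    )


def blup(fit: VarCompFit, spec: MixedModelSpec) -> dict[str, np.ndarray]:
    """BLUP vectors u-hat = sigma^2 K V^-1 (y - 1 mu-hat) for each component.

    The decomposition identity u-hat + w-hat + e-hat = y - 1 mu-hat holds
    exactly because V * V^-1 (y - 1 mu-hat) telescopes.
    """
    variances = [fit.variances[name] for name, _ in spec.components] + [
        fit.variances["residual"]
    ]
    _, _, py, *_ = _reml_parts(spec, variances)
    out = {name: s * (k @ py) for (name, k), s in zip(spec.components, variances[:-1])}
    out["residual"] = variances[-1] * py
    return out
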