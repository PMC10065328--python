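"""Univariate and bivariate (two-year) REML mixed models with BLUP.

The univariate model is

    y = 1*mu + g + e,   g ~ N(0, sg2 * K),  e ~ N(0, se2 * I),

maximized exactly over lambda = sg2/se2 by eigendecomposition of the
intercept-projected kernel (one-dimensional, deterministic profile REML).

The bivariate model treats the same trait measured in two years as two
traits with per-year intercepts:

    y_t = 1*mu_t + g_t + e_t,   (g_1; g_2) ~ N(0, G0 kron K),

residuals independent within and between years (different seasons and
plots, so the residual covariance is structurally zero), unbalanced line
sets allowed.  Estimation is EM-REML through the mixed-model equations
(monotone in the restricted likelihood) with a guarded average-information
(AI) step: the AI proposal is taken only when it keeps the genetic
covariance matrix PSD (after eigenvalue clipping), respects the variance
floor, and does not decrease the restricted log-likelihood; otherwise the
EM step is used.

``fit_with_protocol`` implements the two-stage initialization used for
cross-validation: variance components are pre-estimated on the full
dataset (at most 100 iterations; non-converged components at iteration
100 are still usable as starting values), each fold fit starts from the
pre-fit components and runs at most 50 iterations, and a fold fit that
does not converge falls back to BLUPs computed with the components fixed
at the starting values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .data_io import PhenotypeRecords
from .kernels import RelationshipKernel

logger = logging.getLogger("epiblup")

__all__ = [
    "UnivariateFit",
    "BivariateFit",
    "reml_univariate",
    "reml_bivariate",
    "fit_with_protocol",
    "genomic_correlation",
    "genomic_heritability",
    "predict_blup",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class UnivariateFit:
    beta_hat: float
    sigma2_g: float
    sigma2_e: float
    lam: float
    logL_reml: float
    g_hat: pd.Series  # indexed by kernel line id, all lines
    converged: bool
    n_iter: int


@dataclass
class BivariateFit:
    years: tuple[int, int]
    beta_hat: np.ndarray          # per-year intercepts
    G0: np.ndarray                # 2x2 genetic (co)variance
    sigma2_e1: float
    sigma2_e2: float
    logL_reml: float
    g_hat: pd.DataFrame           # index line id, columns the two years
    converged: bool
    n_iter: int
    init_values: np.ndarray       # (g11, g12, g22, e1, e2) at start
    fixed_fallback: bool = False
    logL_path: np.ndarray = field(default=None, repr=False)

    @property
    def components(self) -> np.ndarray:
        return np.array(
            [self.G0[0, 0], self.G0[0, 1], self.G0[1, 1], self.sigma2_e1, self.sigma2_e2]
        )


# ---------------------------------------------------------------------------
# univariate


def _projected_spectrum(k_obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of S K S on the intercept-orthogonal contrast space."""
    n = k_obs.shape[0]
    s = np.eye(n) - np.full((n, n), 1.0 / n)
    w, v = np.linalg.eigh(s @ k_obs @ s)
    # drop the eigenvector spanned by the intercept (smallest |value| after
    # projection is exactly 0 up to roundoff); keep the top n-1
    return w[1:], v[:, 1:]


def reml_univariate(
    y: pd.Series,
    K: RelationshipKernel,
    max_iter: int = 100,
) -> UnivariateFit:
    """Exact profile REML for the single-kernel animal model.

    ``y`` is indexed by line id (a subset of the kernel lines, >= 10).
    BLUPs are returned for every kernel line, including unphenotyped ones,
    via the kernel cross-block.
    """
    y = y.dropna()
    if len(y) < 10:
        raise ValueError(f"need >= 10 phenotyped lines, got {len(y)}")
    obs = K.index_of(y.index)
    yv = y.to_numpy(dtype=float)
    n = len(yv)
    k_full = K.ridged()
    k_obs = k_full[np.ix_(obs, obs)]

    xi, u = _projected_spectrum(k_obs)
    eta = u.T @ yv
    spread = float(xi.max() - xi.min())
    if spread <= 1e-8 * max(abs(float(xi.max())), 1.0):
        warnings.warn(
            "kernel is proportional to identity on the contrast space; "
            "genetic and residual variances are not separately identifiable",
            stacklevel=2,
        )

    nm1 = n - 1

    def neg_restricted_ll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        d = lam * xi + 1.0
        r = float(np.sum(eta**2 / d))
        ll = 0.5 * (nm1 * np.log(nm1 / (2.0 * np.pi * r)) - nm1 - float(np.sum(np.log(d))))
        return -ll

    grid = np.linspace(-20.0, 20.0, 161)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i0 = int(np.argmin(vals))
    lo, hi = grid[max(i0 - 1, 0)], grid[min(i0 + 1, len(grid) - 1)]
    res = minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10, "maxiter": max_iter},
    )
    log_lam = float(res.x) if res.fun <= vals[i0] else float(grid[i0])
    lam = float(np.exp(log_lam))
    d = lam * xi + 1.0
    se2 = float(np.sum(eta**2 / d)) / nm1
    floor = 1e-10 * float(np.var(yv))
    se2 = max(se2, floor)
    sg2 = max(lam * se2, floor)

    v_obs = sg2 * k_obs + se2 * np.eye(n)
    cf = cho_factor(v_obs)
    vinv_y = cho_solve(cf, yv)
    vinv_1 = cho_solve(cf, np.ones(n))
    mu = float(np.ones(n) @ vinv_y) / float(np.ones(n) @ vinv_1)
    resid = cho_solve(cf, yv - mu)
    g_all = sg2 * (k_full[:, obs] @ resid)
    return UnivariateFit(
        beta_hat=mu, sigma2_g=sg2, sigma2_e=se2, lam=sg2 / se2,
        logL_reml=-float(res.fun),
        g_hat=pd.Series(g_all, index=list(K.line_ids)),
        converged=bool(res.success), n_iter=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# bivariate


class _BivariateWorkspace:
    """Fixed data-dependent structures for one bivariate REML problem."""

    def __init__(self, records: PhenotypeRecords, K: RelationshipKernel):
        years = records.years
        if len(years) != 2:
            raise ValueError(f"bivariate model needs exactly two years, got {years}")
        self.years = (years[0], years[1])
        self.K = K
        self.N = K.n_lines
        self.kmat = K.ridged()
        self.kinv = np.linalg.inv(self.kmat)

        frames = []
        for yr in years:
            df = records.frame[records.frame["year"] == yr]
            df = df.groupby("line_id", sort=True)["value"].mean()  # one record/line/year
            if len(df) < 10:
                raise ValueError(f"year {yr} has {len(df)} phenotyped lines; need >= 10")
            frames.append(df)
        self.obs = [K.index_of(f.index) for f in frames]
        self.y = [f.to_numpy(dtype=float) for f in frames]
        self.n1, self.n2 = len(self.y[0]), len(self.y[1])
        self.n_obs = self.n1 + self.n2
        self.yvec = np.concatenate(self.y)
        self.var_y = float(np.var(self.yvec))
        self.floor = 1e-10 * self.var_y
        self.common = np.intersect1d(self.obs[0], self.obs[1])
        # kernel blocks restricted to observed lines
        self.k11 = self.kmat[np.ix_(self.obs[0], self.obs[0])]
        self.k12 = self.kmat[np.ix_(self.obs[0], self.obs[1])]
        self.k22 = self.kmat[np.ix_(self.obs[1], self.obs[1])]
        x = np.zeros((self.n_obs, 2))
        x[: self.n1, 0] = 1.0
        x[self.n1 :, 1] = 1.0
        self.x = x

    # -- likelihood machinery ------------------------------------------------

    def build_v(self, th: np.ndarray) -> np.ndarray:
        g11, g12, g22, e1, e2 = th
        v = np.empty((self.n_obs, self.n_obs))
        v[: self.n1, : self.n1] = g11 * self.k11 + e1 * np.eye(self.n1)
        v[: self.n1, self.n1 :] = g12 * self.k12
        v[self.n1 :, : self.n1] = g12 * self.k12.T
        v[self.n1 :, self.n1 :] = g22 * self.k22 + e2 * np.eye(self.n2)
        return v

    def loglik(self, th: np.ndarray) -> float:
        """Restricted log-likelihood (constants dropped consistently)."""
        try:
            cf = cho_factor(self.build_v(th))
        except np.linalg.LinAlgError:
            return -np.inf
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        vinv_x = cho_solve(cf, self.x)
        xtvx = self.x.T @ vinv_x
        sign, logdet_xvx = np.linalg.slogdet(xtvx)
        if sign <= 0:
            return -np.inf
        vinv_y = cho_solve(cf, self.yvec)
        beta = np.linalg.solve(xtvx, self.x.T @ vinv_y)
        py = vinv_y - vinv_x @ beta
        quad = float(self.yvec @ py)
        return -0.5 * (logdet_v + logdet_xvx + quad + (self.n_obs - 2) * _LOG2PI)

    def _p_matrix(self, th: np.ndarray):
        cf = cho_factor(self.build_v(th))
        vinv = cho_solve(cf, np.eye(self.n_obs))
        vinv_x = vinv @ self.x
        xtvx_inv = np.linalg.inv(self.x.T @ vinv_x)
        p = vinv - vinv_x @ xtvx_inv @ vinv_x.T
        return p

    # -- EM step through the mixed-model equations ---------------------------

    def em_step(self, th: np.ndarray, g12_free: bool) -> np.ndarray:
        g11, g12, g22, e1, e2 = th
        g0 = np.array([[g11, g12], [g12, g22]])
        g0 = _project_psd(g0, strict=True)
        g0_inv = np.linalg.inv(g0)
        N, n1 = self.N, self.n1
        dim = 2 + 2 * N
        c = np.zeros((dim, dim))
        rhs = np.zeros(dim)
        rinv = np.concatenate([np.full(n1, 1.0 / e1), np.full(self.n2, 1.0 / e2)])
        # column index of the u entry for each record
        ucols = np.concatenate([2 + self.obs[0], 2 + N + self.obs[1]])
        xcols = np.concatenate([np.zeros(n1, int), np.ones(self.n2, int)])
        # X'R^-1X and X'R^-1Z
        for i in range(self.n_obs):
            a, b, w = xcols[i], ucols[i], rinv[i]
            c[a, a] += w
            c[a, b] += w
            c[b, a] += w
            c[b, b] += w
            rhs[a] += w * self.yvec[i]
            rhs[b] += w * self.yvec[i]
        # + G^-1 = G0^-1 kron K^-1
        for s in range(2):
            for t in range(2):
                c[2 + s * N : 2 + (s + 1) * N, 2 + t * N : 2 + (t + 1) * N] += (
                    g0_inv[s, t] * self.kinv
                )
        cinv = np.linalg.inv(c)
        sol = cinv @ rhs
        u1, u2 = sol[2 : 2 + N], sol[2 + N :]
        cuu = lambda s, t: cinv[2 + s * N : 2 + (s + 1) * N, 2 + t * N : 2 + (t + 1) * N]
        g0_new = np.empty((2, 2))
        us = [u1, u2]
        for s in range(2):
            for t in range(s, 2):
                g0_new[s, t] = (us[s] @ self.kinv @ us[t] + np.sum(self.kinv * cuu(t, s).T)) / N
                g0_new[t, s] = g0_new[s, t]
        # residual updates: E[e_t'e_t | y] / n_t
        fitted = sol[xcols] + sol[ucols]
        ehat = self.yvec - fitted
        wcw_diag = (
            cinv[xcols, xcols] + 2.0 * cinv[xcols, ucols] + cinv[ucols, ucols]
        )
        e1_new = (float(ehat[:n1] @ ehat[:n1]) + float(wcw_diag[:n1].sum())) / n1
        e2_new = (float(ehat[n1:] @ ehat[n1:]) + float(wcw_diag[n1:].sum())) / self.n2
        g12_new = g0_new[0, 1] if g12_free else 0.0
        th_new = np.array([g0_new[0, 0], g12_new, g0_new[1, 1], e1_new, e2_new])
        return self._apply_bounds(th_new)

    # -- average-information step --------------------------------------------

    def ai_step(self, th: np.ndarray, g12_free: bool) -> np.ndarray | None:
        n1 = self.n1
        try:
            p = self._p_matrix(th)
        except np.linalg.LinAlgError:
            return None
        py = p @ self.yvec
        p11, p12, p22 = p[:n1, :n1], p[:n1, n1:], p[n1:, n1:]
        py1, py2 = py[:n1], py[n1:]

        # dV * Py for each parameter (block structure)
        dvpy = {}
        dvpy["g11"] = np.concatenate([self.k11 @ py1, np.zeros(self.n2)])
        dvpy["g12"] = np.concatenate([self.k12 @ py2, self.k12.T @ py1])
        dvpy["g22"] = np.concatenate([np.zeros(n1), self.k22 @ py2])
        dvpy["e1"] = np.concatenate([py1, np.zeros(self.n2)])
        dvpy["e2"] = np.concatenate([np.zeros(n1), py2])
        tr_pdv = {
            "g11": float(np.sum(p11 * self.k11)),
            "g12": 2.0 * float(np.sum(p12 * self.k12)),
            "g22": float(np.sum(p22 * self.k22)),
            "e1": float(np.trace(p11)),
            "e2": float(np.trace(p22)),
        }
        names = ["g11", "g12", "g22", "e1", "e2"]
        free = names if g12_free else ["g11", "g22", "e1", "e2"]
        idx = {nm: i for i, nm in enumerate(names)}
        score = np.array([-0.5 * (tr_pdv[nm] - py @ dvpy[nm]) for nm in free])
        ai = np.empty((len(free), len(free)))
        pdv = {nm: p @ dvpy[nm] for nm in free}
        for a, na in enumerate(free):
            for b, nb in enumerate(free):
                ai[a, b] = 0.5 * float(dvpy[na] @ pdv[nb])
        try:
            delta = np.linalg.solve(ai + 1e-12 * np.eye(len(free)) * np.trace(ai), score)
        except np.linalg.LinAlgError:
            return None
        th_new = th.copy()
        for a, nm in enumerate(free):
            th_new[idx[nm]] += delta[a]
        return self._apply_bounds(th_new)

    def _apply_bounds(self, th: np.ndarray) -> np.ndarray:
        th = th.copy()
        th[[0, 2, 3, 4]] = np.maximum(th[[0, 2, 3, 4]], self.floor)
        g0 = _project_psd(np.array([[th[0], th[1]], [th[1], th[2]]]))
        th[0], th[1], th[2] = g0[0, 0], g0[0, 1], g0[1, 1]
        th[[0, 2]] = np.maximum(th[[0, 2]], self.floor)
        return th

    # -- BLUP at given components --------------------------------------------

    def solve_blups(self, th: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g11, g12, g22, e1, e2 = th
        g0 = np.array([[g11, g12], [g12, g22]])
        cf = cho_factor(self.build_v(th))
        vinv_x = cho_solve(cf, self.x)
        xtvx = self.x.T @ vinv_x
        beta = np.linalg.solve(xtvx, vinv_x.T @ self.yvec)
        r = cho_solve(cf, self.yvec - self.x @ beta)
        r1, r2 = r[: self.n1], r[self.n1 :]
        k_o1 = self.kmat[:, self.obs[0]]
        k_o2 = self.kmat[:, self.obs[1]]
        g_hat = np.empty((self.N, 2))
        for t in range(2):
            g_hat[:, t] = g0[t, 0] * (k_o1 @ r1) + g0[t, 1] * (k_o2 @ r2)
        return beta, g_hat


def _project_psd(g0: np.ndarray, strict: bool = False) -> np.ndarray:
    """Eigenvalue-clip a 2x2 symmetric matrix to the PSD cone."""
    w, v = np.linalg.eigh(g0)
    eps = 1e-10 * max(float(np.trace(g0)), 1e-300)
    lo = eps if strict else 0.0
    if w[0] >= lo:
        return g0
    w = np.maximum(w, max(lo, eps if strict else 0.0))
    return v @ np.diag(w) @ v.T


def _default_init(ws: _BivariateWorkspace) -> np.ndarray:
    v1, v2 = float(np.var(ws.y[0])), float(np.var(ws.y[1]))
    g11, g22 = 0.5 * v1, 0.5 * v2
    e1, e2 = 0.5 * v1, 0.5 * v2
    g12 = 0.0
    if ws.common.size >= 3:
        pos1 = {o: i for i, o in enumerate(ws.obs[0])}
        pos2 = {o: i for i, o in enumerate(ws.obs[1])}
        a = np.array([ws.y[0][pos1[o]] for o in ws.common])
        b = np.array([ws.y[1][pos2[o]] for o in ws.common])
        rp = float(np.corrcoef(a, b)[0, 1]) if a.std() > 0 and b.std() > 0 else 0.0
        g12 = np.clip(rp, -0.9, 0.9) * np.sqrt(g11 * g22)
    return np.array([g11, g12, g22, e1, e2])


def reml_bivariate(
    records: PhenotypeRecords,
    K: RelationshipKernel,
    init: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BivariateFit:
    """EM/AI REML for the two-year bivariate model.

    ``records`` must contain exactly two years (one value per line and
    year; one environment/trait, pre-subset by the caller).  ``init`` is a
    component vector (g11, g12, g22, e1, e2) or None for a data-driven
    start.  If the two years share no lines and no ``init`` is given, the
    genetic covariance is unidentifiable and is fixed at zero (flagged via
    a warning).
    """
    ws = _BivariateWorkspace(records, K)
    g12_free = True
    if ws.common.size == 0 and init is None:
        warnings.warn(
            "no lines phenotyped in both years and no init given; "
            "genetic covariance fixed at 0", stacklevel=2,
        )
        g12_free = False
    th = ws._apply_bounds(np.asarray(init, float).copy()) if init is not None else _default_init(ws)
    if not g12_free:
        th[1] = 0.0

    ll = ws.loglik(th)
    path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        th_new = None
        prop = ws.ai_step(th, g12_free)
        if prop is not None:
            ll_prop = ws.loglik(prop)
            if np.isfinite(ll_prop) and ll_prop >= ll - 1e-12:
                th_new, ll_new = prop, ll_prop
        if th_new is None:
            th_new = ws.em_step(th, g12_free)
            ll_new = ws.loglik(th_new)
            if not np.isfinite(ll_new) or ll_new < ll - 1e-8:
                # EM blocked by bounds/projection; stop at current point
                th_new, ll_new = th, ll
        rel = np.max(np.abs(th_new - th) / np.maximum(np.abs(th), ws.floor + 1e-300))
        dll = abs(ll_new - ll)
        th, ll = th_new, ll_new
        path.append(ll)
        if rel < tol and dll < 1e-6:
            converged = True
            break

    beta, g_hat = ws.solve_blups(th)
    return BivariateFit(
        years=ws.years, beta_hat=beta,
        G0=np.array([[th[0], th[1]], [th[1], th[2]]]),
        sigma2_e1=th[3], sigma2_e2=th[4], logL_reml=ll,
        g_hat=pd.DataFrame(g_hat, index=list(K.line_ids), columns=list(ws.years)),
        converged=converged, n_iter=it,
        init_values=np.asarray(init, float) if init is not None else _default_init(ws),
        logL_path=np.array(path),
    )


def fit_with_protocol(
    records: PhenotypeRecords,
    K: RelationshipKernel,
    stage: str,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int | None = None,
) -> BivariateFit:
    """Two-stage variance-component protocol for cross-validation.

    ``stage="prefit"``: fit on the full dataset with at most 100
    iterations; non-converged components at iteration 100 are returned
    (converged=False) and serve as starting values downstream.

    ``stage="cv_fold"``: requires ``init`` (normally the pre-fit
    components); runs at most 50 iterations.  If the fold fit does not
    converge, BLUPs are recomputed with the components *fixed at the
    starting values* and ``fixed_fallback`` is set.
    """
    if stage == "prefit":
        return reml_bivariate(records, K, init=None, max_iter=max_iter or 100, tol=tol)
    if stage != "cv_fold":
        raise ValueError(f"unknown stage {stage!r}")
    if init is None:
        raise ValueError("cv_fold stage requires init components")
    fit = reml_bivariate(records, K, init=init, max_iter=max_iter or 50, tol=tol)
    if fit.converged:
        return fit
    ws = _BivariateWorkspace(records, K)
    th = ws._apply_bounds(np.asarray(init, float).copy())
    beta, g_hat = ws.solve_blups(th)
    return BivariateFit(
        years=ws.years, beta_hat=beta,
        G0=np.array([[th[0], th[1]], [th[1], th[2]]]),
        sigma2_e1=th[3], sigma2_e2=th[4], logL_reml=ws.loglik(th),
        g_hat=pd.DataFrame(g_hat, index=list(K.line_ids), columns=list(ws.years)),
        converged=False, n_iter=fit.n_iter,
        init_values=np.asarray(init, float), fixed_fallback=True,
    )


def genomic_heritability(sigma2_g: float, sigma2_e: float, K: RelationshipKernel) -> float:
    """Heritability on the phenotypic-variance scale implied by the kernel.

    The across-line variance of g ~ N(0, sg2*K) is sg2 * (mean diag(K) -
    mean(K)); for a DH panel with VanRaden scaling the kernel diagonal
    averages about 2 (full inbreeding), so the raw ratio sg2/(sg2+se2)
    would understate heritability by that factor.
    """
    d = float(np.mean(np.diag(K.matrix)) - np.mean(K.matrix))
    return d * sigma2_g / (d * sigma2_g + sigma2_e)


def genomic_correlation(fit: BivariateFit) -> float:
    """r_g = sigma_g12 / sqrt(sigma2_g1 * sigma2_g2), clipped to [-1, 1]."""
    g11, g22 = fit.G0[0, 0], fit.G0[1, 1]
    if g11 <= 0 or g22 <= 0:
        raise ValueError("zero genetic variance in one year; genomic correlation undefined")
    r = float(fit.G0[0, 1] / np.sqrt(g11 * g22))
    if abs(r) > 1.0:
        logger.info("genomic correlation %.4f clipped to [-1, 1]", r)
        r = float(np.clip(r, -1.0, 1.0))
    return r


def predict_blup(
    fit: BivariateFit,
    K: RelationshipKernel,
    target_year: int,
    target_lines,
) -> pd.Series:
    """Predicted genetic values of target lines in the target year."""
    if target_year not in fit.years:
        raise ValueError(f"year {target_year} not in fit years {fit.years}")
    K.index_of(target_lines)  # raises if a line is absent from the kernel
    return fit.g_hat.loc[list(target_lines), target_year]
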