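"""Binomial logit mixed models with RIL and vial random intercepts.

The genome scan compares, at every position, a base model

    y_v ~ Binomial(n_v, p_v),   logit(p_v) = x_v'beta0 + u_{ril(v)} + w_v

against an alternative adding founder-probability covariates to the fixed
part.  ``u`` are per-RIL intercepts (iid N(0, sd_ril^2)) and ``w`` per-vial
intercepts nested within RIL (iid N(0, sd_rep^2)).  Both models are fit by
Laplace-approximate maximum likelihood: for candidate (beta, sds) the joint
posterior mode of the random effects is found by damped Newton (the
per-RIL blocks are independent and their Hessians are arrow matrices —
diagonal in the vial effects plus one coupled RIL effect — so the mode and
log-determinant cost O(#vials) per block), and the marginal log-likelihood
is the Laplace approximation at that mode.  The outer optimisation over
(beta, log sd_ril, log sd_rep) uses L-BFGS-B.

Fixed covariates must be constant within a vial (they are RIL-level founder
probabilities in the scan); observations are therefore aggregated per vial
first, which leaves every likelihood *difference* identical between per-fly
Bernoulli and vial-aggregated binomial representations (the two differ only
by a fixed binomial-coefficient constant, which is reported in the loglik
so values are directly comparable with other mixed-model software).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

_LOG_SD_BOUNDS = (-8.0, 4.0)
_INNER_TOL = 1e-10
_MAX_INNER = 100


@dataclass
class GLMMFit:
    """One fitted binomial mixed model."""

    loglik: float
    fixed_coefficients: np.ndarray
    sd_ril: float
    sd_replicate: float
    converged: bool
    n_obs: int
    n_params: int

    @property
    def variance_components(self) -> tuple[float, float]:
        return (self.sd_ril, self.sd_replicate)


class _VialData:
    """Per-vial aggregated data padded into (n_ril, max_vials) arrays."""

    def __init__(self, y, n, X, ril_idx, vial_idx):
        y = np.asarray(y, float)
        n = np.asarray(n, float)
        X = np.atleast_2d(np.asarray(X, float))
        ril_idx = np.asarray(ril_idx)
        vial_idx = np.asarray(vial_idx)
        if not (len(y) == len(n) == X.shape[0] == len(ril_idx) == len(vial_idx)):
            raise ValueError("inconsistent input lengths")
        if (y < 0).any() or (y > n).any():
            raise ValueError("need 0 <= successes <= trials")

        # aggregate rows sharing a vial (covariates constant within vial)
        keys = {}
        order = []
        for i, (r, v) in enumerate(zip(ril_idx, vial_idx)):
            k = (r, v)
            if k not in keys:
                keys[k] = len(order)
                order.append(i)
        m = len(order)
        self.yv = np.zeros(m)
        self.nv = np.zeros(m)
        for i, (r, v) in enumerate(zip(ril_idx, vial_idx)):
            j = keys[(r, v)]
            self.yv[j] += y[i]
            self.nv[j] += n[i]
        self.Xv = X[order]
        rils = []
        seen = {}
        self.vril = np.empty(m, dtype=np.int64)
        for j, (r, v) in enumerate(keys):
            if r not in seen:
                seen[r] = len(rils)
                rils.append(r)
            self.vril[j] = seen[r]
        self.n_ril = len(rils)
        self.n_vial = m
        self.p = X.shape[1]

        counts = np.bincount(self.vril, minlength=self.n_ril)
        self.max_m = int(counts.max())
        self.slot = np.zeros(m, dtype=np.int64)
        fill = np.zeros(self.n_ril, dtype=np.int64)
        for j in range(m):
            r = self.vril[j]
            self.slot[j] = fill[r]
            fill[r] += 1
        self.mask = np.zeros((self.n_ril, self.max_m), dtype=bool)
        self.mask[self.vril, self.slot] = True
        self.Y = np.zeros((self.n_ril, self.max_m))
        self.N = np.zeros((self.n_ril, self.max_m))
        self.Y[self.vril, self.slot] = self.yv
        self.N[self.vril, self.slot] = self.nv
        # dropping the binomial coefficient changes loglik by a constant only
        self.log_binom = float(np.sum(
            special.gammaln(self.nv + 1) - special.gammaln(self.yv + 1)
            - special.gammaln(self.nv - self.yv + 1)))


def _laplace_loglik(theta, data: _VialData, include_const=True):
    """Marginal Laplace log-likelihood at theta = (beta, log sd_ril, log sd_rep)."""
    p = data.p
    beta = theta[:p]
    s1 = np.exp(theta[p])
    s2 = np.exp(theta[p + 1])
    inv_v1 = 1.0 / (s1 * s1)
    inv_v2 = 1.0 / (s2 * s2)

    off = np.zeros((data.n_ril, data.max_m))
    off[data.vril, data.slot] = data.Xv @ beta
    Y, N, mask = data.Y, data.N, data.mask

    u = np.zeros(data.n_ril)
    v = np.zeros((data.n_ril, data.max_m))

    def objective(u, v):
        eta = off + u[:, None] + v
        ll = np.where(mask, Y * eta - N * np.logaddexp(0.0, eta), 0.0).sum(axis=1)
        return ll - 0.5 * inv_v1 * u * u - 0.5 * inv_v2 * (v * v * mask).sum(axis=1)

    obj = objective(u, v)
    for _ in range(_MAX_INNER):
        eta = off + u[:, None] + v
        mu = special.expit(eta)
        W = np.where(mask, N * mu * (1.0 - mu), 0.0)
        resid = np.where(mask, Y - N * mu, 0.0)
        grad_v = resid - inv_v2 * v * mask
        grad_u = resid.sum(axis=1) - inv_v1 * u
        gmax = max(np.abs(grad_u).max(initial=0.0), np.abs(grad_v).max(initial=0.0))
        if gmax < _INNER_TOL:
            break
        d = np.where(mask, W + inv_v2, 1.0)  # padded slots: benign dummy
        a = W.sum(axis=1) + inv_v1
        w_over_d = np.where(mask, W / d, 0.0)
        schur = a - (W * w_over_d).sum(axis=1)
        du = (grad_u - (w_over_d * grad_v).sum(axis=1)) / schur
        dv = (grad_v - W * du[:, None]) / d * mask
        # damped step: halve on blocks whose objective worsened
        step = np.ones(data.n_ril)
        for _ in range(30):
            u_new = u + step * du
            v_new = v + step[:, None] * dv
            obj_new = objective(u_new, v_new)
            bad = obj_new < obj - 1e-12
            if not bad.any():
                break
            step[bad] *= 0.5
        u, v, obj = u_new, v_new, obj_new

    eta = off + u[:, None] + v
    mu = special.expit(eta)
    W = np.where(mask, N * mu * (1.0 - mu), 0.0)
    d = np.where(mask, W + inv_v2, 1.0)
    a = W.sum(axis=1) + inv_v1
    schur = a - np.where(mask, W * W / d, 0.0).sum(axis=1)
    logdet = np.where(mask, np.log(d), 0.0).sum(axis=1) + np.log(schur)

    ll = obj.sum()
    ll -= data.n_ril * np.log(s1) + data.n_vial * np.log(s2)
    ll -= 0.5 * logdet.sum()
    if include_const:
        ll += data.log_binom
    return ll


def fit_binomial_glmm(y, n, X, ril_idx, vial_idx,
                      start: GLMMFit | None = None) -> GLMMFit:
    """Fit a binomial logit mixed model with RIL and vial random intercepts.

    Parameters are per-observation arrays: successes ``y``, trials ``n``,
    fixed design ``X`` (constant within vial), and RIL / vial grouping
    labels.  ``start`` warm-starts the variance components (and the leading
    fixed coefficients) from a previous fit, which both speeds up the scan
    and guarantees the alternative model never starts below its nested base.
    """
    data = _VialData(y, n, X, ril_idx, vial_idx)
    p = data.p

    theta0 = np.zeros(p + 2)
    theta0[p:] = np.log(0.3)
    if start is not None:
        k = min(p, len(start.fixed_coefficients))
        theta0[:k] = start.fixed_coefficients[:k]
        theta0[p] = np.log(max(start.sd_ril, 1e-4))
        theta0[p + 1] = np.log(max(start.sd_replicate, 1e-4))
    theta0[p:] = np.clip(theta0[p:], *_LOG_SD_BOUNDS)

    def nll(theta):
        return -_laplace_loglik(theta, data, include_const=False)

    bounds = [(None, None)] * p + [_LOG_SD_BOUNDS] * 2
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-7})
    # polish: restart once from the optimum (finite-difference L-BFGS can
    # stall early on flat variance directions)
    res2 = optimize.minimize(
        nll, res.x, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-8})
    if res2.fun <= res.fun:
        res = res2
    if not res.success:
        # rare line-search stalls: fall back to a derivative-free polish
        res3 = optimize.minimize(
            nll, res.x, method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8})
        if res3.fun <= res.fun + 1e-9:
            res3.x[p:] = np.clip(res3.x[p:], *_LOG_SD_BOUNDS)
            res = res3

    theta = res.x
    return GLMMFit(
        loglik=float(-res.fun + data.log_binom),
        fixed_coefficients=theta[:p].copy(),
        sd_ril=float(np.exp(theta[p])),
        sd_replicate=float(np.exp(theta[p + 1])),
        converged=bool(res.success),
        n_obs=data.n_vial,
        n_params=p + 2,
    )
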