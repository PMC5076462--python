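"""Linear mixed-effects models with crossed random effects, fitted by ML.

Implements the profiled maximum-likelihood formulation of the linear
mixed model

    y = X b + Z u + e,   u ~ N(0, s2 * L L'),   e ~ N(0, s2 * I)

where ``L`` (the relative covariance factor) is block diagonal over
grouping factors — e.g. a full lower-triangular 4x4 block repeated over
subjects, crossed with a scalar block repeated over items.  For a given
relative factor the fixed effects, the random-effect modes and the
residual variance all have closed forms via one Cholesky factorization
of ``L'Z'ZL + I``, so optimization runs over the covariance parameters
only (penalized-least-squares profiling, as in lme4).  ML rather than
REML is used throughout so that likelihood-ratio tests between models
differing in fixed effects are valid.

The deviance for covariance parameters ``theta`` is

    -2 l(theta) = 2 log|L_chol| + n (1 + log(2 pi r2 / n))

with ``r2`` the minimized penalized residual sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import optimize

__all__ = ["RandomTerm", "MixedLMSpec", "MixedLMFit", "fit_mixedlm"]


@dataclass(frozen=True)
class RandomTerm:
    """One grouping factor: random intercept plus optional random slopes.

    ``structure`` is ``"full"`` (unstructured covariance over intercept
    and slopes) or ``"diag"`` (independent effects).
    """

    group: str
    slopes: tuple = ()
    structure: str = "full"

    @property
    def dim(self) -> int:
        return 1 + len(self.slopes)

    @property
    def n_params(self) -> int:
        if self.structure == "full":
            return self.dim * (self.dim + 1) // 2
        return self.dim


@dataclass(frozen=True)
class MixedLMSpec:
    """Model specification: response, fixed covariates, random structure.

    An intercept is always included in the fixed part and in every
    random term.
    """

    response: str
    fixed: tuple
    random: tuple

    @property
    def n_theta(self) -> int:
        return sum(t.n_params for t in self.random)

    def drop_fixed(self, term: str) -> "MixedLMSpec":
        """The same model without one fixed covariate (for nested LRTs)."""
        if term not in self.fixed:
            raise ValueError(f"{term!r} is not a fixed term")
        return MixedLMSpec(
            response=self.response,
            fixed=tuple(f for f in self.fixed if f != term),
            random=self.random,
        )


@dataclass
class MixedLMFit:
    """Fitted model: estimates, variance components, likelihood, AIC."""

    spec: MixedLMSpec
    params: pd.Series          # fixed-effect estimates (incl. intercept)
    bse: pd.Series             # standard errors (observed information)
    tvalues: pd.Series         # params / bse
    loglik: float
    n_params: int              # fixed + covariance parameters + residual
    sigma2: float              # residual variance
    cov_re: dict               # group -> random-effect covariance matrix
    theta: np.ndarray
    converged: bool
    singular: bool
    n_obs: int
    fallback: str | None = None
    vcov_fixed: np.ndarray = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2 * self.n_params - 2 * self.loglik

    def predict_fixed(self, df: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects-only) prediction."""
        X = _design(df, self.spec.fixed)
        return X @ self.params.to_numpy()


def _design(df: pd.DataFrame, fixed: tuple) -> np.ndarray:
    cols = [np.ones(len(df))]
    for c in fixed:
        cols.append(df[c].to_numpy(dtype=float))
    return np.column_stack(cols)


class _Problem:
    """Precomputed cross-products for one (data, spec) pair."""

    def __init__(self, df: pd.DataFrame, spec: MixedLMSpec):
        y = df[spec.response].to_numpy(dtype=float)
        X = _design(df, spec.fixed)
        if np.any(~np.isfinite(y)) or np.any(~np.isfinite(X)):
            raise ValueError("non-finite values in response or covariates")
        n = len(y)
        self.n, self.p = n, X.shape[1]
        self.terms = spec.random
        self.level_counts = []
        all_rows, all_cols, all_vals = [], [], []
        col0 = 0
        self.block_slices = []
        for term in spec.random:
            codes, levels = pd.factorize(df[term.group], sort=True)
            if len(levels) < 2:
                raise ValueError(f"grouping factor {term.group!r} needs >= 2 levels")
            m = term.dim
            L = len(levels)
            data_cols = [np.ones(n)] + [
                df[s].to_numpy(dtype=float) for s in term.slopes
            ]
            all_rows.append(np.repeat(np.arange(n), m))
            all_cols.append(
                ((codes[:, None] * m + np.arange(m)[None, :]) + col0).ravel()
            )
            all_vals.append(np.column_stack(data_cols).ravel())
            self.level_counts.append(L)
            self.block_slices.append((col0, col0 + L * m, L, m))
            col0 += L * m
        self.q = col0
        Z = sp.coo_matrix(
            (np.concatenate(all_vals),
             (np.concatenate(all_rows), np.concatenate(all_cols))),
            shape=(n, self.q),
        ).tocsr()
        self.A = np.asarray((Z.T @ Z).todense())
        self.ZtX = np.asarray((Z.T @ sp.csr_matrix(X)).todense())
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.X = X

    def lambdas(self, theta: np.ndarray) -> list:
        """Per-term relative covariance factors (lower triangular)."""
        out, pos = [], 0
        for term in self.terms:
            m = term.dim
            lam = np.zeros((m, m))
            if term.structure == "full":
                k = term.n_params
                lam[np.tril_indices(m)] = theta[pos : pos + k]
                pos += k
            else:
                np.fill_diagonal(lam, theta[pos : pos + m])
                pos += m
            out.append(lam)
        return out

    def _transform(self, mat: np.ndarray, lams: list, side: str) -> np.ndarray:
        """Apply the block-diagonal Lambda' (left) or Lambda (right)."""
        out = mat.copy()
        for (c0, c1, L, m), lam in zip(self.block_slices, lams):
            if side == "left":
                blk = out[c0:c1].reshape(L, m, -1)
                out[c0:c1] = np.einsum("ba,lbq->laq", lam, blk).reshape(c1 - c0, -1)
            else:
                blk = out[:, c0:c1].reshape(out.shape[0], L, m)
                out[:, c0:c1] = np.einsum("qlb,ba->qla", blk, lam).reshape(
                    out.shape[0], -1
                )
        return out

    def profiled(self, theta: np.ndarray):
        """Profiled deviance and the profiled-out quantities at ``theta``.

        Returns (deviance, beta, r2, chol, RZX, XtVinvX) or (inf, ...)
        when the penalized system is numerically singular.
        """
        lams = self.lambdas(theta)
        M = self._transform(self._transform(self.A, lams, "left"), lams, "right")
        M[np.diag_indices_from(M)] += 1.0
        try:
            chol = sla.cho_factor(M, lower=True, check_finite=False)
        except sla.LinAlgError:
            return np.inf, None, None, None, None, None
        LtZty = self._transform(self.Zty[:, None], lams, "left").ravel()
        LtZtX = self._transform(self.ZtX, lams, "left")
        cu = sla.cho_solve(chol, LtZty, check_finite=False)
        CX = sla.cho_solve(chol, LtZtX, check_finite=False)
        XtVinvX = self.XtX - LtZtX.T @ CX
        XtVinvy = self.Xty - LtZtX.T @ cu
        try:
            beta = sla.solve(XtVinvX, XtVinvy, assume_a="pos")
        except (sla.LinAlgError, ValueError):
            return np.inf, None, None, None, None, None
        # pwrss = y'V^-1 y - beta' X'V^-1 y  (profiled GLS residual)
        r2 = self.yty - LtZty @ cu - beta @ XtVinvy
        if r2 <= 0:
            return np.inf, None, None, None, None, None
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        n = self.n
        dev = logdet + n * (1.0 + np.log(2.0 * np.pi * r2 / n))
        return dev, beta, r2, chol, LtZtX, XtVinvX

    def deviance(self, theta: np.ndarray) -> float:
        return self.profiled(theta)[0]

    def deviance_and_grad(self, theta: np.ndarray):
        """Profiled deviance and its analytic gradient.

        d(logdet)/dθ_j uses tr(M^-1 dM_j) = 2 <Λ_j, A Λ M^-1>;
        d(pwrss)/dθ_j uses the envelope theorem at the optimal (β, u):
        -2 (Z'e)' Λ_j u with e the full residual.
        """
        lams = self.lambdas(theta)
        LtA = self._transform(self.A, lams, "left")  # Λ' A
        M = self._transform(LtA, lams, "right")
        M[np.diag_indices_from(M)] += 1.0
        try:
            chol = sla.cho_factor(M, lower=True, check_finite=False)
        except sla.LinAlgError:
            return np.inf, np.zeros_like(theta)
        LtZty = self._transform(self.Zty[:, None], lams, "left").ravel()
        LtZtX = self._transform(self.ZtX, lams, "left")
        cu = sla.cho_solve(chol, LtZty, check_finite=False)
        CX = sla.cho_solve(chol, LtZtX, check_finite=False)
        XtVinvX = self.XtX - LtZtX.T @ CX
        XtVinvy = self.Xty - LtZtX.T @ cu
        try:
            beta = sla.solve(XtVinvX, XtVinvy, assume_a="pos")
        except (sla.LinAlgError, ValueError):
            return np.inf, np.zeros_like(theta)
        r2 = self.yty - LtZty @ cu - beta @ XtVinvy
        if r2 <= 0:
            return np.inf, np.zeros_like(theta)
        n = self.n
        dev = 2.0 * np.sum(np.log(np.diag(chol[0]))) \
            + n * (1.0 + np.log(2.0 * np.pi * r2 / n))
        # gradient pieces
        Gt = sla.cho_solve(chol, LtA, check_finite=False)   # M^-1 Λ' A = G'
        u = sla.cho_solve(
            chol,
            self._transform((self.Zty - self.ZtX @ beta)[:, None], lams,
                            "left").ravel(),
            check_finite=False,
        )
        lam_u = self._lambda_dot(u, lams)                    # Λ u
        Zte = self.Zty - self.ZtX @ beta - self.A @ lam_u    # Z' e
        grad = np.empty_like(theta)
        pos = 0
        for (c0, c1, L, m), term in zip(self.block_slices, self.terms):
            # level-diagonal blocks of G' restricted to this term
            idx = np.arange(L)
            Gd = Gt[c0:c1, c0:c1].reshape(L, m, L, m)[idx, :, idx, :]  # (L,m,m) of G'
            u_t = u[c0:c1].reshape(L, m)
            Zte_t = Zte[c0:c1].reshape(L, m)
            if term.structure == "full":
                pairs = [(a, b) for a, b in zip(*np.tril_indices(m))]
            else:
                pairs = [(a, a) for a in range(m)]
            for a, b in pairs:
                # dM term: 2 * sum_l G[(l,a),(l,b)] = 2 * sum_l G'[(l,b),(l,a)]
                g_logdet = 2.0 * float(np.sum(Gd[:, b, a]))
                # pwrss term: -2 sum_l Z'e[(l,a)] * u[(l,b)]
                g_r2 = -2.0 * float(np.sum(Zte_t[:, a] * u_t[:, b]))
                grad[pos] = g_logdet + (n / r2) * g_r2
                pos += 1
        return dev, grad

    def _lambda_dot(self, vec: np.ndarray, lams: list) -> np.ndarray:
        """Λ @ vec for a q-vector."""
        out = np.empty_like(vec)
        for (c0, c1, L, m), lam in zip(self.block_slices, lams):
            out[c0:c1] = (vec[c0:c1].reshape(L, m) @ lam.T).ravel()
        return out

    def start(self) -> np.ndarray:
        theta = []
        for term in self.terms:
            m = term.dim
            if term.structure == "full":
                lam = np.eye(m)[np.tril_indices(m)]
            else:
                lam = np.ones(m)
            theta.extend(lam)
        return np.array(theta)


def _term_names(spec: MixedLMSpec) -> list:
    return ["Intercept"] + list(spec.fixed)


def _optimize(fun_grad, fun, x0, maxfev: int, polish: bool = True):
    """Quasi-Newton search on the analytic gradient, with simplex polish.

    L-BFGS-B with the exact profiled-deviance gradient converges in a
    few dozen iterations; an optional short Nelder-Mead polish from a
    tiny simplex guards against line-search stalls.  Convergence is
    declared when the final stage cannot improve the deviance by more
    than 1e-3.
    """
    opts = {"maxfun": maxfev, "ftol": 1e-13, "gtol": 1e-7}
    res = optimize.minimize(fun_grad, x0, jac=True, method="L-BFGS-B",
                            options=opts)
    x, best = (res.x, res.fun) if np.isfinite(res.fun) else (x0, fun(x0))
    if not polish:
        return x, best, True

    def _polish(x, best):
        simplex = np.vstack([x, x + np.diag(np.maximum(1e-3, 1e-3 * np.abs(x)))])
        pol = optimize.minimize(
            fun, x, method="Nelder-Mead",
            options={"maxfev": 400, "fatol": 1e-8, "xatol": 1e-6,
                     "initial_simplex": simplex},
        )
        if pol.fun <= best:
            return pol.x, pol.fun, best - pol.fun
        return x, best, 0.0

    x, best, improvement = _polish(x, best)
    if improvement > 1e-3:  # quasi-Newton had stalled; take another pass
        res2 = optimize.minimize(fun_grad, x, jac=True, method="L-BFGS-B",
                                 options=opts)
        if res2.fun <= best:
            x, best = res2.x, res2.fun
        x, best, improvement = _polish(x, best)
    return x, best, bool(improvement <= 1e-3)


def fit_mixedlm(
    df: pd.DataFrame,
    spec: MixedLMSpec,
    start: np.ndarray | None = None,
    maxfev: int = 4000,
    singular_tol: float = 1e-4,
    polish: bool = True,
) -> MixedLMFit:
    """Fit a crossed random-effects linear mixed model by ML.

    ``start`` warm-starts the covariance-parameter search (useful when
    fitting a nested pair of models on the same data).  If the
    unstructured-covariance optimization fails to converge, the model is
    refitted with diagonal covariance blocks and the result is flagged
    (``fallback="diagonal"``), mirroring common practice for singular
    fits.
    """
    prob = _Problem(df, spec)
    x0 = prob.start() if start is None else np.asarray(start, dtype=float)
    theta, best, converged = _optimize(prob.deviance_and_grad, prob.deviance,
                                       x0, maxfev, polish)
    fallback = None
    if not converged and any(t.structure == "full" for t in spec.random):
        diag_spec = MixedLMSpec(
            response=spec.response,
            fixed=spec.fixed,
            random=tuple(
                RandomTerm(t.group, t.slopes, "diag") for t in spec.random
            ),
        )
        diag_prob = _Problem(df, diag_spec)
        theta2, best2, conv2 = _optimize(diag_prob.deviance_and_grad,
                                         diag_prob.deviance,
                                         diag_prob.start(), maxfev, polish)
        if conv2:
            prob, spec = diag_prob, diag_spec
            theta, best, converged = theta2, best2, conv2
            fallback = "diagonal"
    dev, beta, r2, chol, LtZtX, XtVinvX = prob.profiled(theta)
    if not np.isfinite(dev):
        raise RuntimeError("mixed-model fit failed: non-finite deviance")
    n = prob.n
    sigma2 = r2 / n
    vcov = sigma2 * np.linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(vcov))
    names = _term_names(spec)
    lams = prob.lambdas(theta)
    cov_re = {
        t.group: sigma2 * (lam @ lam.T) for t, lam in zip(spec.random, lams)
    }
    singular = any(
        np.min(np.abs(np.diag(lam))) < singular_tol for lam in lams
    )
    k = prob.p + spec.n_theta + 1
    params = pd.Series(beta, index=names)
    bse = pd.Series(se, index=names)
    return MixedLMFit(
        spec=spec,
        params=params,
        bse=bse,
        tvalues=params / bse,
        loglik=-dev / 2.0,
        n_params=k,
        sigma2=sigma2,
        cov_re=cov_re,
        theta=theta,
        converged=converged,
        singular=singular,
        n_obs=n,
        fallback=fallback,
        vcov_fixed=vcov,
    )
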