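"""Confirmatory factor analysis by full-information maximum likelihood.

The measurement model is ``x = mu + Lambda eta + eps`` with each indicator
loading on exactly one latent construct.  Identification fixes every latent
variance to 1 so loadings are directly interpretable on the standardized
metric; construct correlations are free (first-order model) or induced by a
single second-order severity factor with unit variance, ``Phi = gamma gamma'
+ diag(1 - gamma^2)`` (second-order model — with three first-order
constructs the two structures are exactly equivalent and share fit
statistics).

Missing cells are handled without imputation: rows are grouped by
missingness pattern and the casewise observed-data log-likelihood

    l(theta) = sum_i log N(x_i,obs ; mu_obs, Sigma_obs,obs(theta))

is maximized with analytic gradients.  The chi-square statistic compares the
model against the unstructured (saturated) multivariate-normal likelihood,
obtained by an EM algorithm over the same missingness patterns; the baseline
for CFI/TLI is the independence model (free means and variances, zero
covariances), whose FIML solution factorizes per indicator.

Residual-driven modification mirrors common SEM practice: indicators with a
residual correlation above 0.10 against another construct are removed
(largest first), then residual covariances are added between same-construct
pairs exceeding 0.10, one change per refit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .table import PreparedMatrix

__all__ = [
    "CfaModelSpec",
    "CfaFit",
    "ResidualReport",
    "SeverityScores",
    "fit_cfa",
    "saturated_loglik",
    "baseline_loglik",
    "chi_square",
    "count_df",
    "fit_indices",
    "fit_summary",
    "residual_correlations",
    "modify_model",
    "add_second_order",
    "severity_factor_scores",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class CfaModelSpec:
    """Construct -> indicator map, residual covariances, optional second order.

    ``constructs`` maps each latent construct name to the ordered tuple of
    indicator ids that load on it (every indicator on exactly one
    construct).  ``second_order``, when set, names a severity factor loading
    on all first-order constructs.
    """

    constructs: Mapping[str, tuple[str, ...]]
    residual_covariances: tuple[tuple[str, str], ...] = ()
    second_order: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "constructs", {k: tuple(v) for k, v in self.constructs.items()})
        seen: dict[str, str] = {}
        for c, inds in self.constructs.items():
            if not inds:
                raise ValueError(f"construct {c!r} has no indicators")
            for i in inds:
                if i in seen:
                    raise ValueError(f"indicator {i!r} appears in {seen[i]!r} and {c!r}")
                seen[i] = c
        for a, b in self.residual_covariances:
            if a == b:
                raise ValueError("residual covariance must join two distinct indicators")
            if a not in seen or b not in seen:
                raise ValueError(f"residual covariance pair ({a!r}, {b!r}) not in model")
            if seen[a] != seen[b]:
                raise ValueError(
                    f"residual covariance ({a!r}, {b!r}) spans constructs; only "
                    "within-construct pairs are allowed"
                )
        if self.second_order is not None and len(self.constructs) < 3:
            raise ValueError("a second-order factor needs >= 3 first-order constructs")

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(i for inds in self.constructs.values() for i in inds)

    @property
    def construct_names(self) -> tuple[str, ...]:
        return tuple(self.constructs)

    @property
    def construct_of(self) -> dict[str, str]:
        return {i: c for c, inds in self.constructs.items() for i in inds}

    def n_free_parameters(self) -> int:
        p = len(self.indicator_ids)
        k = len(self.constructs)
        r = len(self.residual_covariances)
        structural = k if self.second_order is not None else k * (k - 1) // 2
        return 2 * p + r + structural + p  # loadings + residual vars + covs + structure + means

    def drop_indicator(self, indicator: str) -> "CfaModelSpec":
        constructs = {
            c: tuple(i for i in inds if i != indicator)
            for c, inds in self.constructs.items()
        }
        constructs = {c: inds for c, inds in constructs.items() if inds}
        rc = tuple(p for p in self.residual_covariances if indicator not in p)
        return CfaModelSpec(constructs, rc, self.second_order)

    def add_residual_covariance(self, a: str, b: str) -> "CfaModelSpec":
        return CfaModelSpec(
            self.constructs, self.residual_covariances + ((a, b),), self.second_order
        )


def add_second_order(spec: CfaModelSpec, name: str = "crisis_severity") -> CfaModelSpec:
    """Place a second-order factor over all first-order constructs.

    The first-order construct correlations are replaced by the rank-one
    structure induced by the severity factor.  With exactly three
    first-order constructs the second-order structure is just-identified and
    the fit statistics coincide with the correlated-first-order model.
    """
    if len(spec.constructs) < 3:
        raise ValueError("a second-order factor needs >= 3 first-order constructs")
    return CfaModelSpec(spec.constructs, spec.residual_covariances, name)


# ---------------------------------------------------------------------------
# data: missingness-pattern sufficient statistics


class _PatternData:
    """Rows grouped by missingness pattern with per-pattern moments."""

    def __init__(self, X: np.ndarray):
        X = np.asarray(X, dtype=float)
        self.p = X.shape[1]
        obs_mask = ~np.isnan(X)
        usable = obs_mask.any(axis=1)
        self.n_dropped = int((~usable).sum())
        X = X[usable]
        self.n = X.shape[0]
        if self.n == 0:
            raise ValueError("no rows with at least one observed indicator")
        self.patterns: list[dict] = []
        keys = np.packbits(obs_mask[usable], axis=1)
        _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
        for g in range(len(first)):
            rows = X[inverse == g]
            o = np.flatnonzero(~np.isnan(rows[0]))
            sub = rows[:, o]
            ng = sub.shape[0]
            mean = sub.mean(axis=0)
            centered = sub - mean
            scatter = centered.T @ centered / ng
            self.patterns.append(
                {"o": o, "n": ng, "mean": mean, "scatter": scatter, "rows": sub}
            )

    def loglik(self, mu: np.ndarray, sigma: np.ndarray) -> float:
        ll = 0.0
        for pat in self.patterns:
            o, ng = pat["o"], pat["n"]
            S, xbar = pat["scatter"], pat["mean"]
            sub = sigma[np.ix_(o, o)]
            try:
                c = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return -np.inf
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            V = np.linalg.inv(sub)
            d = xbar - mu[o]
            ll -= 0.5 * ng * (
                len(o) * _LOG2PI + logdet + np.trace(S @ V) + d @ V @ d
            )
        return float(ll)

    def loglik_and_moment_grads(self, mu: np.ndarray, sigma: np.ndarray):
        """Log-likelihood plus gradients w.r.t. the full mu and Sigma.

        Returns ``(ll, dmu, dSigma)`` with ``dSigma`` the matrix such that
        ``dll = <dSigma, dSigma_matrix> + dmu . dmu_vec`` for symmetric
        perturbations of Sigma.
        """
        p = self.p
        ll = 0.0
        dmu = np.zeros(p)
        dSig = np.zeros((p, p))
        for pat in self.patterns:
            o, ng = pat["o"], pat["n"]
            S, xbar = pat["scatter"], pat["mean"]
            sub = sigma[np.ix_(o, o)]
            try:
                c = np.linalg.cholesky(sub)
            except np.linalg.LinAlgError:
                return -np.inf, dmu, dSig
            logdet = 2.0 * np.sum(np.log(np.diag(c)))
            V = np.linalg.inv(sub)
            d = xbar - mu[o]
            M = S + np.outer(d, d)
            ll -= 0.5 * ng * (len(o) * _LOG2PI + logdet + np.trace(M @ V))
            dmu[o] += ng * (V @ d)
            dSig[np.ix_(o, o)] += 0.5 * ng * (V @ M @ V - V)
        return float(ll), dmu, dSig


# ---------------------------------------------------------------------------
# fitted model


@dataclass(frozen=True)
class CfaFit:
    """Estimates and log-likelihood of a fitted CFA."""

    spec: CfaModelSpec
    loadings: np.ndarray            # per-indicator loading on its construct
    theta: np.ndarray               # residual covariance matrix (p x p)
    phi: np.ndarray                 # construct correlation matrix (k x k)
    second_order_loadings: np.ndarray | None  # gamma per construct, or None
    means: np.ndarray
    loglik: float
    n: int
    converged: bool
    n_iter: int

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return self.spec.indicator_ids

    def lambda_matrix(self) -> np.ndarray:
        ids = self.spec.indicator_ids
        cons = self.spec.construct_names
        cidx = {c: j for j, c in enumerate(cons)}
        lam = np.zeros((len(ids), len(cons)))
        cof = self.spec.construct_of
        for i, ind in enumerate(ids):
            lam[i, cidx[cof[ind]]] = self.loadings[i]
        return lam

    def implied_sigma(self) -> np.ndarray:
        lam = self.lambda_matrix()
        return lam @ self.phi @ lam.T + self.theta

    def implied_correlation(self) -> np.ndarray:
        sig = self.implied_sigma()
        d = 1.0 / np.sqrt(np.diag(sig))
        return sig * np.outer(d, d)

    def standardized_loadings(self) -> pd.Series:
        """Loadings on the correlation metric: lambda_j / sd(x_j)."""
        sd = np.sqrt(np.diag(self.implied_sigma()))
        return pd.Series(self.loadings / sd, index=list(self.indicator_ids))

    def estimates_frame(self) -> pd.DataFrame:
        cof = self.spec.construct_of
        std = self.standardized_loadings()
        return pd.DataFrame(
            {
                "indicator": list(self.indicator_ids),
                "construct": [cof[i] for i in self.indicator_ids],
                "loading": self.loadings,
                "std_loading": std.to_numpy(),
                "residual_variance": np.diag(self.theta),
                "mean": self.means,
            }
        )


# ---------------------------------------------------------------------------
# parameter vector <-> model matrices

# fixed deterministic starting values
_START_LOADING = 0.5
_START_RESVAR = 0.5
_START_CORR = 0.2
_START_GAMMA = 0.5


def _phi_from_w(w: np.ndarray, k: int) -> np.ndarray:
    """Correlation matrix from unconstrained row-normalized Cholesky factors."""
    L = np.zeros((k, k))
    L[0, 0] = 1.0
    pos = 0
    for i in range(1, k):
        row = np.empty(i + 1)
        row[:i] = w[pos : pos + i]
        row[i] = 1.0
        pos += i
        L[i, : i + 1] = row / np.linalg.norm(row)
    return L @ L.T


def _w_from_corr(r: float, k: int) -> np.ndarray:
    """Unconstrained start giving an equicorrelation matrix ~ r (approximate)."""
    # row 2: a/sqrt(1+a^2) = r  ->  a = r/sqrt(1-r^2); later rows start the same
    a = r / math.sqrt(1.0 - r * r)
    return np.full(k * (k - 1) // 2, a)


class _Parameterization:
    def __init__(self, spec: CfaModelSpec):
        self.spec = spec
        self.ids = spec.indicator_ids
        self.p = len(self.ids)
        self.k = len(spec.constructs)
        self.r = len(spec.residual_covariances)
        self.second = spec.second_order is not None
        self.n_struct = self.k if self.second else self.k * (self.k - 1) // 2
        idx = {i: j for j, i in enumerate(self.ids)}
        self.rc_idx = [(idx[a], idx[b]) for a, b in spec.residual_covariances]
        cons = spec.construct_names
        cidx = {c: j for j, c in enumerate(cons)}
        self.col = np.array([cidx[spec.construct_of[i]] for i in self.ids])

    @property
    def n_params(self) -> int:
        return 3 * self.p + self.r + self.n_struct

    def start(self, data_means: np.ndarray) -> np.ndarray:
        x = np.empty(self.n_params)
        x[: self.p] = _START_LOADING
        x[self.p : 2 * self.p] = math.log(_START_RESVAR)
        x[2 * self.p : 2 * self.p + self.r] = 0.0
        s0 = 2 * self.p + self.r
        if self.second:
            x[s0 : s0 + self.n_struct] = math.atanh(_START_GAMMA)
        else:
            x[s0 : s0 + self.n_struct] = _w_from_corr(_START_CORR, self.k)
        x[s0 + self.n_struct :] = data_means
        return x

    def unpack(self, x: np.ndarray):
        p, r, k = self.p, self.r, self.k
        lam = x[:p]
        theta_d = np.exp(x[p : 2 * p])
        theta_od = x[2 * p : 2 * p + r]
        s0 = 2 * p + r
        sv = x[s0 : s0 + self.n_struct]
        mu = x[s0 + self.n_struct :]
        theta = np.diag(theta_d)
        for (i, j), v in zip(self.rc_idx, theta_od):
            theta[i, j] = theta[j, i] = v
        if self.second:
            gamma = np.tanh(sv)
            phi = np.outer(gamma, gamma)
            np.fill_diagonal(phi, 1.0)
        else:
            gamma = None
            phi = _phi_from_w(sv, k)
        return lam, theta, phi, gamma, mu, sv

    def sigma(self, lam, theta, phi):
        L = np.zeros((self.p, self.k))
        L[np.arange(self.p), self.col] = lam
        return L, L @ phi @ L.T + theta


def _neg_loglik_and_grad(x: np.ndarray, par: _Parameterization, data: _PatternData):
    lam, theta, phi, gamma, mu, sv = par.unpack(x)
    # penalize indefinite residual-covariance blocks
    if par.r:
        if np.linalg.eigvalsh(theta).min() <= 0:
            return 1e12, np.zeros_like(x)
    L, sigma = par.sigma(lam, theta, phi)
    ll, dmu, dSig = data.loglik_and_moment_grads(mu, sigma)
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(x)

    g = np.empty_like(x)
    p, r = par.p, par.r
    # loadings: dSigma/dlam_j = e_j (phi L')_{c(j),.} + sym
    OLP = dSig @ L @ phi  # p x k
    g[:p] = 2.0 * OLP[np.arange(p), par.col]
    # residual variances (log scale)
    g[p : 2 * p] = np.diag(dSig) * np.diag(theta)
    # residual covariances
    for t, (i, j) in enumerate(par.rc_idx):
        g[2 * p + t] = 2.0 * dSig[i, j]
    # structural parameters
    S = L.T @ dSig @ L  # k x k, dll = <S, dPhi>
    s0 = 2 * p + r
    if par.second:
        for c in range(par.k):
            dgc = 2.0 * (S[c] @ gamma - S[c, c] * gamma[c])
            g[s0 + c] = dgc * (1.0 - gamma[c] ** 2)
    else:
        # chain through the row-normalized Cholesky numerically (tiny k)
        eps = 1e-6
        for t in range(par.n_struct):
            sv_hi = sv.copy(); sv_hi[t] += eps
            sv_lo = sv.copy(); sv_lo[t] -= eps
            dPhi = (_phi_from_w(sv_hi, par.k) - _phi_from_w(sv_lo, par.k)) / (2 * eps)
            g[s0 + t] = np.sum(S * dPhi)
    g[s0 + par.n_struct :] = dmu
    return -ll, -g


def fit_cfa(
    matrix: PreparedMatrix | pd.DataFrame,
    spec: CfaModelSpec,
    *,
    max_iter: int = 2000,
) -> CfaFit:
    """Fit a CFA by full-information maximum likelihood.

    ``matrix`` is the standardized indicator matrix (missing cells allowed);
    rows with no observed model indicator are dropped.  On complete data the
    estimator coincides with ordinary complete-data ML.  Starting values are
    fixed (loadings 0.5, residual variances 0.5, correlations 0.2) so fits
    are deterministic.
    """
    df = matrix.to_frame() if isinstance(matrix, PreparedMatrix) else matrix
    ids = list(spec.indicator_ids)
    missing_cols = [i for i in ids if i not in df.columns]
    if missing_cols:
        raise KeyError(f"indicators not in matrix: {missing_cols}")
    X = df[ids].to_numpy(dtype=float)
    data = _PatternData(X)
    par = _Parameterization(spec)
    start_means = np.array([np.nanmean(X[:, j]) for j in range(par.p)])
    x0 = par.start(start_means)
    res = optimize.minimize(
        _neg_loglik_and_grad,
        x0,
        args=(par, data),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 10 * max_iter, "ftol": 1e-13, "gtol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"CFA did not converge: {res.message}")
    lam, theta, phi, gamma, mu, _ = par.unpack(res.x)
    lam, phi, gamma = _canonical_signs(lam, phi, gamma, par)
    converged = bool(res.success)
    if not res.success:
        # L-BFGS-B sometimes reports ABNORMAL after the line search stalls at
        # the optimum; accept if the gradient is essentially flat.
        gnorm = float(np.max(np.abs(res.jac)))
        converged = gnorm < 1e-3
        if not converged:
            raise RuntimeError(f"CFA did not converge: {res.message} (|grad|={gnorm:.2e})")
    return CfaFit(
        spec=spec,
        loadings=lam,
        theta=theta,
        phi=phi,
        second_order_loadings=gamma,
        means=mu,
        loglik=-float(res.fun),
        n=data.n,
        converged=converged,
        n_iter=int(res.nit),
    )


def _canonical_signs(lam, phi, gamma, par: _Parameterization):
    """Resolve factor sign indeterminacy: each construct's loadings sum
    positive; the severity factor points along the majority of gammas."""
    lam = lam.copy()
    phi = phi.copy()
    flips = np.ones(par.k)
    for c in range(par.k):
        if lam[par.col == c].sum() < 0:
            flips[c] = -1.0
            lam[par.col == c] *= -1.0
    phi = phi * np.outer(flips, flips)
    if gamma is not None:
        gamma = gamma * flips
        if gamma.sum() < 0:
            gamma = -gamma
        # phi is invariant to the severity sign
    return lam, phi, gamma


# ---------------------------------------------------------------------------
# reference likelihoods, chi-square and fit indices


def saturated_loglik(
    matrix: PreparedMatrix | pd.DataFrame,
    indicator_ids: Sequence[str] | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 2000,
) -> float:
    """FIML log-likelihood of the unstructured multivariate normal.

    Complete data gives the closed-form MLE; with missing cells the MLE of
    ``(mu, Sigma)`` is found by EM over missingness patterns.
    """
    df = matrix.to_frame() if isinstance(matrix, PreparedMatrix) else matrix
    if indicator_ids is not None:
        df = df[list(indicator_ids)]
    X = df.to_numpy(dtype=float)
    data = _PatternData(X)
    p = data.p

    # initial estimates: available-case means, pairwise covariances
    mu = np.array([np.nanmean(X[:, j]) for j in range(p)])
    sigma = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if both.sum() > 1:
                xi, xj = X[both, i], X[both, j]
                sigma[i, j] = sigma[j, i] = np.mean((xi - xi.mean()) * (xj - xj.mean()))
            else:
                sigma[i, j] = sigma[j, i] = 0.0
    w, v = np.linalg.eigh(sigma)
    sigma = (v * np.clip(w, 1e-6, None)) @ v.T

    if len(data.patterns) == 1 and len(data.patterns[0]["o"]) == p:
        pat = data.patterns[0]
        return data.loglik(pat["mean"], pat["scatter"])

    ll_old = data.loglik(mu, sigma)
    n = data.n
    for _ in range(max_iter):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        for pat in data.patterns:
            o, ng = pat["o"], pat["n"]
            m = np.setdiff1d(np.arange(p), o)
            rows = pat["rows"]
            s_o = rows.sum(axis=0)
            SS_oo = rows.T @ rows
            T1[o] += s_o
            T2[np.ix_(o, o)] += SS_oo
            if m.size:
                V = np.linalg.inv(sigma[np.ix_(o, o)])
                B = sigma[np.ix_(m, o)] @ V
                C = sigma[np.ix_(m, m)] - B @ sigma[np.ix_(o, m)]
                a = B @ (s_o - ng * mu[o])
                Em_sum = ng * mu[m] + a
                T1[m] += Em_sum
                # E[x_o x_m'] summed over rows
                XoEm = s_o[:, None] * mu[m][None, :] + (SS_oo - np.outer(s_o, mu[o])) @ B.T
                T2[np.ix_(o, m)] += XoEm
                T2[np.ix_(m, o)] += XoEm.T
                center = SS_oo - np.outer(s_o, mu[o]) - np.outer(mu[o], s_o) + ng * np.outer(mu[o], mu[o])
                EmEm = (
                    ng * np.outer(mu[m], mu[m])
                    + np.outer(mu[m], a) + np.outer(a, mu[m])
                    + B @ center @ B.T
                )
                T2[np.ix_(m, m)] += EmEm + ng * C
        mu = T1 / n
        sigma = T2 / n - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2.0
        ll = data.loglik(mu, sigma)
        if abs(ll - ll_old) < tol:
            ll_old = ll
            break
        ll_old = ll
    return float(ll_old)


def baseline_loglik(
    matrix: PreparedMatrix | pd.DataFrame,
    indicator_ids: Sequence[str] | None = None,
) -> float:
    """FIML log-likelihood of the independence model (diagonal Sigma).

    With zero covariances the likelihood factorizes, so each indicator's
    mean and variance MLE come from its own observed values.
    """
    df = matrix.to_frame() if isinstance(matrix, PreparedMatrix) else matrix
    if indicator_ids is not None:
        df = df[list(indicator_ids)]
    X = df.to_numpy(dtype=float)
    obs_any = ~np.isnan(X)
    X = X[obs_any.any(axis=1)]
    ll = 0.0
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = col[~np.isnan(col)]
        nj = obs.size
        var = np.mean((obs - obs.mean()) ** 2)
        ll -= 0.5 * nj * (_LOG2PI + math.log(var) + 1.0)
    return float(ll)


def count_df(spec: CfaModelSpec) -> int:
    """Model degrees of freedom: observed first- and second-order moments
    minus free parameters (means counted on both sides)."""
    p = len(spec.indicator_ids)
    moments = p * (p + 3) // 2
    return moments - spec.n_free_parameters()


def baseline_df(p: int) -> int:
    """Degrees of freedom of the independence baseline: p(p-1)/2."""
    return p * (p - 1) // 2


def chi_square(fit: CfaFit, saturated_ll: float) -> tuple[float, int]:
    """Likelihood-ratio chi-square against the saturated model, with df."""
    chi2 = 2.0 * (saturated_ll - fit.loglik)
    if chi2 < -1e-4:
        raise ArithmeticError(
            f"model log-likelihood exceeds the saturated log-likelihood "
            f"({fit.loglik:.6f} > {saturated_ll:.6f}); numerical failure"
        )
    return max(chi2, 0.0), count_df(fit.spec)


def fit_indices(
    chi2: float, df: int, chi2_b: float, df_b: int, n: int
) -> tuple[float, float, float]:
    """CFI, TLI and RMSEA from model and baseline chi-squares.

    RMSEA uses the conventional n-1 scaling.
    """
    if df_b <= df:
        warnings.warn("baseline df not larger than model df; malformed baseline", stacklevel=2)
    d = max(chi2 - df, 0.0)
    d_b = max(chi2_b - df_b, 0.0)
    cfi = 1.0 - d / max(d_b, d) if max(d_b, d) > 0 else 1.0
    denom = chi2_b / df_b - 1.0
    tli = (chi2_b / df_b - chi2 / df) / denom if df > 0 and denom != 0 else float("nan")
    rmsea = math.sqrt(d / (df * (n - 1))) if df > 0 else 0.0
    return cfi, tli, rmsea


@dataclass(frozen=True)
class FitSummary:
    chi_square: float
    df: int
    baseline_chi_square: float
    baseline_df: int
    cfi: float
    tli: float
    rmsea: float
    loglik: float
    n: int

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "baseline_chi_square": self.baseline_chi_square,
            "baseline_df": self.baseline_df,
            "cfi": self.cfi,
            "tli": self.tli,
            "rmsea": self.rmsea,
            "loglik": self.loglik,
            "n": self.n,
        }


def fit_summary(fit: CfaFit, matrix: PreparedMatrix | pd.DataFrame) -> FitSummary:
    """Chi-square and fit indices for a fitted model on its data."""
    ids = fit.spec.indicator_ids
    ll_sat = saturated_loglik(matrix, ids)
    ll_base = baseline_loglik(matrix, ids)
    chi2, df = chi_square(fit, ll_sat)
    chi2_b = 2.0 * (ll_sat - ll_base)
    df_b = baseline_df(len(ids))
    cfi, tli, rmsea = fit_indices(chi2, df, chi2_b, df_b, fit.n)
    return FitSummary(chi2, df, chi2_b, df_b, cfi, tli, rmsea, fit.loglik, fit.n)


# ---------------------------------------------------------------------------
# residuals and modification


@dataclass(frozen=True)
class ResidualReport:
    """Observed-minus-implied correlations with flags above a threshold."""

    residuals: pd.DataFrame
    cross_construct_flags: tuple[tuple[str, str, float], ...]
    within_construct_flags: tuple[tuple[str, str, float], ...]
    threshold: float


def residual_correlations(
    fit: CfaFit,
    matrix: PreparedMatrix | pd.DataFrame,
    threshold: float = 0.10,
) -> ResidualReport:
    """Pairwise-complete observed correlations minus model-implied ones.

    Pairs with absolute residual above ``threshold`` are flagged and
    classified as within- or cross-construct; flagged within-construct pairs
    already joined by a residual covariance are not re-flagged.
    """
    df = matrix.to_frame() if isinstance(matrix, PreparedMatrix) else matrix
    ids = list(fit.spec.indicator_ids)
    obs = df[ids].corr(method="pearson", min_periods=3).to_numpy()
    implied = fit.implied_correlation()
    resid = obs - implied
    cof = fit.spec.construct_of
    have_rc = {frozenset(p) for p in fit.spec.residual_covariances}
    cross, within = [], []
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            r = resid[a, b]
            if np.isnan(r) or abs(r) <= threshold:
                continue
            pair = (ids[a], ids[b], float(r))
            if cof[ids[a]] == cof[ids[b]]:
                if frozenset((ids[a], ids[b])) not in have_rc:
                    within.append(pair)
            else:
                cross.append(pair)
    resid_df = pd.DataFrame(resid, index=ids, columns=ids)
    return ResidualReport(resid_df, tuple(cross), tuple(within), threshold)


def _cross_residual_load(report: ResidualReport) -> dict[str, float]:
    load: dict[str, float] = {}
    for a, b, r in report.cross_construct_flags:
        for i in (a, b):
            load[i] = max(load.get(i, 0.0), abs(r))
    return load


def modify_model(
    matrix: PreparedMatrix | pd.DataFrame,
    spec: CfaModelSpec,
    *,
    budget: int = 10,
    threshold: float = 0.10,
    min_indicators: int = 2,
) -> tuple[CfaModelSpec, CfaFit, list[dict]]:
    """Residual-driven model modification, one change per refit.

    At each step: if any cross-construct residual exceeds the threshold, the
    indicator involved in the largest one is removed; otherwise, if a
    within-construct pair exceeds it, a residual covariance is added for the
    largest such pair.  The loop stops when no flags remain, the budget is
    exhausted, or a removal would leave a construct with fewer than
    ``min_indicators`` indicators.  Returns the final spec, its fit, and the
    modification log.
    """
    log: list[dict] = []
    fit = fit_cfa(matrix, spec)
    for step in range(budget):
        report = residual_correlations(fit, matrix, threshold)
        if report.cross_construct_flags:
            load = _cross_residual_load(report)
            victim = max(load, key=lambda i: load[i])
            construct = spec.construct_of[victim]
            if len(spec.constructs[construct]) - 1 < min_indicators:
                warnings.warn(
                    f"stopping: removing {victim!r} would leave construct "
                    f"{construct!r} with fewer than {min_indicators} indicators",
                    stacklevel=2,
                )
                break
            log.append({"step": step, "action": "remove_indicator", "target": victim,
                        "residual": load[victim]})
            spec = spec.drop_indicator(victim)
        elif report.within_construct_flags:
            a, b, r = max(report.within_construct_flags, key=lambda t: abs(t[2]))
            log.append({"step": step, "action": "add_residual_covariance",
                        "target": (a, b), "residual": r})
            spec = spec.add_residual_covariance(a, b)
        else:
            break
        fit = fit_cfa(matrix, spec)
    return spec, fit, log


# ---------------------------------------------------------------------------
# factor scores


@dataclass(frozen=True)
class SeverityScores:
    """Per-crisis latent severity estimates, raw and min-max normalized."""

    crisis_ids: tuple[str, ...]
    raw: np.ndarray
    normalized: np.ndarray
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"severity_raw": self.raw, "severity_normalized": self.normalized},
            index=list(self.crisis_ids),
        )

    def summarize_by(self, labels: Mapping[str, str]) -> pd.DataFrame:
        df = self.to_frame()
        df["group"] = [labels.get(c, "unknown") for c in self.crisis_ids]
        return (
            df.groupby("group")["severity_normalized"]
            .agg(["mean", "median", "min", "max", "count"])
            .reset_index()
        )


def severity_factor_scores(
    fit: CfaFit, matrix: PreparedMatrix | pd.DataFrame
) -> SeverityScores:
    """Regression-method scores for the second-order severity factor.

    Each crisis's score is the conditional expectation of the severity
    factor given its observed indicators,
    ``E[s | x_obs] = c_obs' Sigma_obs^{-1} (x_obs - mu_obs)`` with
    ``c = Lambda gamma`` the model-implied indicator-severity covariances.
    Scores are min-max normalized over the scored crises; crises with no
    observed model indicator get NaN.
    """
    if fit.second_order_loadings is None:
        raise ValueError("fit has no second-order severity factor")
    df = matrix.to_frame() if isinstance(matrix, PreparedMatrix) else matrix
    ids = list(fit.spec.indicator_ids)
    X = df[ids].to_numpy(dtype=float)
    sigma = fit.implied_sigma()
    lam = fit.lambda_matrix()
    c = lam @ fit.second_order_loadings
    raw = np.full(X.shape[0], np.nan)
    for i in range(X.shape[0]):
        o = np.flatnonzero(~np.isnan(X[i]))
        if o.size == 0:
            continue
        V = np.linalg.inv(sigma[np.ix_(o, o)])
        raw[i] = c[o] @ V @ (X[i, o] - fit.means[o])
    scored = ~np.isnan(raw)
    lo, hi = np.nanmin(raw), np.nanmax(raw)
    degenerate = bool(np.isclose(hi, lo))
    if degenerate:
        warnings.warn("all severity scores identical; normalization degenerate", stacklevel=2)
        norm = np.where(scored, np.nan, np.nan)
    else:
        norm = (raw - lo) / (hi - lo)
    return SeverityScores(tuple(df.index.astype(str)), raw, norm, degenerate)
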