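"""Maximum-likelihood exploratory factor analysis with oblique rotation.

Extraction minimizes the ML discrepancy over the uniquenesses: with
``R* = Psi^{-1/2} R Psi^{-1/2}`` and eigenvalues ``l_1 >= ... >= l_p``, the
profile objective for a k-factor model is ``sum_{m>k} (l_m - log l_m - 1)``,
whose minimizer yields loadings ``Lambda = Psi^{1/2} W_k (L_k - I)^{1/2}``
from the top-k eigenpairs.  Rotation is direct quartimin (oblimin with
gamma = 0) via the oblique gradient-projection algorithm, so factors are
allowed to correlate.

Solution evaluation implements three retention criteria — per-factor sums of
squared loadings above 1.0, per-factor proportion of variance of at least
10%, and cumulative variance of at least 60% — and the indicator-pruning
rules (low loadings, cross-loadings, sign conflicts) used to carry a reduced
indicator set into the confirmatory stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .table import PreparedMatrix

__all__ = [
    "EfaSolution",
    "RetentionReport",
    "PruneReport",
    "scree",
    "fit_efa",
    "fit_efa_corr",
    "rotate_quartimin",
    "evaluate_solutions",
    "prune_indicators",
]

UNIQUENESS_FLOOR = 0.005


@dataclass(frozen=True)
class EfaSolution:
    """A k-factor oblique ML solution.

    ``pattern`` holds the rotated pattern loadings (regression weights of
    indicators on factors), ``factor_corr`` the factor correlation matrix,
    ``uniquenesses`` the residual variances of the standardized indicators.
    ``ss_loadings`` uses the oblique convention: per-factor column sums of
    pattern x structure, which reduce to plain squared-loading sums when the
    factors are uncorrelated.
    """

    k: int
    indicator_ids: tuple[str, ...]
    pattern: np.ndarray
    factor_corr: np.ndarray
    uniquenesses: np.ndarray
    ss_loadings: np.ndarray
    proportion_var: np.ndarray
    cumulative_var: np.ndarray
    eigenvalues: np.ndarray
    loglik_discrepancy: float
    n_obs: int
    heywood: bool = False

    @property
    def structure(self) -> np.ndarray:
        return self.pattern @ self.factor_corr

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    def implied_correlation(self) -> np.ndarray:
        return self.pattern @ self.factor_corr @ self.pattern.T + np.diag(self.uniquenesses)

    def loadings_frame(self, display_threshold: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.pattern,
            index=list(self.indicator_ids),
            columns=[f"factor{j + 1}" for j in range(self.k)],
        )
        if display_threshold is not None:
            df = df.where(df.abs() >= display_threshold)
        return df

    def variance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": [f"factor{j + 1}" for j in range(self.k)],
                "ss_loadings": self.ss_loadings,
                "proportion_var": self.proportion_var,
                "cumulative_var": self.cumulative_var,
            }
        )


@dataclass(frozen=True)
class RetentionReport:
    """Verdicts of the three factor-retention criteria per solution."""

    ss_pass: dict[int, list[bool]]          # k -> per-factor ss > 1.0
    proportion_pass: dict[int, list[bool]]  # k -> per-factor proportion >= 10%
    cumulative_pass: dict[int, bool]        # k -> cumulative >= 60%
    recommended: tuple[int, ...]            # k's whose every factor passes both per-factor rules

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.ss_pass:
            rows.append(
                {
                    "k": k,
                    "all_ss_above_1": all(self.ss_pass[k]),
                    "all_proportion_above_10pct": all(self.proportion_pass[k]),
                    "cumulative_above_60pct": self.cumulative_pass[k],
                    "recommended": k in self.recommended,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PruneReport:
    """Indicators removed after inspecting pattern loadings."""

    removed: dict[str, str]  # indicator id -> reason
    retained: tuple[str, ...]
    display_threshold: float
    cross_loading_gap: float

    def to_frame(self) -> pd.DataFrame:
        rows = [{"indicator": i, "removed": True, "reason": r} for i, r in self.removed.items()]
        rows += [{"indicator": i, "removed": False, "reason": ""} for i in self.retained]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# extraction


def scree(corr: np.ndarray) -> np.ndarray:
    """Eigenvalues of a correlation matrix, sorted descending."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    return np.sort(np.linalg.eigvalsh(corr))[::-1]


def _ml_objective(log_psi: np.ndarray, R: np.ndarray, k: int):
    """Profile ML discrepancy over uniquenesses, with analytic gradient."""
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(d, d)
    lam, W = np.linalg.eigh(Rstar)
    lam, W = lam[::-1], W[:, ::-1]
    tail = lam[k:]
    tail = np.clip(tail, 1e-12, None)
    f = float(np.sum(tail - np.log(tail) - 1.0))
    # dF/d log psi_j = -sum_{m>k} (l_m - 1) w_{mj}^2
    grad = -np.sum((lam[k:] - 1.0)[None, :] * W[:, k:] ** 2, axis=1)
    return f, grad


def _ledermann_ok(p: int, k: int) -> bool:
    return ((p - k) ** 2 - (p + k)) >= 0


def fit_efa_corr(
    R: np.ndarray,
    n_obs: int,
    k: int,
    indicator_ids: Sequence[str] | None = None,
    rotation: str | None = "oblimin",
) -> EfaSolution:
    """ML exploratory factor analysis of a correlation matrix.

    Parameters
    ----------
    R : (p, p) correlation matrix.
    n_obs : number of observations behind ``R`` (kept for reporting).
    k : number of factors; must satisfy the Ledermann bound.
    rotation : ``"oblimin"`` (direct quartimin, the default), or ``None``
        for the unrotated canonical solution.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if not _ledermann_ok(p, k):
        raise ValueError(f"k={k} exceeds the Ledermann bound for p={p}")
    if indicator_ids is None:
        indicator_ids = tuple(f"x{j + 1}" for j in range(p))
    eigvals = scree(R)

    # classical start: psi_j = (1 - k/(2p)) / (R^{-1})_jj
    start = (1.0 - 0.5 * k / p) / np.diag(np.linalg.inv(R))
    start = np.clip(start, UNIQUENESS_FLOOR * 2, 1.0)

    def solve(x0):
        return optimize.minimize(
            _ml_objective,
            np.log(x0),
            args=(R, k),
            jac=True,
            method="L-BFGS-B",
            bounds=[(np.log(UNIQUENESS_FLOOR), 0.0)] * p,
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-10},
        )

    res = solve(start)
    if not np.isfinite(res.fun):
        raise RuntimeError(f"EFA extraction failed to converge: {res.message}")

    def is_heywood(r):
        return bool(np.any(np.exp(r.x) <= UNIQUENESS_FLOOR * (1 + 1e-6)))

    if is_heywood(res):
        # near-flat likelihoods (weak structure) admit spurious boundary
        # optima; prefer an interior solution of equal fit when one exists
        alt = solve(np.full(p, 0.9))
        if np.isfinite(alt.fun) and alt.fun <= res.fun + 1e-8 and not is_heywood(alt):
            res = alt
    psi = np.exp(res.x)
    heywood = bool(np.any(psi <= UNIQUENESS_FLOOR * (1 + 1e-6)))
    if heywood:
        warnings.warn("Heywood case: uniqueness at lower bound", stacklevel=2)

    d = 1.0 / np.sqrt(psi)
    lam, W = np.linalg.eigh(R * np.outer(d, d))
    lam, W = lam[::-1], W[:, ::-1]
    load = np.sqrt(psi)[:, None] * W[:, :k] * np.sqrt(np.clip(lam[:k] - 1.0, 0.0, None))[None, :]

    if rotation is None:
        pattern, phi = load, np.eye(k)
    elif rotation == "oblimin":
        pattern, phi = (load, np.eye(k)) if k == 1 else rotate_quartimin(load)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")

    pattern, phi = _canonicalize(pattern, phi)
    structure = pattern @ phi
    ss = np.sum(pattern * structure, axis=0)
    proportion = ss / p
    cumulative = np.cumsum(proportion)
    return EfaSolution(
        k=k,
        indicator_ids=tuple(indicator_ids),
        pattern=pattern,
        factor_corr=phi,
        uniquenesses=psi,
        ss_loadings=ss,
        proportion_var=proportion,
        cumulative_var=cumulative,
        eigenvalues=eigvals,
        loglik_discrepancy=float(res.fun),
        n_obs=n_obs,
        heywood=heywood,
    )


def fit_efa(
    matrix: PreparedMatrix | pd.DataFrame | np.ndarray,
    k: int,
    rotation: str | None = "oblimin",
) -> EfaSolution:
    """Fit a k-factor ML EFA to a complete data matrix (rows = crises).

    The Pearson correlation matrix of the (median-imputed) numeric scores is
    analysed; ordinal values are treated as numeric.
    """
    if isinstance(matrix, PreparedMatrix):
        df = matrix.to_frame()
    elif isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        arr = np.asarray(matrix, dtype=float)
        df = pd.DataFrame(arr, columns=[f"x{j + 1}" for j in range(arr.shape[1])])
    if df.isna().any().any():
        raise ValueError("EFA requires a complete matrix; impute first")
    R = np.corrcoef(df.to_numpy(), rowvar=False)
    return fit_efa_corr(R, len(df), k, tuple(df.columns), rotation)


# ---------------------------------------------------------------------------
# rotation


def _quartimin(L: np.ndarray):
    L2 = L**2
    X = L2 @ (np.ones((L.shape[1],) * 2) - np.eye(L.shape[1]))
    return float(np.sum(L2 * X)) / 4.0, L * X


def rotate_quartimin(
    A: np.ndarray, max_iter: int = 1000, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-quartimin (oblimin, gamma = 0) rotation by oblique gradient
    projection.

    Returns the rotated pattern matrix and the factor correlation matrix.
    The model-implied correlation matrix is invariant under the rotation.
    """
    A = np.asarray(A, dtype=float)
    k = A.shape[1]
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp**2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            Tt = X / np.sqrt(np.sum(X**2, axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin(L)
            if ft < f - 0.5 * s**2 * al:
                break
            al /= 2.0
        T, f = Tt, ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi


def _canonicalize(pattern: np.ndarray, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Order factors by descending explained variance; flip signs so each
    factor's largest-|loading| indicator loads positively."""
    structure = pattern @ phi
    ss = np.sum(pattern * structure, axis=0)
    order = np.argsort(-ss, kind="stable")
    pattern = pattern[:, order]
    phi = phi[np.ix_(order, order)]
    signs = np.ones(pattern.shape[1])
    for j in range(pattern.shape[1]):
        i = int(np.argmax(np.abs(pattern[:, j])))
        if pattern[i, j] < 0:
            signs[j] = -1.0
    pattern = pattern * signs[None, :]
    phi = phi * np.outer(signs, signs)
    return pattern, phi


# ---------------------------------------------------------------------------
# evaluation and pruning


def evaluate_solutions(
    solutions: Sequence[EfaSolution],
    *,
    ss_cutoff: float = 1.0,
    proportion_cutoff: float = 0.10,
    cumulative_cutoff: float = 0.60,
) -> RetentionReport:
    """Apply the three retention criteria to a family of solutions.

    A solution is *recommended* when every factor clears both per-factor
    rules (sums of squared loadings above ``ss_cutoff`` and proportion of
    variance at least ``proportion_cutoff``); the cumulative-variance rule is
    reported separately since on weakly determined data no solution may
    reach it.
    """
    ids = {s.indicator_ids for s in solutions}
    if len(ids) != 1:
        raise ValueError("solutions must share the same indicator set")
    ss_pass, prop_pass, cum_pass = {}, {}, {}
    recommended = []
    for s in sorted(solutions, key=lambda s: s.k):
        ss_pass[s.k] = [bool(v > ss_cutoff) for v in s.ss_loadings]
        prop_pass[s.k] = [bool(v >= proportion_cutoff) for v in s.proportion_var]
        cum_pass[s.k] = bool(s.cumulative_var[-1] >= cumulative_cutoff)
        if all(ss_pass[s.k]) and all(prop_pass[s.k]):
            recommended.append(s.k)
    return RetentionReport(ss_pass, prop_pass, cum_pass, tuple(recommended))


def _prune_one(
    pattern: np.ndarray, display_threshold: float, gap: float
) -> str | None:
    """Reason one indicator row should be removed, or None."""
    a = np.abs(pattern)
    order = np.argsort(-a)
    primary, secondary = order[0], (order[1] if len(order) > 1 else None)
    if a[primary] < display_threshold:
        return "low_loading"
    if secondary is not None:
        big = a >= display_threshold
        if big.sum() >= 2:
            signs = np.sign(pattern[big])
            if (signs > 0).any() and (signs < 0).any():
                return "sign_conflict"
        if a[secondary] >= display_threshold and (a[primary] - a[secondary]) < gap:
            return "cross_loading"
    return None


def prune_indicators(
    solution3: EfaSolution,
    solution4: EfaSolution,
    display_threshold: float = 0.30,
    cross_loading_gap: float = 0.20,
) -> PruneReport:
    """Flag indicators for removal ahead of the confirmatory stage.

    An indicator is removed if, in either solution, (a) its largest absolute
    pattern loading falls below ``display_threshold``; (b) it carries
    loadings of opposite sign, each at or above the display threshold, on
    two factors; or (c) it loads at or above the display threshold on two
    factors whose absolute loadings differ by less than
    ``cross_loading_gap`` (it fails to pick a side).
    """
    if solution3.indicator_ids != solution4.indicator_ids:
        raise ValueError("solutions cover different indicator sets")
    removed: dict[str, str] = {}
    for row, ind in enumerate(solution3.indicator_ids):
        for sol in (solution3, solution4):
            reason = _prune_one(sol.pattern[row], display_threshold, cross_loading_gap)
            if reason is not None:
                removed[ind] = reason
                break
    retained = tuple(i for i in solution3.indicator_ids if i not in removed)
    return PruneReport(removed, retained, display_threshold, cross_loading_gap)
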