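"""Beta mixture modeling of per-cluster methylation with BIC selection.

Methylation beta values are proportions, so each CpG cluster's tumor
profile is modeled as a finite mixture of Beta(alpha_k, beta_k)
densities.  Components are added one at a time starting from K = 1 and a
larger model is kept only if it strictly improves the Bayesian
Information Criterion

    BIC = -2 log L + (3K - 1) log n

(two shape parameters per component plus K - 1 free weights).  Each
component is interpreted as a methylation state, i.e. a patient subgroup
with a distinct methylation level.

EM details: responsibilities are initialized from a quantile split of the
sorted values (first restart) or random seed points (remaining restarts);
the M-step solves the weighted Beta maximum-likelihood equations exactly
by Newton iteration on the digamma system, so the observed-data
log-likelihood is non-decreasing across iterations.  Values are clamped
to [1e-3, 1 - 1e-3] before likelihood evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaln, digamma, polygamma

__all__ = ["BetaMixtureModel", "fit_beta_mixture", "EPS"]

EPS = 1e-3
_SHAPE_LO, _SHAPE_HI = 1e-3, 1e7


@dataclass
class BetaMixtureModel:
    """Fitted Beta mixture for one CpG cluster."""

    alpha: np.ndarray  # shape (K,)
    beta: np.ndarray  # shape (K,)
    weights: np.ndarray  # shape (K,), sums to 1
    loglik: float
    bic: float
    responsibilities: np.ndarray  # (n, K)
    assignments: np.ndarray  # (n,) max-posterior component index
    n_obs: int
    converged: bool = True
    degenerate: bool = False
    n_iter: int = 0
    restart: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def means(self) -> np.ndarray:
        return self.alpha / (self.alpha + self.beta)


def _clamp(x: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(x, dtype=float), EPS, 1.0 - EPS)


def _solve_beta_mle(
    s1: np.ndarray,
    s2: np.ndarray,
    m: np.ndarray,
    v: np.ndarray,
    a0: np.ndarray | None = None,
    b0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Beta MLE from sufficient statistics s1 = E[log x],
    s2 = E[log(1-x)]: solves psi(a) - psi(a+b) = s1 and
    psi(b) - psi(a+b) = s2 by damped Newton iteration, vectorized over
    components.  Warm-started from (a0, b0) when given (the previous EM
    iterate), otherwise from the weighted moments."""
    s1 = np.atleast_1d(np.asarray(s1, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    if a0 is None or b0 is None:
        mm = np.clip(np.atleast_1d(m), EPS, 1.0 - EPS)
        vv = np.maximum(np.atleast_1d(v), 1e-10)
        c = np.maximum(mm * (1.0 - mm) / vv - 1.0, 1e-2)
        a = np.clip(mm * c, _SHAPE_LO, _SHAPE_HI)
        b = np.clip((1.0 - mm) * c, _SHAPE_LO, _SHAPE_HI)
    else:
        a = np.array(a0, dtype=float)
        b = np.array(b0, dtype=float)
    for _ in range(100):
        dg = digamma(np.concatenate([a, b, a + b]))
        K = len(a)
        common = dg[2 * K :]
        g1 = s1 - dg[:K] + common
        g2 = s2 - dg[K : 2 * K] + common
        if max(np.max(np.abs(g1)), np.max(np.abs(g2))) < 1e-11:
            break
        tg = polygamma(1, np.concatenate([a, b, a + b]))
        t = tg[2 * K :]
        j11 = t - tg[:K]
        j22 = t - tg[K : 2 * K]
        det = j11 * j22 - t * t
        tiny = np.abs(det) < 1e-300
        det = np.where(tiny, 1.0, det)
        da = np.where(tiny, 0.0, -(j22 * g1 - t * g2) / det)
        db = np.where(tiny, 0.0, -(j11 * g2 - t * g1) / det)
        lam = np.ones(K)
        for _ in range(40):
            na, nb = a + lam * da, b + lam * db
            bad = (
                (na < _SHAPE_LO) | (na > _SHAPE_HI)
                | (nb < _SHAPE_LO) | (nb > _SHAPE_HI)
            )
            if not bad.any():
                break
            lam = np.where(bad, lam * 0.5, lam)
        a = np.clip(a + lam * da, _SHAPE_LO, _SHAPE_HI)
        b = np.clip(b + lam * db, _SHAPE_LO, _SHAPE_HI)
    bad = ~(np.isfinite(a) & np.isfinite(b))
    if bad.any():
        mm = np.clip(np.atleast_1d(m), EPS, 1.0 - EPS)
        vv = np.maximum(np.atleast_1d(v), 1e-10)
        c = np.maximum(mm * (1.0 - mm) / vv - 1.0, 1e-2)
        a = np.where(bad, np.clip(mm * c, _SHAPE_LO, _SHAPE_HI), a)
        b = np.where(bad, np.clip((1.0 - mm) * c, _SHAPE_LO, _SHAPE_HI), b)
    return a, b


def _component_loglik(
    logx: np.ndarray, log1mx: np.ndarray, a: np.ndarray, b: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """(n, K) matrix of log(w_k) + log BetaPDF_k(x_i)."""
    return (
        logx[:, None] * (a - 1.0)
        + log1mx[:, None] * (b - 1.0)
        - betaln(a, b)
        + np.log(w)
    )


def _em(
    x: np.ndarray,
    logx: np.ndarray,
    log1mx: np.ndarray,
    resp: np.ndarray,
    max_iter: int,
    tol: float,
) -> dict | None:
    """Run EM from an initial responsibility matrix; None on collapse.

    Returns the final responsibilities so a short run can be continued
    to convergence (short-EM restart strategy)."""
    n, K = resp.shape
    a = b = None
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        rk = resp.sum(axis=0)
        if np.any(rk < 1e-8):
            return None  # component lost all mass
        w = rk / n
        s1 = logx @ resp / rk
        s2 = log1mx @ resp / rk
        m = x @ resp / rk
        v = (x * x) @ resp / rk - m * m
        # warm-start Newton from the previous iterate after the first pass
        a, b = _solve_beta_mle(s1, s2, m, v, a, b)
        logcomp = _component_loglik(logx, log1mx, a, b, w)
        row_max = logcomp.max(axis=1)
        row_ll = row_max + np.log(np.exp(logcomp - row_max[:, None]).sum(axis=1))
        ll = float(row_ll.sum())
        resp = np.exp(logcomp - row_ll[:, None])
        if ll + 1e-7 * (1.0 + abs(ll)) < ll_old:
            # exact M-step makes EM monotone; a drop signals numerics
            return None
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
    return {
        "alpha": a.copy(),
        "beta": b.copy(),
        "weights": w.copy(),
        "loglik": ll,
        "resp": resp,
        "converged": converged,
        "n_iter": it,
    }


def _quantile_split_resp(x: np.ndarray, K: int) -> np.ndarray:
    """Deterministic init: contiguous equal-size blocks of the sorted
    values, one block per component."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    resp = np.zeros((n, K))
    for k, block in enumerate(np.array_split(order, K)):
        resp[block, k] = 1.0
    return resp


def _random_seed_resp(x: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Random restart: K distinct data points as seeds, hard-assign by
    nearest seed."""
    n = len(x)
    seeds = rng.choice(x, size=K, replace=False)
    lab = np.argmin(np.abs(x[:, None] - seeds[None, :]), axis=1)
    resp = np.zeros((n, K))
    resp[np.arange(n), lab] = 1.0
    # make sure no component starts empty
    for k in range(K):
        if resp[:, k].sum() == 0:
            resp[rng.integers(n)] = 0.0
            resp[rng.integers(n), k] = 1.0
    return resp


def _finalize(fit: dict, n: int, restart: int) -> BetaMixtureModel:
    K = len(fit["weights"])
    order = np.argsort(fit["alpha"] / (fit["alpha"] + fit["beta"]), kind="stable")
    a = fit["alpha"][order]
    b = fit["beta"][order]
    w = fit["weights"][order]
    resp = fit["resp"][:, order]
    bic = -2.0 * fit["loglik"] + (3 * K - 1) * np.log(n)
    # argmax returns the first maximum, i.e. ties go to the lower-mean state
    assignments = np.argmax(resp, axis=1)
    return BetaMixtureModel(
        alpha=a,
        beta=b,
        weights=w,
        loglik=fit["loglik"],
        bic=float(bic),
        responsibilities=resp,
        assignments=assignments,
        n_obs=n,
        converged=fit["converged"],
        n_iter=fit["n_iter"],
        restart=restart,
    )


def fit_beta_mixture(
    betas: np.ndarray,
    k_max: int = 3,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    min_weight: float | None = None,
) -> BetaMixtureModel:
    """Fit a Beta mixture with forward BIC selection of the component
    count.

    Starting from K = 1, a (K+1)-component model (best of ``n_restarts``
    EM initializations) replaces the current one only if its BIC is
    strictly lower; selection stops at the first rejection or at
    ``k_max``.  Candidates with any mixing weight below ``min_weight``
    (default 1/n, i.e. less than one expected sample) are rejected.
    Deterministic given ``seed``.
    """
    x = _clamp(betas)
    n = len(x)
    if n < 10:
        raise ValueError("mixture fitting needs at least 10 observations")
    rng = np.random.default_rng(seed)
    if min_weight is None:
        min_weight = 1.0 / n

    if np.ptp(x) < 1e-10:
        m = float(x[0])
        c = 1e6
        a = np.array([m * c])
        b = np.array([(1.0 - m) * c])
        ll = float(
            np.sum((a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b))
        )
        return BetaMixtureModel(
            alpha=a,
            beta=b,
            weights=np.array([1.0]),
            loglik=ll,
            bic=float(-2 * ll + 2 * np.log(n)),
            responsibilities=np.ones((n, 1)),
            assignments=np.zeros(n, dtype=int),
            n_obs=n,
            degenerate=True,
        )

    logx = np.log(x)
    log1mx = np.log1p(-x)

    def fit_k(K: int) -> BetaMixtureModel | None:
        """Short-EM restarts: every initialization runs a capped number of
        iterations, only the best short run is continued to convergence."""
        best: dict | None = None
        best_restart = 0
        restarts = 1 if K == 1 else n_restarts
        short_iter = max_iter if K == 1 else min(50, max_iter)
        for r in range(restarts):
            resp0 = (
                _quantile_split_resp(x, K)
                if r == 0
                else _random_seed_resp(x, K, rng)
            )
            fit = _em(x, logx, log1mx, resp0, short_iter, tol)
            if fit is None or np.min(fit["weights"]) < min_weight:
                continue
            if best is None or fit["loglik"] > best["loglik"]:
                best = fit
                best_restart = r
        if best is None:
            return None
        if not best["converged"] and short_iter < max_iter:
            cont = _em(x, logx, log1mx, best["resp"], max_iter, tol)
            if cont is not None and np.min(cont["weights"]) >= min_weight:
                best = cont
        return _finalize(best, n, best_restart)

    model = fit_k(1)
    assert model is not None  # K = 1 cannot collapse
    for K in range(2, k_max + 1):
        candidate = fit_k(K)
        if candidate is None or candidate.bic >= model.bic:
            break
        model = candidate
    return model
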