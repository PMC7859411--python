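"""Tumor purity from copy-neutral SNVs via an ordered binomial mixture.

Model
-----
For SNVs restricted to copy-neutral segments (total CN 2, minor CN 1) the
tumor alt-read count at site *i* follows

    x_i ~ sum_k  pi_k * Binom(x_i; N_i, theta_k),    theta_K < ... < theta_1 <= 0.5

where each component is a (sub)clone.  A fully clonal heterozygous SNV in a
tumor of purity ``rho`` has expected VAF ``rho / 2``, so purity is estimated
as ``2 * theta_1`` from the largest component mean.  Parameters are fitted by
EM; the number of components is chosen by BIC with ``p = 2K - 1`` free
parameters (K means, K-1 weights), ties broken toward the smaller K.

The ordering constraint and the 0.5 bound are enforced after each M-step by
sorting components on theta descending and clipping at 0.5 (a projection; the
EM ascent property is asserted per iteration up to numerical tolerance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .core import CNProfile, VariantRecord

log = logging.getLogger("chordwgs")

_THETA_FLOOR = 1e-9


@dataclass
class PurityFit:
    """Fitted ordered binomial mixture."""

    K: int
    theta: np.ndarray  # descending, theta[0] <= 0.5
    pi: np.ndarray  # sums to 1
    loglik: float
    bic: float
    purity: float  # 2 * theta[0], clipped to <= 1
    n_variants: int
    converged: bool
    n_iter: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class PurityCall:
    """Per-sample purity estimate, or a no-call with its reason."""

    sample_id: str
    purity: float | None
    fit: PurityFit | None
    n_neutral: int
    status: str  # "ok" | "no-call"
    reason: str = ""


def select_neutral_variants(
    variants: list[VariantRecord], profile: CNProfile
) -> list[VariantRecord]:
    """Keep variants lying in copy-neutral segments (tcn=2, minor=1).

    Variants falling in coverage gaps are dropped with a warning.
    """
    kept: list[VariantRecord] = []
    n_gap = 0
    for v in variants:
        seg = profile.segment_at(v.chrom, v.pos - 1)
        if seg is None:
            n_gap += 1
            continue
        if seg.tcn == 2 and seg.mcn_minor == 1:
            kept.append(v)
    if n_gap:
        log.warning(
            "%s: %d variant(s) fall in segment gaps and were dropped",
            profile.sample_id, n_gap,
        )
    return kept


def _binom_logpmf_matrix(x: np.ndarray, n: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """log Binom(x; n, theta_k) as a (K, n_obs) matrix; theta=0/1 handled exactly."""
    th = np.clip(theta, _THETA_FLOOR, 1 - _THETA_FLOOR)[:, None]
    coef = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    return coef[None, :] + x[None, :] * np.log(th) + (n - x)[None, :] * np.log1p(-th)


def em_fit(
    alt_counts,
    depths,
    K: int,
    init: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PurityFit:
    """Single EM run for a K-component ordered binomial mixture.

    ``init`` is an optional (theta, pi) pair; by default theta starts at K
    evenly spaced quantiles of x/N (descending) and pi is uniform, which is
    invariant under permutation of the input variants.
    """
    x = np.asarray(alt_counts, dtype=float)
    n = np.asarray(depths, dtype=float)
    if x.shape != n.shape or x.ndim != 1:
        raise ValueError("alt_counts and depths must be equal-length 1-D arrays")
    if np.any(n <= 0):
        raise ValueError("all depths must be > 0")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > x.size:
        raise ValueError(f"K={K} exceeds number of variants ({x.size})")

    if init is not None:
        theta = np.asarray(init[0], dtype=float).copy()
        pi = np.asarray(init[1], dtype=float).copy()
    else:
        qs = (2 * np.arange(K, 0, -1) - 1) / (2 * K)  # descending quantile levels
        theta = np.quantile(x / n, qs)
        pi = np.full(K, 1.0 / K)
    theta = np.minimum(np.maximum(theta, _THETA_FLOOR), 0.5)
    pi = np.maximum(pi, 1e-12)
    pi = pi / pi.sum()

    history = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = np.log(pi)[:, None] + _binom_logpmf_matrix(x, n, theta)
        log_mix = logsumexp(log_comp, axis=0)
        ll = float(log_mix.sum())
        history.append(ll)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        gamma = np.exp(log_comp - log_mix[None, :])  # responsibilities (K, n_obs)
        weight = gamma.sum(axis=1)
        weight = np.maximum(weight, 1e-12)
        theta = (gamma @ x) / (gamma @ n)
        pi = weight / weight.sum()
        order = np.argsort(-theta, kind="stable")
        theta = theta[order]
        pi = pi[order]
        theta = np.minimum(np.maximum(theta, 0.0), 0.5)

    ll = float(logsumexp(np.log(pi)[:, None] + _binom_logpmf_matrix(x, n, theta), axis=0).sum())
    p_free = 2 * K - 1
    bic = -2.0 * ll + p_free * np.log(x.size)
    purity = min(1.0, 2.0 * float(theta[0]))
    if purity < 0.05:
        log.warning("purity estimate %.3f is near zero (low-purity or degenerate data)", purity)
    return PurityFit(
        K=K, theta=theta, pi=pi, loglik=ll, bic=float(bic), purity=purity,
        n_variants=int(x.size), converged=converged, n_iter=it,
        loglik_history=np.asarray(history),
    )


def fit_mixture(
    alt_counts,
    depths,
    K: int,
    n_starts: int = 10,
    jitter: float = 0.03,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PurityFit:
    """Multi-start EM: quantile init plus jittered restarts, best log-lik kept.

    Restart jitter depends only on the restart index (not on data order), so
    the fit is exchangeable in the input variants.
    """
    x = np.asarray(alt_counts, dtype=float)
    n = np.asarray(depths, dtype=float)
    best = em_fit(x, n, K, tol=tol, max_iter=max_iter)
    if K == 1:
        return best
    qs = (2 * np.arange(K, 0, -1) - 1) / (2 * K)
    base_theta = np.minimum(np.maximum(np.quantile(x / n, qs), _THETA_FLOOR), 0.5)
    for s in range(1, n_starts):
        rng = np.random.default_rng(1_000_003 + s)
        theta0 = np.sort(base_theta + rng.normal(0.0, jitter, K))[::-1]
        pi0 = rng.dirichlet(np.full(K, 5.0))
        fit = em_fit(x, n, K, init=(theta0, pi0), tol=tol, max_iter=max_iter)
        if fit.loglik > best.loglik:
            best = fit
    return best


def select_K(alt_counts, depths, K_max: int = 4, n_starts: int = 10) -> PurityFit:
    """Fit K = 1..K_max and return the BIC-optimal mixture.

    K_max is truncated so the parameter count 2K-1 stays below the number of
    variants; BIC ties break toward the smaller K (parsimony).
    """
    x = np.asarray(alt_counts, dtype=float)
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    k_cap = max(1, min(K_max, x.size // 2))  # keeps p = 2K-1 < n_variants
    if k_cap < K_max:
        log.warning("K_max truncated from %d to %d (only %d variants)", K_max, k_cap, x.size)
    best: PurityFit | None = None
    for K in range(1, k_cap + 1):
        fit = fit_mixture(x, depths, K, n_starts=n_starts)
        if best is None or fit.bic < best.bic:  # strict: ties keep smaller K
            best = fit
    assert best is not None
    return best


def estimate_purity(
    variants: list[VariantRecord],
    profile: CNProfile,
    K_max: int = 4,
    min_variants: int = 20,
    n_starts: int = 10,
) -> PurityCall:
    """Purity for one sample: neutral-SNV selection, BIC-selected mixture, 2*theta1."""
    neutral = select_neutral_variants(variants, profile)
    if len(neutral) < min_variants:
        return PurityCall(
            sample_id=profile.sample_id, purity=None, fit=None,
            n_neutral=len(neutral), status="no-call",
            reason=f"only {len(neutral)} copy-neutral SNVs (< {min_variants})",
        )
    alt = np.array([v.t_alt for v in neutral], dtype=float)
    dep = np.array([v.t_depth for v in neutral], dtype=float)
    fit = select_K(alt, dep, K_max=K_max, n_starts=n_starts)
    return PurityCall(
        sample_id=profile.sample_id, purity=fit.purity, fit=fit,
        n_neutral=len(neutral), status="ok",
    )
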