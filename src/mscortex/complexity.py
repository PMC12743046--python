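"""Gaussian information-theoretic complexity measures.

For a stationary multivariate Gaussian signal with covariance matrix
``Sigma`` over d channels, the differential entropy is

    H = 0.5 ln[(2 pi e)^d |Sigma|]    (nats),

and the *integration* is the total deviation from independence,

    I = sum_i H_i - H = 0.5 (sum_i ln var_i - ln|Sigma|) >= 0.

*Neural complexity* compares the integration of the whole system with the
expected integration of its subsystems,

    C = sum_{k=1}^{d-1} [(k/d) I - <I>_k]
      = sum_{k=1}^{d-1} 0.5 (<ln|Sigma_S|>_{|S|=k} - (k/d) ln|Sigma|),

where <.>_k averages over all C(d, k) principal submatrices.  C is high
when the system is simultaneously integrated (high I) and differentiated
(subsystems less integrated than a linear share would predict).  Exact
evaluation enumerates 2^d subsets and is capped at d <= 20.

*Structural complexity* is a second-order weak-coupling approximation that
needs only the connection matrix W (not the dynamics):

    C^s = C* + C**,
    C*  = ((d+1)/48) sum_{i != j} (W_ij^2 + W_ij W_ji),
    C** = ((d+1)/96) sum_{i != j != k} (3 W_ij W_jk W_ik + W_ij W_jk W_ki)
        + ((d+1)/24) sum_{i != j} W_ii (W_ij^2 + W_ij W_ji),

valid when the coupled system behaves like a multivariate
Ornstein–Uhlenbeck (OU) process dx = (W - I) x dt + s dB with weak
off-diagonal coupling; :func:`ou_stationary_covariance` provides the
corresponding stationary covariance (the verification oracle for the
approximation).

*Dynamical complexity* applies exact neural complexity to the covariance
of the z region-averaged voltage series, enumerating subsets of regions
(2^z, not 2^(z*m)), which keeps the computation feasible for multi-scale
networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import scipy.linalg

from .neurodyn import RegionalTraces

__all__ = [
    "ComplexityResult",
    "check_covariance",
    "to_correlation",
    "gaussian_entropy",
    "integration_gaussian",
    "neural_complexity_exact",
    "neural_complexity_from_integrations",
    "structural_complexity",
    "ou_stationary_covariance",
    "dynamical_complexity",
]

_LOG_2PIE = math.log(2.0 * math.pi * math.e)


@dataclass(frozen=True)
class ComplexityResult:
    """A complexity value (nats) with its per-component breakdown.

    ``components`` holds per-subset-size terms for the exact and dynamical
    kinds, or the (C*, C**) pair for the structural kind; ``d`` is the
    system size entering the (d+1) prefactors / subset enumeration.
    """

    value: float
    kind: str  # "exact_gaussian" | "structural" | "dynamical"
    components: dict
    d: int


def check_covariance(cov: np.ndarray, *, sym_tol: float = 1e-10) -> np.ndarray:
    """Validate a symmetric positive-definite covariance matrix.

    Raises ``ValueError`` naming the offending eigenvalue when the matrix
    is not positive definite.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square; got shape {cov.shape}")
    scale = max(1.0, float(np.abs(cov).max()))
    if np.abs(cov - cov.T).max() > sym_tol * scale:
        raise ValueError("covariance matrix is not symmetric")
    eigmin = float(np.linalg.eigvalsh(cov)[0])
    if eigmin <= 0.0:
        raise ValueError(
            f"covariance is not positive definite: smallest eigenvalue {eigmin:.3e}"
        )
    return cov


def to_correlation(cov: np.ndarray) -> np.ndarray:
    """Channel-standardize a covariance matrix to unit variances."""
    cov = np.asarray(cov, dtype=float)
    s = 1.0 / np.sqrt(np.diag(cov))
    return cov * np.outer(s, s)


def gaussian_entropy(cov: np.ndarray) -> float:
    """Differential entropy 0.5 ln[(2 pi e)^d |cov|] in nats."""
    cov = check_covariance(cov)
    d = cov.shape[0]
    sign, logdet = np.linalg.slogdet(cov)
    return 0.5 * (d * _LOG_2PIE + logdet)


def integration_gaussian(cov: np.ndarray) -> float:
    """Integration I = sum_i H_i - H = 0.5 (sum_i ln var_i - ln|cov|); >= 0."""
    cov = check_covariance(cov)
    _, logdet = np.linalg.slogdet(cov)
    return 0.5 * (float(np.sum(np.log(np.diag(cov)))) - logdet)


def _mean_subset_logdets(cov: np.ndarray) -> np.ndarray:
    """<ln|cov_S|>_{|S|=k} for k = 1..d, by enumeration of principal submatrices."""
    d = cov.shape[0]
    out = np.empty(d)
    out[0] = float(np.mean(np.log(np.diag(cov))))
    for k in range(2, d):
        total = 0.0
        for idx in combinations(range(d), k):
            sub = cov[np.ix_(idx, idx)]
            _, logdet = np.linalg.slogdet(sub)
            total += logdet
        out[k - 1] = total / math.comb(d, k)
    _, logdet = np.linalg.slogdet(cov)
    out[d - 1] = logdet
    return out


def neural_complexity_exact(cov: np.ndarray, *, max_dim: int = 20) -> ComplexityResult:
    """Exact Gaussian neural complexity by subset enumeration (d <= max_dim)."""
    cov = check_covariance(cov)
    d = cov.shape[0]
    if d > max_dim:
        raise ValueError(
            f"subset enumeration is capped at d={max_dim} (got d={d}); use "
            "dynamical_complexity on region averages or structural_complexity "
            "on the connection matrix instead"
        )
    mean_logdets = _mean_subset_logdets(cov)
    logdet = mean_logdets[d - 1]
    per_k = {
        k: 0.5 * (mean_logdets[k - 1] - (k / d) * logdet) for k in range(1, d)
    }
    return ComplexityResult(
        value=float(sum(per_k.values())),
        kind="exact_gaussian",
        components=per_k,
        d=d,
    )


def neural_complexity_from_integrations(cov: np.ndarray) -> ComplexityResult:
    """Neural complexity via sum_k [(k/d) I - <I>_k]; the alternate formula.

    Algebraically identical to :func:`neural_complexity_exact`; kept as a
    separate code path (entropies and integrations computed per subset) so
    the two forms can be cross-checked.
    """
    cov = check_covariance(cov)
    d = cov.shape[0]
    if d > 20:
        raise ValueError("subset enumeration is capped at d=20")
    I_full = integration_gaussian(cov)
    H_single = 0.5 * (_LOG_2PIE + np.log(np.diag(cov)))
    per_k = {}
    for k in range(1, d):
        total_I = 0.0
        count = 0
        for idx in combinations(range(d), k):
            sub = cov[np.ix_(idx, idx)]
            _, logdet = np.linalg.slogdet(sub)
            H_sub = 0.5 * (k * _LOG_2PIE + logdet)
            total_I += float(np.sum(H_single[list(idx)])) - H_sub
            count += 1
        per_k[k] = (k / d) * I_full - total_I / count
    return ComplexityResult(
        value=float(sum(per_k.values())),
        kind="exact_gaussian",
        components=per_k,
        d=d,
    )


def structural_complexity(W: np.ndarray) -> ComplexityResult:
    """Second-order structural complexity C* + C** of a weighted matrix.

    Implemented with matrix-product identities; sums run over distinct
    indices (the zero-diagonal copy of W makes coincident-index terms
    vanish, and the i = k terms of the triple products carry a zeroed
    diagonal factor).  The diagonal of W itself enters only the C** term
    weighted by W_ii.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"connection matrix must be square; got shape {W.shape}")
    if not np.all(np.isfinite(W)):
        raise ValueError("connection matrix must have finite entries")
    d = W.shape[0]
    diag = np.diag(W).copy()
    W0 = W - np.diag(diag)

    sq = W0 * W0  # W_ij^2, i != j
    recip = W0 * W0.T  # W_ij W_ji, i != j
    c_star = (d + 1) / 48.0 * float(np.sum(sq + recip))

    W0sq = W0 @ W0
    # sum over distinct i, j, k of W_ij W_jk W_ik: i = k terms vanish
    # because W0 has zero diagonal inside the product chain.
    feedforward = float(np.sum(W0sq * W0))
    cycle = float(np.trace(W0sq @ W0))
    self_term = float(np.sum(diag * np.sum(sq + recip, axis=1)))
    c_star_star = (d + 1) / 96.0 * (3.0 * feedforward + cycle) + (
        d + 1
    ) / 24.0 * self_term

    return ComplexityResult(
        value=c_star + c_star_star,
        kind="structural",
        components={"c_star": c_star, "c_star_star": c_star_star},
        d=d,
    )


def ou_stationary_covariance(W: np.ndarray, noise_scale: float = 1.0) -> np.ndarray:
    """Stationary covariance of the OU process dx = (W - I) x dt + s dB.

    Solves the continuous Lyapunov equation
    (W - I) Sigma + Sigma (W - I)^T + s^2 I = 0.  Requires the drift
    matrix W - I to be stable (all eigenvalue real parts negative).
    """
    W = np.asarray(W, dtype=float)
    d = W.shape[0]
    drift = W - np.eye(d)
    abscissa = float(np.max(np.linalg.eigvals(drift).real))
    if abscissa >= 0.0:
        raise ValueError(
            f"OU drift W - I is unstable: spectral abscissa {abscissa:.3e} >= 0"
        )
    sigma = scipy.linalg.solve_continuous_lyapunov(
        drift, -(noise_scale**2) * np.eye(d)
    )
    return 0.5 * (sigma + sigma.T)


def dynamical_complexity(
    traces: RegionalTraces | np.ndarray,
    *,
    max_dim: int = 20,
    ridge: bool = False,
) -> ComplexityResult:
    """Coarse-grained complexity of region-averaged voltage dynamics.

    Estimates the z x z sample covariance (denominator N - 1) of the
    regional mean-voltage series and applies exact Gaussian neural
    complexity over subsets of *regions*.  ``ridge=True`` adds a tiny
    diagonal regularizer (1e-10 * trace/z) before the computation, for
    degenerate inputs such as identical traces; off by default.
    """
    X = traces.L if isinstance(traces, RegionalTraces) else np.asarray(traces, float)
    if X.ndim != 2:
        raise ValueError("traces must be a (samples, regions) array")
    n_samples, z = X.shape
    if z > max_dim:
        raise ValueError(f"subset enumeration is capped at d={max_dim} regions")
    if n_samples < 10 * z:
        raise ValueError(
            f"need at least 10*z = {10 * z} time samples for a usable covariance; "
            f"got {n_samples}"
        )
    cov = np.cov(X, rowvar=False, ddof=1)
    if ridge:
        cov = cov + (1e-10 * np.trace(cov) / z) * np.eye(z)
    try:
        res = neural_complexity_exact(cov, max_dim=max_dim)
    except ValueError as err:
        raise ValueError(
            f"regional covariance is unusable ({err}); identical or collinear "
            "traces can be handled with ridge=True"
        ) from err
    return ComplexityResult(
        value=res.value, kind="dynamical", components=res.components, d=z
    )
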