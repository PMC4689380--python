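"""Per-gene EM for isoform proportions, with and without a Dirichlet prior.

The base model treats the reads aligned to one gene as i.i.d. draws from a
mixture over the gene's isoforms: read j has marginal probability
sum_k p_k q_jk, where p is the unknown categorical parameter and q_jk the
per-base sampling probability of the read from isoform k.  The "uncommitted"
log-likelihood over equivalence classes is

    ll(p) = sum_e c_e * log(sum_k p_k q_ek).

EM alternates soft read assignments a_ek = p_k q_ek / sum_k' p_k' q_ek'
(E-step) with p_k proportional to the expected assigned read count (M-step).
With a Dirichlet prior with parameters alpha_k = lam * phi_k + 1 the M-step
becomes

    p_k = (lam * phi_k + sum_e c_e a_ek) / sum_k (lam * phi_k + sum_e c_e a_ek),

i.e. the prior acts as phi_k pseudo-reads weighted by lam.  The base model
is the lam = 0 special case.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from .compat import GeneCompat

__all__ = [
    "gene_log_likelihood",
    "base_em_fit",
    "em_with_prior",
    "gene_posterior_loglik",
    "relative_abundance",
    "transcript_expression",
]

#: floor used inside logarithms only; stored proportions may be exactly 0
LOG_FLOOR = 1e-12


def _check_simplex(p: np.ndarray, k: int) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (k,):
        raise ValueError(f"expected proportion vector of length {k}, got {p.shape}")
    return p


def gene_log_likelihood(p: np.ndarray, compat: GeneCompat) -> float:
    """Uncommitted log-likelihood of one gene's classes under proportions p.

    A class whose mixture probability sum_k p_k q_ek is zero contributes
    -inf (the data are impossible under p).
    """
    k = compat.q.shape[1] if compat.q.size else len(np.atleast_1d(p))
    p = _check_simplex(p, k)
    if compat.n_classes == 0:
        return 0.0
    mix = compat.q @ p
    if np.any(mix <= 0):
        return -np.inf
    return float(compat.counts @ np.log(mix))


def _em_core(
    compat: GeneCompat,
    prior: np.ndarray,
    p0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int]:
    """Shared EM loop: ``prior`` is the vector of lam*phi pseudo-counts."""
    p = p0.copy()
    counts, q = compat.counts, compat.q
    total_prior = prior.sum()
    if compat.n_classes == 0:
        # no reads: the posterior mode is the normalized prior (uniform if flat)
        if total_prior > 0:
            return prior / total_prior, 0
        return np.full_like(p, 1.0 / p.size), 0
    for it in range(1, max_iter + 1):
        mix = q @ p
        mix = np.maximum(mix, 1e-300)
        # expected assigned reads per transcript: sum_e c_e a_ek
        assigned = p * (q.T @ (counts / mix))
        new = prior + assigned
        new /= new.sum()
        delta = np.max(np.abs(new - p))
        p = new
        if delta < tol:
            break
    return p, it


def _initial(init, k: int, rng: np.random.Generator | None) -> np.ndarray:
    if isinstance(init, np.ndarray) or isinstance(init, (list, tuple)):
        p0 = np.asarray(init, dtype=np.float64)
        if p0.shape != (k,) or np.any(p0 < 0) or not np.isclose(p0.sum(), 1.0):
            raise ValueError("explicit init must be a length-K simplex vector")
        return p0
    if init == "uniform":
        return np.full(k, 1.0 / k)
    if init == "random":
        if rng is None:
            raise ValueError("random init requires a seeded Generator")
        return rng.dirichlet(np.ones(k))
    raise ValueError(f"unknown init {init!r}")


def base_em_fit(
    compat: GeneCompat,
    init="uniform",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Maximum-likelihood isoform proportions of one gene by EM."""
    k = compat.q.shape[1]
    rng = np.random.default_rng(seed) if seed is not None else None
    p0 = _initial(init, k, rng)
    p, _ = _em_core(compat, np.zeros(k), p0, tol, max_iter)
    return p


def em_with_prior(
    compat: GeneCompat,
    lam_phi: np.ndarray,
    init="uniform",
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Posterior-mode proportions under Dirichlet pseudo-counts lam*phi."""
    k = compat.q.shape[1] if compat.q.size else len(np.atleast_1d(lam_phi))
    lam_phi = np.asarray(lam_phi, dtype=np.float64)
    if lam_phi.shape != (k,):
        raise ValueError("lam_phi shape disagrees with gene transcript count")
    if np.any(lam_phi < 0):
        raise ValueError("prior pseudo-counts must be non-negative")
    rng = np.random.default_rng(seed) if seed is not None else None
    p0 = _initial(init, k, rng)
    p, _ = _em_core(compat, lam_phi, p0, tol, max_iter)
    return p


def log_dirichlet_normalizer(alpha: np.ndarray) -> float:
    """log C(alpha) = logGamma(sum alpha) - sum logGamma(alpha)."""
    return float(gammaln(alpha.sum()) - gammaln(alpha).sum())


def gene_posterior_loglik(
    p: np.ndarray, alpha: np.ndarray, compat: GeneCompat
) -> float:
    """Log of the per-gene objective: Dirichlet prior density times the
    uncommitted read likelihood.

    ``alpha`` must satisfy alpha >= 1, which always holds for
    alpha = lam * phi + 1 with lam, phi >= 0.
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    p = _check_simplex(p, alpha.size)
    if np.any(alpha < 1):
        raise ValueError("Dirichlet parameters must be >= 1")
    logp = np.log(np.maximum(p, LOG_FLOOR))
    return (
        log_dirichlet_normalizer(alpha)
        + float((alpha - 1) @ logp)
        + gene_log_likelihood(p, compat)
    )


def relative_abundance(p: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Molar (per-molecule) isoform proportions: rho_k ∝ p_k / l_k."""
    p = np.asarray(p, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    if np.any(lengths <= 0):
        raise ValueError("lengths must be positive")
    w = p / lengths
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero proportion vector")
    return w / total


def transcript_expression(
    p: np.ndarray, read_count: float, lengths: np.ndarray
) -> np.ndarray:
    """Reads-per-base expression: pi_k = |r_i| * p_k / l_k."""
    if read_count < 0:
        raise ValueError("read_count must be non-negative")
    p = np.asarray(p, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    return read_count * p / lengths
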