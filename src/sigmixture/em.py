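"""Low-level likelihoods and EM machinery for multinomial mixture models.

All functions here operate on plain numpy arrays; the catalog/parameter object
interfaces live in :mod:`sigmixture.model`.

The single-sample building block is a multinomial mixture: K signatures, each a
probability distribution ``e_i`` over M mutation categories, mixed by relative
exposures ``pi``. The per-sample likelihood is

    f(V, pi, e) = prod_j (sum_i pi_i e_i(j)) ** V_j

The full model places samples into L latent clusters with priors ``w``; each
cluster l has its own exposure vector ``pi^l`` while signatures are shared, so
the data likelihood is ``prod_n sum_l w_l f(V^n, pi^l, e)``. EM alternates a
responsibility/expectation step with closed-form normalisation updates.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

# Floor applied to strictly positive mixture probabilities before taking logs;
# exact structural zeros are preserved (they yield -inf only when the count is
# positive).
PROB_FLOOR = 1e-300


def _check_count_vector(V: np.ndarray) -> np.ndarray:
    V = np.asarray(V)
    if V.ndim != 1:
        raise ValueError("V must be a 1-D count vector")
    if np.any(V < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(V.dtype, np.integer) and not np.all(np.mod(V, 1) == 0):
        raise ValueError("counts must be integers")
    return V.astype(float)


def _check_mixture(pi: np.ndarray, e: np.ndarray, M: int) -> tuple[np.ndarray, np.ndarray]:
    pi = np.asarray(pi, dtype=float)
    e = np.asarray(e, dtype=float)
    if pi.ndim != 1 or e.ndim != 2:
        raise ValueError("pi must be 1-D and e 2-D")
    if e.shape != (pi.shape[0], M):
        raise ValueError(
            f"dimension mismatch: pi has {pi.shape[0]} signatures, "
            f"e is {e.shape}, expected ({pi.shape[0]}, {M})"
        )
    return pi, e


def mmm_log_likelihood(V, pi, e) -> float:
    """Log-likelihood ``log f(V, pi, e)`` of one sample under a multinomial mixture.

    Returns ``-inf`` exactly when some category with a positive count has zero
    mixture probability. An all-zero count vector gives 0 (empty product).
    """
    V = _check_count_vector(V)
    pi, e = _check_mixture(pi, e, V.shape[0])
    q = pi @ e
    pos = q > 0
    if np.any((V > 0) & ~pos):
        return float("-inf")
    logq = np.where(pos, np.log(np.maximum(q, PROB_FLOOR)), 0.0)
    return float(V @ logq)


def mmm_expectations(V, pi, e) -> tuple[np.ndarray, np.ndarray]:
    """E-step expectations for one sample under a multinomial mixture.

    Returns ``(E, A)`` where ``E[i, j]`` is the expected number of mutations of
    category j emitted by signature i, ``E_i(j) = V_j pi_i e_i(j) / sum_k pi_k
    e_k(j)``, and ``A[i] = sum_j E[i, j]`` is the expected number of times
    signature i was used.
    """
    V = _check_count_vector(V)
    pi, e = _check_mixture(pi, e, V.shape[0])
    q = pi @ e
    bad = (V > 0) & (q <= 0)
    if np.any(bad):
        j = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"category {j} has count {int(V[j])} but zero mixture probability"
        )
    ratio = np.divide(V, q, out=np.zeros_like(V, dtype=float), where=q > 0)
    E = (pi[:, None] * e) * ratio[None, :]
    return E, E.sum(axis=1)


def log_joint_matrix(counts: np.ndarray, w: np.ndarray, pi: np.ndarray, e: np.ndarray) -> np.ndarray:
    """(N, L) matrix of ``log w_l + log f(V^n, pi^l, e)``.

    Vectorised over samples and clusters; entries are ``-inf`` where a cluster
    assigns zero probability to an observed category (or has zero prior).
    ``counts`` may be a scipy CSR matrix (sparse panel catalogs).
    """
    if not sp.issparse(counts):
        counts = np.asarray(counts, dtype=float)
    q = pi @ e  # (L, M) per-cluster category probabilities
    pos = q > 0
    logq = np.where(pos, np.log(np.maximum(q, PROB_FLOOR)), 0.0)
    S = counts @ logq.T  # (N, L)
    if not pos.all():
        # a zero-probability category only matters where it actually has
        # counts; categories unobserved in the catalog (the usual reason for
        # an exact zero after an M-step) can be skipped outright
        col_totals = np.asarray(counts.sum(axis=0)).ravel()
        relevant = (~pos) & (col_totals > 0)[None, :]
        if relevant.any():
            dense = counts.toarray() if sp.issparse(counts) else counts
            impossible = (dense > 0) @ relevant.T.astype(float)
            S = np.where(impossible > 0, -np.inf, S)
    with np.errstate(divide="ignore"):
        return S + np.log(w)


def mix_log_likelihood_counts(counts, w, pi, e, sample_weights=None) -> float:
    """Total log-likelihood ``sum_n log sum_l w_l f(V^n, pi^l, e)``."""
    logJ = log_joint_matrix(counts, w, pi, e)
    ll = logsumexp(logJ, axis=1)
    if sample_weights is not None:
        return float(sample_weights @ ll)
    return float(ll.sum())


def mix_responsibilities_counts(counts, w, pi, e) -> np.ndarray:
    """(N, L) posterior cluster probabilities ``f^{n,l}``.

    A sample with zero mutations has likelihood 1 under every cluster and so
    gets posterior equal to the prior ``w``.
    """
    logJ = log_joint_matrix(counts, w, pi, e)
    ll = logsumexp(logJ, axis=1)
    dead = ~np.isfinite(ll)
    if np.any(dead):
        n = int(np.flatnonzero(dead)[0])
        raise ValueError(f"sample {n} has zero likelihood under every cluster")
    return np.exp(logJ - ll[:, None])


def e_step(counts, w, pi, e, sample_weights=None):
    """Pooled E-step over a catalog.

    Returns ``(F, E, A, W, loglik)``: responsibilities (N, L); pooled expected
    emissions E (K, M); per-cluster expected signature usage A (L, K); expected
    cluster occupancy W (L,); and the total log-likelihood of the *current*
    parameters. ``sample_weights`` lets identical count rows be collapsed with
    multiplicities — the statistics are mathematically unchanged.
    """
    if not sp.issparse(counts):
        counts = np.asarray(counts, dtype=float)
    logJ = log_joint_matrix(counts, w, pi, e)
    # manual log-sum-exp: cheaper than the scipy generic on (N, L)
    m = logJ.max(axis=1)
    with np.errstate(invalid="ignore"):
        F = np.exp(logJ - m[:, None])
    norm = F.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = m + np.log(norm)
    dead = ~np.isfinite(ll)
    if np.any(dead):
        n = int(np.flatnonzero(dead)[0])
        raise ValueError(f"sample {n} has zero likelihood under every cluster")
    F /= norm[:, None]
    if sample_weights is None:
        Fw = F
        total_ll = float(ll.sum())
    else:
        Fw = F * np.asarray(sample_weights, dtype=float)[:, None]
        total_ll = float(np.asarray(sample_weights, dtype=float) @ ll)

    q = pi @ e  # (L, M)
    # responsibility-weighted category counts (L, M)
    B = (counts.T @ Fw).T if sp.issparse(counts) else Fw.T @ counts
    B = np.asarray(B)
    Bq = np.divide(B, q, out=np.zeros_like(B), where=q > 0)
    E = e * (pi.T @ Bq)  # (K, M)
    A = pi * (Bq @ e.T)  # (L, K)
    W = Fw.sum(axis=0)  # (L,)
    return F, E, A, W, total_ll


def m_step(E, A, W, pi_old, e_old, refit: bool = False):
    """Normalise pooled expectations into new parameters.

    A cluster or signature whose pooled expectation is entirely zero keeps its
    previous parameters (with a warning) rather than dividing 0/0. In refit
    mode the signature matrix is returned untouched (the same object).
    """
    w_new = W / W.sum()

    A_sums = A.sum(axis=1)
    pi_new = np.array(pi_old, dtype=float, copy=True)
    ok = A_sums > 0
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} cluster(s) with zero expected occupancy kept "
            "their previous exposures",
            RuntimeWarning,
            stacklevel=2,
        )
    pi_new[ok] = A[ok] / A_sums[ok, None]

    if refit:
        return w_new, pi_new, e_old

    E_sums = E.sum(axis=1)
    e_new = np.array(e_old, dtype=float, copy=True)
    ok_e = E_sums > 0
    if not ok_e.all():
        warnings.warn(
            f"{int((~ok_e).sum())} signature(s) with zero expected emissions "
            "kept their previous distribution",
            RuntimeWarning,
            stacklevel=2,
        )
    e_new[ok_e] = E[ok_e] / E_sums[ok_e, None]
    return w_new, pi_new, e_new


def run_em(
    counts: np.ndarray,
    w: np.ndarray,
    pi: np.ndarray,
    e: np.ndarray,
    *,
    refit: bool = False,
    max_iter: int = 1000,
    tol: float = 1e-6,
    rel_tol: float = 1e-8,
    sample_weights: np.ndarray | None = None,
):
    """Run EM from an initial state until convergence or the iteration cap.

    Stops when the absolute log-likelihood improvement drops below ``tol`` or
    the relative improvement below ``rel_tol``. Returns
    ``(w, pi, e, trajectory, n_iter, converged)`` where ``trajectory`` is the
    log-likelihood evaluated at each visited parameter state (non-decreasing up
    to numerical slack) and ``n_iter`` counts applied parameter updates.
    """
    trajectory: list[float] = []
    n_iter = 0
    converged = False
    while n_iter < max_iter:
        _, E, A, W, ll = e_step(counts, w, pi, e, sample_weights=sample_weights)
        trajectory.append(ll)
        if len(trajectory) > 1:
            gain = trajectory[-1] - trajectory[-2]
            if abs(gain) < tol or abs(gain) < rel_tol * abs(ll):
                converged = True
                break
        w, pi, e = m_step(E, A, W, pi, e, refit=refit)
        n_iter += 1
    if not converged:
        trajectory.append(
            mix_log_likelihood_counts(counts, w, pi, e, sample_weights=sample_weights)
        )
    return w, pi, e, np.asarray(trajectory), n_iter, converged
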