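"""The clustered multinomial mixture model and its trainer.

The model soft-clusters N tumor samples into L latent clusters and explains
each sample's mutation counts as a multinomial mixture of K shared signatures,
with exposures tied per cluster rather than per sample. Tying exposures keeps
the parameter count independent of N, which is what makes the model usable on
sparse targeted-panel catalogs where samples carry only a handful of mutations.

Two entry points are provided: a scikit-learn-style estimator
(:class:`SignatureMixture`) and a functional trainer (:func:`fit_mix`). The
estimator composes with sklearn model selection and pipelines; the functions
are thin wrappers over the same EM core in :mod:`sigmixture.em`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import em
from .catalog import MutationCatalog, as_counts

_SUM_TOL = 1e-9


def _check_prob_vector(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    if abs(x.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} must sum to 1 (got {x.sum()!r})")
    return x


def _check_prob_rows(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if np.any(x < 0):
        raise ValueError(f"{name} must be non-negative")
    sums = x.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _SUM_TOL):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise ValueError(f"row {bad} of {name} must sum to 1 (got {sums[bad]!r})")
    return x


@dataclass
class MixParameters:
    """Full model state: cluster priors, per-cluster exposures, signatures.

    Attributes
    ----------
    w : (L,) cluster prior probabilities.
    pi : (L, K) rows are per-cluster relative signature exposures.
    e : (K, M) rows are signatures (distributions over mutation categories).
    refit_mode : True when ``e`` is externally fixed and never updated.
    """

    w: np.ndarray
    pi: np.ndarray
    e: np.ndarray
    refit_mode: bool = False

    def __post_init__(self) -> None:
        self.w = _check_prob_vector(self.w, "w")
        self.pi = _check_prob_rows(self.pi, "pi")
        self.e = _check_prob_rows(self.e, "e")
        if self.pi.shape[0] != self.w.shape[0]:
            raise ValueError("pi must have one row per cluster")
        if self.pi.shape[1] != self.e.shape[0]:
            raise ValueError("pi columns must match signature rows")

    @property
    def n_clusters(self) -> int:
        return self.w.shape[0]

    @property
    def n_signatures(self) -> int:
        return self.e.shape[0]

    @property
    def n_categories(self) -> int:
        return self.e.shape[1]

    def to_dict(self, category_labels=None, meta=None) -> dict:
        out = {
            "w": self.w.tolist(),
            "pi": self.pi.tolist(),
            "e": self.e.tolist(),
            "category_labels": list(category_labels) if category_labels is not None else None,
            "refit_mode": bool(self.refit_mode),
            "meta": dict(meta) if meta else {},
        }
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "MixParameters":
        return cls(
            w=np.asarray(d["w"], dtype=float),
            pi=np.asarray(d["pi"], dtype=float),
            e=np.asarray(d["e"], dtype=float),
            refit_mode=bool(d.get("refit_mode", False)),
        )


@dataclass
class SufficientStats:
    """Pooled E-step expectations.

    ``E`` (K, M): expected emissions per signature and category; ``A`` (L, K):
    expected signature usage per cluster; ``W`` (L,): expected cluster
    occupancy. ``W`` sums to N and ``A`` and ``E`` both sum to the total
    mutation count.
    """

    E: np.ndarray
    A: np.ndarray
    W: np.ndarray


@dataclass
class FitResult:
    """Outcome of one training run (the best of the random restarts)."""

    params: MixParameters
    log_likelihood: float
    n_iterations: int
    converged: bool
    seed: int
    restart_index: int
    trajectory: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def mix_log_likelihood(catalog, params: MixParameters) -> float:
    """Total log-likelihood ``sum_n log sum_l w_l f(V^n, pi^l, e)``."""
    return em.mix_log_likelihood_counts(as_counts(catalog), params.w, params.pi, params.e)


def mix_responsibilities(catalog, params: MixParameters) -> np.ndarray:
    """(N, L) posterior cluster probabilities; rows sum to 1."""
    return em.mix_responsibilities_counts(as_counts(catalog), params.w, params.pi, params.e)


def mix_em_step(catalog, params: MixParameters):
    """One EM update.

    Returns ``(new_params, stats, log_likelihood_before)`` where the
    log-likelihood is that of the *input* parameters; applying the update can
    only increase it.
    """
    counts = as_counts(catalog)
    _, E, A, W, ll = em.e_step(counts, params.w, params.pi, params.e)
    w, pi, e = em.m_step(E, A, W, params.pi, params.e, refit=params.refit_mode)
    new = MixParameters(w=w, pi=pi, e=e, refit_mode=params.refit_mode)
    return new, SufficientStats(E=E, A=A, W=W), ll


def _init_params(rng: np.random.Generator, L: int, K: int, M: int,
                 fixed_signatures: np.ndarray | None):
    """Symmetric-Dirichlet(1) initialisation; signatures skipped in refit mode."""
    w = rng.dirichlet(np.ones(L))
    pi = rng.dirichlet(np.ones(K), size=L)
    if fixed_signatures is not None:
        e = fixed_signatures
    else:
        e = rng.dirichlet(np.ones(M), size=K)
    return w, pi, e


def fit_mix(
    catalog,
    L: int,
    K: int | None = None,
    *,
    fixed_signatures=None,
    n_restarts: int = 10,
    max_iterations: int = 1000,
    tolerance: float = 1e-6,
    rel_tolerance: float = 1e-8,
    seed: int = 0,
) -> FitResult:
    """Train the model by multi-restart EM and keep the best restart.

    Each restart r draws its initial parameters from a generator seeded with
    ``seed + r`` and is run up to ``max_iterations`` EM updates; the restart
    with the highest final log-likelihood wins. Passing ``fixed_signatures``
    switches to refitting mode: ``e`` is set to the given matrix and never
    updated. The result is bit-reproducible for a fixed seed.
    """
    counts = as_counts(catalog)
    N, M = counts.shape
    if N == 0:
        raise ValueError("cannot fit an empty catalog")
    if L < 1:
        raise ValueError("L must be >= 1")
    if fixed_signatures is not None:
        fixed_signatures = _check_prob_rows(np.asarray(fixed_signatures, float), "fixed_signatures")
        if fixed_signatures.shape[1] != M:
            raise ValueError("fixed_signatures categories do not match the catalog")
        if K is None:
            K = fixed_signatures.shape[0]
        elif K != fixed_signatures.shape[0]:
            raise ValueError("K must equal the number of fixed signatures")
    if K is None or K < 1:
        raise ValueError("K must be >= 1")
    if K > M:
        warnings.warn(
            f"K={K} exceeds the number of categories M={M}; the model is "
            "over-parameterized",
            UserWarning,
            stacklevel=2,
        )

    # Collapse duplicate count rows into weighted unique rows; with sparse
    # panel-like data this shrinks N substantially without changing any
    # statistic of the fit.
    uniq, mult = np.unique(counts, axis=0, return_counts=True)
    weights = mult.astype(float)
    # sparse panel catalogs: CSR cuts the per-iteration matmul cost roughly
    # by the fill fraction
    train: np.ndarray | "sparse.csr_array" = uniq.astype(float)
    if M >= 32 and np.count_nonzero(uniq) < 0.25 * uniq.size:
        from scipy import sparse

        train = sparse.csr_array(train)

    best: FitResult | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        w0, pi0, e0 = _init_params(rng, L, K, M, fixed_signatures)
        w, pi, e, traj, n_iter, converged = em.run_em(
            train, w0, pi0, e0,
            refit=fixed_signatures is not None,
            max_iter=max_iterations,
            tol=tolerance,
            rel_tol=rel_tolerance,
            sample_weights=weights,
        )
        result = FitResult(
            params=MixParameters(w=w, pi=pi, e=e, refit_mode=fixed_signatures is not None),
            log_likelihood=float(traj[-1]),
            n_iterations=n_iter,
            converged=converged,
            seed=seed + r,
            restart_index=r,
            trajectory=traj,
        )
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# scikit-learn estimator
# ---------------------------------------------------------------------------

class SignatureMixture(BaseEstimator):
    """Joint soft-clustering and signature learning for sparse mutation catalogs.

    A mixture of multinomial mixture models: samples belong to one of
    ``n_clusters`` latent clusters with prior probabilities ``weights_``; a
    cluster l emits mutations from ``n_signatures`` shared signatures
    ``signatures_`` mixed by the cluster's exposure vector ``exposures_[l]``.
    Trained by multi-restart EM; hyperparameters are typically chosen by BIC
    (see :mod:`sigmixture.selection`).

    Parameters
    ----------
    n_clusters : int, default=1
        Number of latent sample clusters L.
    n_signatures : int, default=1
        Number of signatures K (ignored when ``signatures`` is given).
    signatures : array of shape (K, M), optional
        Known signatures for refitting mode: held fixed during training, only
        cluster priors and exposures are learned.
    n_restarts : int, default=10
        Random restarts; the highest-likelihood run is kept.
    max_iter : int, default=1000
        EM iteration cap per restart.
    tol, rel_tol : float
        Absolute / relative log-likelihood improvement stopping thresholds.
    random_state : int or None
        Seed; restart r uses ``random_state + r``.

    Attributes
    ----------
    weights_ : (L,) cluster priors.
    exposures_ : (L, K) per-cluster signature exposures.
    signatures_ : (K, M) signatures.
    log_likelihood_ : final training log-likelihood.
    n_iter_ : EM updates of the winning restart.
    converged_ : whether the winning restart converged before the cap.
    result_ : the full :class:`FitResult`.

    Examples
    --------
    >>> from sigmixture.simulate import default_base_model, generate_catalog
    >>> base = default_base_model()
    >>> catalog, truth = generate_catalog(base, n_samples=200, poisson_mean=8, seed=0)
    >>> model = SignatureMixture(n_clusters=10, n_signatures=6, random_state=0).fit(catalog)
    >>> labels = model.predict(catalog)          # hard cluster per sample
    >>> exposures = model.transform(catalog)     # soft per-sample exposures
    """

    def __init__(
        self,
        n_clusters: int = 1,
        n_signatures: int = 1,
        *,
        signatures=None,
        n_restarts: int = 10,
        max_iter: int = 1000,
        tol: float = 1e-6,
        rel_tol: float = 1e-8,
        random_state=None,
    ):
        self.n_clusters = n_clusters
        self.n_signatures = n_signatures
        self.signatures = signatures
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.rel_tol = rel_tol
        self.random_state = random_state

    def _seed(self) -> int:
        if self.random_state is None:
            return int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        return int(self.random_state)

    def fit(self, X, y=None):
        """Fit by multi-restart EM on a count matrix or :class:`MutationCatalog`."""
        result = fit_mix(
            X,
            L=self.n_clusters,
            K=None if self.signatures is not None else self.n_signatures,
            fixed_signatures=self.signatures,
            n_restarts=self.n_restarts,
            max_iterations=self.max_iter,
            tolerance=self.tol,
            rel_tolerance=self.rel_tol,
            seed=self._seed(),
        )
        p = result.params
        self.weights_ = p.w
        self.exposures_ = p.pi
        self.signatures_ = p.e
        self.refit_mode_ = p.refit_mode
        self.log_likelihood_ = result.log_likelihood
        self.n_iter_ = result.n_iterations
        self.converged_ = result.converged
        self.result_ = result
        self.n_features_in_ = p.n_categories
        return self

    def _params(self) -> MixParameters:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "weights_")
        return MixParameters(
            w=self.weights_, pi=self.exposures_, e=self.signatures_,
            refit_mode=getattr(self, "refit_mode_", False),
        )

    def predict_proba(self, X) -> np.ndarray:
        """Posterior cluster responsibilities, shape (N, L)."""
        return mix_responsibilities(X, self._params())

    def predict(self, X) -> np.ndarray:
        """Maximum-posterior (hard) cluster assignment per sample."""
        from .inference import assign_clusters

        return assign_clusters(X, self._params())

    def transform(self, X, scheme: str = "soft", scale: str = "relative") -> np.ndarray:
        """Per-sample signature exposures, shape (N, K).

        ``scheme='soft'`` (default) returns responsibility-weighted sums of the
        cluster exposures; ``'hard'`` returns the best cluster's exposures.
        ``scale='counts'`` multiplies each row by the sample's mutation total.
        """
        from .inference import infer_exposures

        return infer_exposures(X, self._params(), scheme=scheme, scale=scale).exposures

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X).transform(X, **kwargs)

    def score(self, X, y=None) -> float:
        """Average per-sample log-likelihood (sklearn mixture convention)."""
        counts = as_counts(X)
        return mix_log_likelihood(counts, self._params()) / counts.shape[0]

    def score_total(self, X) -> float:
        """Total log-likelihood of a catalog under the fitted model."""
        return mix_log_likelihood(X, self._params())
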