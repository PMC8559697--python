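"""Evaluation utilities: NNLS refitting baseline, reconstruction errors,
cosine signature matching, and adjusted mutual information.

Two L1 error metrics quantify how well exposures inferred from sparse
(downsampled) data describe the rich data they came from. The reconstruction
error (RE) compares the row-normalized full mutation profile with its
signature reconstruction; the exposure reconstruction error (ERE) compares the
inferred relative exposures with "true" exposures obtained by NNLS on the full
data. Both are per-sample L1 distances between probability vectors, hence in
[0, 2]; the mean over evaluable samples is the headline number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.metrics import adjusted_mutual_info_score
from sklearn.metrics.pairwise import cosine_similarity




def nnls_exposures(V, S) -> np.ndarray:
    """Per-sample non-negative least-squares exposures against signatures S.

    Row n minimises ``|| V[n] - x @ S ||_2`` over x >= 0. This is the standard
    refitting baseline for rich data; on very sparse counts it is noisy, which
    is exactly the regime the clustered mixture model targets.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    S = np.asarray(S, dtype=float)
    if V.shape[1] != S.shape[1]:
        raise ValueError("V and S must have the same number of categories")
    if np.linalg.matrix_rank(S) < S.shape[0]:
        warnings.warn("signature matrix is rank-deficient; NNLS solution may "
                      "not be unique", RuntimeWarning, stacklevel=2)
    out = np.zeros((V.shape[0], S.shape[0]))
    for n in range(V.shape[0]):
        out[n], _ = nnls(S.T, V[n])
    return out


def _normalize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalize; returns (normalized, evaluable_mask). Zero rows are left
    as zeros and masked out."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    sums = X.sum(axis=1)
    ok = sums > 0
    out = np.zeros_like(X)
    out[ok] = X[ok] / sums[ok, None]
    return out, ok


def reconstruction_error(V_full, E_d, S) -> tuple[np.ndarray, float]:
    """Per-sample and mean L1 reconstruction error ``| V~ - E_d S |_1``.

    ``V_full`` is the rich count matrix (row-normalized internally to V~),
    ``E_d`` the relative exposures inferred on downsampled data, ``S`` the
    signature matrix. Samples with an all-zero count row or exposure row are
    skipped (NaN in the per-sample vector) and excluded from the mean.
    """
    V_tilde, ok_v = _normalize_rows(V_full)
    E_d = np.atleast_2d(np.asarray(E_d, dtype=float))
    ok = ok_v & (E_d.sum(axis=1) > 0)
    recon = E_d @ np.asarray(S, dtype=float)
    per_sample = np.abs(V_tilde - recon).sum(axis=1)
    per_sample[~ok] = np.nan
    mean = float(per_sample[ok].mean()) if ok.any() else float("nan")
    return per_sample, mean


def exposure_reconstruction_error(E_true, E_d) -> tuple[np.ndarray, float]:
    """Per-sample and mean L1 error ``| E~ - E_d |_1`` between exposures.

    ``E_true`` (typically NNLS exposures on the full data) is row-normalized
    to E~; samples with an all-zero true-exposure row are skipped with a
    warning.
    """
    E_tilde, ok = _normalize_rows(E_true)
    E_d = np.atleast_2d(np.asarray(E_d, dtype=float))
    if E_d.shape != E_tilde.shape:
        raise ValueError("exposure matrices must have the same shape")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} sample(s) with all-zero true exposures skipped",
            RuntimeWarning, stacklevel=2,
        )
    per_sample = np.abs(E_tilde - E_d).sum(axis=1)
    per_sample[~ok] = np.nan
    mean = float(per_sample[ok].mean()) if ok.any() else float("nan")
    return per_sample, mean


@dataclass
class SignatureMatch:
    """Pairing of learned signatures with reference signatures by cosine.

    ``pairs`` is a list of ``(learned_index, reference_index, cosine)``. In
    ``best_match`` mode each learned signature is paired with its most similar
    reference (repeats allowed, as when screening de-novo signatures against a
    reference catalog); ``one_to_one`` solves the maximum-total-cosine
    assignment (used for parameter-recovery scoring).
    """

    pairs: list[tuple[int, int, float]]
    mode: str

    @property
    def cosines(self) -> np.ndarray:
        return np.array([c for _, _, c in self.pairs])

    @property
    def mean_cosine(self) -> float:
        return float(self.cosines.mean())


def match_signatures(learned, reference, mode: str = "one_to_one") -> SignatureMatch:
    """Match learned signature rows to reference rows by cosine similarity."""
    learned = np.atleast_2d(np.asarray(learned, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if learned.shape[1] != reference.shape[1]:
        raise ValueError("signature matrices must share the category dimension")
    if np.any(np.linalg.norm(learned, axis=1) == 0) or np.any(
        np.linalg.norm(reference, axis=1) == 0
    ):
        raise ValueError("zero-vector signature")
    C = cosine_similarity(learned, reference)
    if mode == "best_match":
        pairs = [(i, int(C[i].argmax()), float(C[i].max())) for i in range(C.shape[0])]
    elif mode == "one_to_one":
        rows, cols = linear_sum_assignment(-C)
        pairs = [(int(i), int(j), float(C[i, j])) for i, j in zip(rows, cols)]
    else:
        raise ValueError("mode must be 'best_match' or 'one_to_one'")
    return SignatureMatch(pairs=pairs, mode=mode)


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """Chance-corrected partition agreement (max-entropy normalization).

    1.0 for identical partitions up to relabeling, ~0 for independent ones.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.size == 0 or labels_b.size == 0:
        raise ValueError("empty label arrays")
    if labels_a.shape != labels_b.shape:
        raise ValueError("label arrays must have equal length")
    return float(adjusted_mutual_info_score(labels_a, labels_b, average_method="max"))


def model_recovery_score(true_params, learned_params) -> dict:
    """Cosine-similarity summary of how well a fit recovers a known model.

    Signatures are matched one-to-one by maximum total cosine; cluster
    exposure rows (expressed over the matched signature order) are then
    matched one-to-one the same way. Returns per-part mean cosines and their
    overall average — the headline parameter-recovery number.
    """
    sig_match = match_signatures(learned_params.e, true_params.e, mode="one_to_one")
    # reorder learned signatures (and exposure columns) to the true order
    order = np.empty(true_params.n_signatures, dtype=int)
    for i, j, _ in sig_match.pairs:
        order[j] = i
    pi_learned = learned_params.pi[:, order]
    expo_match = match_signatures(pi_learned, true_params.pi, mode="one_to_one")
    sig_cos = sig_match.mean_cosine
    expo_cos = expo_match.mean_cosine
    all_cos = np.concatenate([sig_match.cosines, expo_match.cosines])
    return {
        "signature_cosines": sig_match.cosines,
        "exposure_cosines": expo_match.cosines,
        "mean_signature_cosine": sig_cos,
        "mean_exposure_cosine": expo_cos,
        "mean_cosine": float(all_cos.mean()),
    }
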