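"""Synthetic catalogs from the model's own generative process, plus downsampling.

The simulation workflow mirrors how realistic sparse-panel benchmarks are
built: start from a rich "base" model, subsample a ground truth with fewer
clusters and signatures, draw per-sample mutation budgets from a panel-like
empirical distribution, and emit mutations through the generative process
(cluster -> signature -> category). Two downsampling strategies turn rich
catalogs into panel-like ones: Poisson thinning to an average of d mutations
per sample, and restriction of per-mutation records to BED panel regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .catalog import MutationCatalog, sbs96_labels
from .model import MixParameters

#: Internal seed that pins down the shipped default base model.
DEFAULT_BASE_SEED = 920_461_117

#: Internal seed for the shipped panel-like budget list.
DEFAULT_BUDGET_SEED = 402_219


@dataclass
class GroundTruth:
    """Realized latent state of a generated catalog.

    ``cluster_assignments[n]`` is the cluster that generated sample n;
    ``signature_counts[n, i]`` how many of its mutations signature i emitted;
    ``mutation_budgets[n]`` the sample's total T_n.
    """

    params: MixParameters
    cluster_assignments: np.ndarray
    signature_counts: np.ndarray
    mutation_budgets: np.ndarray

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "cluster_assignments": self.cluster_assignments.tolist(),
            "signature_counts": self.signature_counts.tolist(),
            "mutation_budgets": self.mutation_budgets.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            params=MixParameters.from_dict(d["params"]),
            cluster_assignments=np.asarray(d["cluster_assignments"], dtype=int),
            signature_counts=np.asarray(d["signature_counts"], dtype=int),
            mutation_budgets=np.asarray(d["mutation_budgets"], dtype=int),
        )


@dataclass
class MutationRecord:
    """One mutation located on the genome, pre-classified into an SBS category."""

    sample_id: str
    chrom: str
    pos: int  # 1-based
    category: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")


def default_base_model(
    n_clusters: int = 10,
    n_signatures: int = 6,
    n_categories: int = 96,
    seed: int = DEFAULT_BASE_SEED,
) -> MixParameters:
    """A documented synthetic base model standing in for a panel-trained fit.

    The base emulates a pan-cancer cohort in which a few mutational processes
    dominate: the first ``n_signatures - 2`` signatures are "major" processes
    that act as cluster dominants, the last two are rare background processes.
    Signatures are sparse Dirichlet(0.05) draws over the categories (nearly
    mutually orthogonal, i.e. well separated). Each cluster's exposure row
    concentrates ~99% of its mass on a dominant subset of 2-3 major
    signatures — every cluster a *distinct* subset, with jittered weights
    around (0.68, 0.32) for pairs and (0.42, 0.33, 0.25) for triples — and
    spreads the remainder as background (0.002 on non-dominant majors, 0.0002
    on the rare signatures). Cluster priors are a moderately even Dirichlet(5)
    draw. All randomness is pinned by ``seed``, so the default base is a
    fixed, documented object; the default dimensions (10 clusters, 6
    signatures) use all 10 distinct dominant subsets of the 4 majors.
    """
    if n_signatures < 4:
        raise ValueError("the base construction needs at least 4 signatures")
    majors = list(range(n_signatures - 2))
    minors = [n_signatures - 2, n_signatures - 1]
    subsets = list(combinations(majors, 2)) + list(combinations(majors, 3))
    if n_clusters > len(subsets):
        raise ValueError(
            f"at most {len(subsets)} clusters supported for {n_signatures} "
            "signatures (distinct dominant subsets run out)"
        )
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.full(n_clusters, 5.0))
    e = rng.dirichlet(np.full(n_categories, 0.05), size=n_signatures)
    # avoid exact structural zeros in signatures
    e = e + 1e-12
    e = e / e.sum(axis=1, keepdims=True)

    pi = np.zeros((n_clusters, n_signatures))
    for l, dominant in enumerate(subsets[:n_clusters]):
        size = len(dominant)
        weights = np.array([0.68, 0.32]) if size == 2 else np.array([0.42, 0.33, 0.25])
        weights = weights + rng.uniform(-0.03, 0.03, size=size)
        weights = (weights / weights.sum())[rng.permutation(size)]
        rest = [i for i in range(n_signatures) if i not in dominant]
        background = np.array([0.0002 if i in minors else 0.002 for i in rest])
        pi[l, list(dominant)] = (1.0 - background.sum()) * weights
        pi[l, rest] = background
    pi = pi / pi.sum(axis=1, keepdims=True)
    return MixParameters(w=w, pi=pi, e=e)


def default_panel_budgets(n: int = 500, mean: float = 7.0, seed: int = DEFAULT_BUDGET_SEED) -> np.ndarray:
    """A fixed panel-like list of per-sample mutation totals (mean ~ 7).

    Drawn once from a negative binomial (r=2) clipped to >= 1, emulating the
    overdispersed totals of targeted-panel cohorts; resample from this list
    uniformly with replacement to assign budgets to synthetic samples.
    """
    rng = np.random.default_rng(seed)
    r = 2.0
    p = r / (r + mean)
    budgets = rng.negative_binomial(r, p, size=n)
    return np.maximum(budgets, 1)


def build_ground_truth(base: MixParameters, L_sub: int, K_sub: int, seed: int = 0) -> MixParameters:
    """Subsample a ground-truth model from a rich base model.

    Clusters are drawn without replacement with probabilities ``w`` and their
    priors renormalized; signatures are then drawn without replacement with
    probabilities ``p_k = sum_l w_l pi_k^l`` (computed on the renormalized
    cluster subset); exposure rows are restricted to the chosen signatures and
    renormalized; the signature matrix keeps the chosen rows.
    """
    if L_sub > base.n_clusters or K_sub > base.n_signatures:
        raise ValueError("subset sizes exceed the base model's dimensions")
    if min(L_sub, K_sub) < 1:
        raise ValueError("subset sizes must be >= 1")
    rng = np.random.default_rng(seed)

    clusters = rng.choice(base.n_clusters, size=L_sub, replace=False, p=base.w)
    w = base.w[clusters]
    w = w / w.sum()
    pi = base.pi[clusters]

    p_k = w @ pi  # marginal signature usage over the selected clusters
    p_k = p_k / p_k.sum()
    sigs = rng.choice(base.n_signatures, size=K_sub, replace=False, p=p_k)

    pi_sub = pi[:, sigs]
    row_sums = pi_sub.sum(axis=1)
    if np.any(row_sums <= 0):
        warnings.warn(
            "a cluster had zero mass on the selected signatures; using a "
            "uniform exposure row",
            RuntimeWarning,
            stacklevel=2,
        )
        pi_sub[row_sums <= 0] = 1.0
        row_sums = pi_sub.sum(axis=1)
    pi_sub = pi_sub / row_sums[:, None]
    return MixParameters(w=w, pi=pi_sub, e=base.e[sigs])


def generate_catalog(
    params: MixParameters,
    n_samples: int,
    *,
    budgets=None,
    poisson_mean: float | None = None,
    seed: int = 0,
    sample_prefix: str = "sample",
) -> tuple[MutationCatalog, GroundTruth]:
    """Draw a catalog from the generative process.

    Per sample: a cluster ``c ~ w``; a mutation budget T (resampled uniformly
    with replacement from ``budgets``, or ``T ~ Poisson(poisson_mean)``); T
    signature choices iid from ``pi^c``; and each mutation's category from the
    chosen signature's distribution. Returns the catalog together with the
    realized latent state. Defaults to the panel-like budget list when neither
    budget source is given.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if budgets is not None and poisson_mean is not None:
        raise ValueError("give either budgets or poisson_mean, not both")
    rng = np.random.default_rng(seed)
    L, K, M = params.n_clusters, params.n_signatures, params.n_categories

    if poisson_mean is not None:
        T = rng.poisson(poisson_mean, size=n_samples)
    else:
        if budgets is None:
            budgets = default_panel_budgets()
        budgets = np.asarray(budgets, dtype=int)
        if budgets.size == 0:
            raise ValueError("empty budget list")
        T = rng.choice(budgets, size=n_samples, replace=True)

    c = rng.choice(L, size=n_samples, p=params.w)
    counts = np.zeros((n_samples, M), dtype=np.int64)
    sig_counts = np.zeros((n_samples, K), dtype=np.int64)
    for n in range(n_samples):
        zc = rng.multinomial(T[n], params.pi[c[n]])
        sig_counts[n] = zc
        for i in np.flatnonzero(zc):
            counts[n] += rng.multinomial(zc[i], params.e[i])

    labels = sbs96_labels() if M == 96 else None
    catalog = MutationCatalog(
        counts=counts,
        sample_ids=[f"{sample_prefix}_{n}" for n in range(n_samples)],
        category_labels=labels,
    )
    truth = GroundTruth(
        params=params,
        cluster_assignments=c,
        signature_counts=sig_counts,
        mutation_budgets=np.asarray(T, dtype=int),
    )
    return catalog, truth


def poisson_downsample(catalog: MutationCatalog, d: float, seed: int = 0) -> MutationCatalog:
    """Thin each sample to about d mutations on average.

    For each sample, draw ``n_i ~ Poisson(d)`` and keep a uniform
    without-replacement subset of ``min(n_i, T_i)`` of its mutations (a
    multivariate hypergeometric draw over the category counts).
    """
    if d <= 0:
        raise ValueError("d must be > 0")
    rng = np.random.default_rng(seed)
    counts = catalog.counts
    out = np.zeros_like(counts)
    keep = rng.poisson(d, size=counts.shape[0])
    for n in range(counts.shape[0]):
        total = int(counts[n].sum())
        k = min(int(keep[n]), total)
        if k == total:
            out[n] = counts[n]
        elif k > 0:
            out[n] = rng.multivariate_hypergeometric(counts[n], k)
    return MutationCatalog(
        counts=out,
        sample_ids=list(catalog.sample_ids),
        category_labels=list(catalog.category_labels),
    )


def region_downsample(records, intervals) -> list[MutationRecord]:
    """Keep the mutation records falling inside panel regions.

    ``intervals`` is an iterable of ``(chrom, start, end)`` BED-style tuples
    (0-based, half-open). A record with 1-based position ``pos`` is kept iff
    ``start < pos <= end`` for some interval on its chromosome.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        start, end = int(start), int(end)
        if start >= end:
            raise ValueError(f"invalid interval on {chrom}: start {start} >= end {end}")
        by_chrom.setdefault(str(chrom), []).append((start, end))
    kept = []
    for rec in records:
        for start, end in by_chrom.get(rec.chrom, ()):
            if start < rec.pos <= end:
                kept.append(rec)
                break
    return kept
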