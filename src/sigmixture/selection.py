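"""BIC scoring and (L, K) hyperparameter grid search.

The number of clusters L and signatures K are chosen by minimising the
Bayesian information criterion over a grid of candidate values:

    BIC(L, K) = size * log(n) - 2 * loglik

where ``size = (L-1) + L(K-1) + K(M-1)`` is the number of free parameters and
``n`` is the number of data points, i.e. the total number of mutations in the
catalog (mutations are the iid units of the likelihood). In refitting mode the
signatures are fixed, so only ``(L-1) + L(K-1)`` parameters are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import as_counts
from .model import FitResult, fit_mix


def parameter_count(L: int, K: int, M: int, refit_mode: bool = False) -> int:
    """Free parameters of an (L, K) model over M categories."""
    if min(L, K, M) < 1:
        raise ValueError("L, K and M must all be >= 1")
    n = (L - 1) + L * (K - 1)
    if not refit_mode:
        n += K * (M - 1)
    return n


def bic_score(fit: FitResult, total_mutations: int) -> float:
    """``size * log(n) - 2 * loglik`` for a trained model; lower is better."""
    if total_mutations < 1:
        raise ValueError("BIC requires at least one mutation")
    p = fit.params
    size = parameter_count(p.n_clusters, p.n_signatures, p.n_categories, p.refit_mode)
    return size * math.log(total_mutations) - 2.0 * fit.log_likelihood


@dataclass
class BICGridEntry:
    L: int
    K: int
    bic: float
    log_likelihood: float
    n_parameters: int
    fit: FitResult | None = field(repr=False, default=None)
    error: str | None = None


@dataclass
class BICGrid:
    """All grid cells plus the BIC-minimising (L*, K*)."""

    entries: list[BICGridEntry]
    best: tuple[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "L": c.L,
                "K": c.K,
                "n_parameters": c.n_parameters,
                "log_likelihood": c.log_likelihood,
                "bic": c.bic,
                "selected": int((c.L, c.K) == self.best),
            }
            for c in self.entries
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def select_hyperparameters(
    catalog,
    L_range,
    K_range,
    *,
    fixed_signatures=None,
    n_restarts: int = 10,
    max_iterations: int = 1000,
    tolerance: float = 1e-6,
    rel_tolerance: float = 1e-8,
    seed: int = 0,
) -> BICGrid:
    """Fit every (L, K) on the grid and pick the BIC minimiser.

    ``L_range`` / ``K_range`` are iterables of candidate values. Ties in the
    minimum are broken towards smaller K, then smaller L (parsimony). A cell
    whose fit raises is recorded with its error message instead of aborting
    the whole grid.
    """
    counts = as_counts(catalog)
    n_mut = int(counts.sum())
    L_values = sorted(set(int(x) for x in L_range))
    K_values = sorted(set(int(x) for x in K_range))
    if not L_values or not K_values:
        raise ValueError("empty hyperparameter range")

    entries: list[BICGridEntry] = []
    for L in L_values:
        for K in K_values:
            try:
                fit = fit_mix(
                    counts,
                    L=L,
                    K=K if fixed_signatures is None else None,
                    fixed_signatures=fixed_signatures,
                    n_restarts=n_restarts,
                    max_iterations=max_iterations,
                    tolerance=tolerance,
                    rel_tolerance=rel_tolerance,
                    seed=seed,
                )
            except Exception as exc:  # annotate the cell, keep the grid going
                entries.append(
                    BICGridEntry(
                        L=L, K=K, bic=float("nan"), log_likelihood=float("nan"),
                        n_parameters=parameter_count(
                            L, K, counts.shape[1], fixed_signatures is not None
                        ),
                        error=str(exc),
                    )
                )
                continue
            entries.append(
                BICGridEntry(
                    L=L,
                    K=fit.params.n_signatures,
                    bic=bic_score(fit, n_mut),
                    log_likelihood=fit.log_likelihood,
                    n_parameters=parameter_count(
                        L, fit.params.n_signatures, counts.shape[1],
                        fit.params.refit_mode,
                    ),
                    fit=fit,
                )
            )
    scored = [c for c in entries if np.isfinite(c.bic)]
    if not scored:
        raise RuntimeError("every grid cell failed to fit")
    best = min(scored, key=lambda c: (c.bic, c.K, c.L))
    return BICGrid(entries=entries, best=(best.L, best.K))
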