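"""Post-training per-sample outputs: cluster assignments and exposures.

Hard clustering assigns each sample to its maximum-posterior cluster and
adopts that cluster's exposure vector; soft clustering averages the cluster
exposures weighted by the posterior responsibilities. The hard scheme is the
natural choice for reporting clusters, the soft one for exposures. Relative
exposures sum to 1 per sample; count-scaled exposures multiply by the sample's
mutation total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import as_counts
from .model import MixParameters, mix_responsibilities


@dataclass
class ExposureMatrix:
    """N x K per-sample signature exposures plus how they were computed."""

    exposures: np.ndarray
    scale: str  # "relative" or "counts"
    scheme: str  # "hard" or "soft"
    sample_ids: list[str] | None = None
    signature_names: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        k = self.exposures.shape[1]
        names = self.signature_names or [f"sig{i + 1}" for i in range(k)]
        index = self.sample_ids or list(range(self.exposures.shape[0]))
        return pd.DataFrame(self.exposures, index=index, columns=names)


def assign_clusters(catalog, params: MixParameters) -> np.ndarray:
    """Maximum-posterior cluster index per sample (ties -> lowest index)."""
    resp = mix_responsibilities(catalog, params)
    return resp.argmax(axis=1)


def infer_exposures(
    catalog,
    params: MixParameters,
    scheme: str = "soft",
    scale: str = "relative",
) -> ExposureMatrix:
    """Per-sample exposure vectors from a trained model.

    ``scheme='soft'``: row n is ``sum_l f^{n,l} pi^l`` (a convex combination of
    the cluster exposures). ``scheme='hard'``: row n is ``pi^l`` for the
    maximum-posterior cluster l. With ``scale='counts'`` each row is multiplied
    by the sample's mutation total (zero-mutation samples get all-zero rows).
    """
    if scheme not in ("hard", "soft"):
        raise ValueError("scheme must be 'hard' or 'soft'")
    if scale not in ("relative", "counts"):
        raise ValueError("scale must be 'relative' or 'counts'")
    counts = as_counts(catalog)
    resp = mix_responsibilities(counts, params)
    if scheme == "soft":
        expo = resp @ params.pi
    else:
        expo = params.pi[resp.argmax(axis=1)]
    if scale == "counts":
        expo = expo * counts.sum(axis=1, keepdims=True)
    sample_ids = getattr(catalog, "sample_ids", None)
    return ExposureMatrix(exposures=expo, scale=scale, scheme=scheme, sample_ids=sample_ids)
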