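"""Readers and writers for catalogs, signatures, records, panels and models.

File formats
------------
* Catalog TSV: samples in rows; first column the sample id, remaining columns
  the 96 canonical SBS category labels (any column order; reordered to
  canonical on read). Cells are non-negative integers.
* Signature file: the COSMIC v2 tab-delimited layout — 96 context rows with a
  ``Somatic Mutation Type`` column holding labels like ``A[C>A]A``, one column
  per signature. Columns off from unit sum by at most 1e-3 are renormalized
  on load with a warning; larger deviations are rejected as malformed.
* Mutation records TSV: columns sample_id, chrom, pos (1-based), category.
* BED: >= 3 columns, 0-based half-open intervals.
* Model JSON: ``{"w", "pi", "e", "category_labels", "refit_mode", "meta"}``.

Cluster and signature indices are 0-based internally; report writers state
their convention in the header.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MutationCatalog, sbs96_labels
from .inference import ExposureMatrix
from .model import FitResult, MixParameters
from .simulate import MutationRecord

_SIGNATURE_SUM_TOL = 1e-3


def read_catalog(path) -> MutationCatalog:
    """Read a samples x SBS-96 count matrix TSV, reordering to canonical order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    canonical = sbs96_labels()
    unknown = [c for c in df.columns if c not in set(canonical)]
    if unknown:
        raise ValueError(f"unknown category label(s) in {path}: {unknown[:5]}")
    if len(df.columns) != len(canonical) or set(df.columns) != set(canonical):
        missing = sorted(set(canonical) - set(df.columns))
        raise ValueError(f"catalog must have all 96 categories; missing {missing[:5]}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample_id {dup!r}")
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (np.mod(values.astype(float), 1) != 0) | (values < 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"cell ({df.index[r]!r}, {df.columns[c]!r}) = {values[r, c]!r} is not "
            "a non-negative integer"
        )
    df = df[canonical]
    return MutationCatalog.from_frame(df.astype(np.int64))


def write_catalog(catalog: MutationCatalog, path) -> None:
    frame = catalog.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_signatures(path, subset=None) -> tuple[np.ndarray, list[str]]:
    """Read a COSMIC v2 layout signature file.

    Returns ``(S, names)`` with one row per signature, columns in canonical
    SBS-96 order, rows renormalized to sum to 1. ``subset`` selects named
    signature columns (rows returned in request order).
    """
    df = pd.read_csv(path, sep="\t")
    label_col = None
    for cand in ("Somatic Mutation Type", "somatic mutation type"):
        if cand in df.columns:
            label_col = cand
            break
    if label_col is None:
        raise ValueError(f"{path} has no 'Somatic Mutation Type' column")
    df = df.set_index(label_col)
    meta_cols = [c for c in ("Substitution Type", "Trinucleotide") if c in df.columns]
    df = df.drop(columns=meta_cols)
    canonical = sbs96_labels()
    if set(df.index) != set(canonical):
        raise ValueError(f"{path} does not contain the canonical 96 contexts")
    df = df.loc[canonical]

    names = list(df.columns)
    if subset is not None:
        missing = [s for s in subset if s not in names]
        if missing:
            raise ValueError(f"signature(s) {missing} not in file; available: {names}")
        df = df[list(subset)]
        names = list(subset)

    S = df.to_numpy(dtype=float).T  # (K, 96)
    if np.any(S < 0):
        raise ValueError("signature probabilities must be non-negative")
    sums = S.sum(axis=1)
    off = np.abs(sums - 1.0)
    if np.any(off > _SIGNATURE_SUM_TOL):
        k = int(np.argmax(off))
        raise ValueError(f"signature {names[k]!r} sums to {sums[k]:.6f}, not 1")
    if np.any(off > 1e-9):
        warnings.warn("renormalizing signature columns to sum to 1", UserWarning,
                      stacklevel=2)
    return S / sums[:, None], names


def write_signatures(S, names, path) -> None:
    """Write signatures in the COSMIC v2 tab-delimited layout."""
    S = np.asarray(S, dtype=float)
    canonical = sbs96_labels()
    if S.shape[1] != 96:
        raise ValueError("signatures must span the 96 canonical categories")
    df = pd.DataFrame(S.T, columns=list(names))
    df.insert(0, "Somatic Mutation Type", canonical)
    df.insert(0, "Trinucleotide", [f"{c[0]}{c[2]}{c[6]}" for c in canonical])
    df.insert(0, "Substitution Type", [c[2:5] for c in canonical])
    df.to_csv(path, sep="\t", index=False)


def save_model(result: FitResult | MixParameters, path, category_labels=None) -> None:
    """Serialize a model (or fit result) to JSON."""
    if isinstance(result, FitResult):
        params = result.params
        meta = {
            "seed": result.seed,
            "loglik": result.log_likelihood,
            "iterations": result.n_iterations,
        }
    else:
        params, meta = result, {}
    if category_labels is None and params.n_categories == 96:
        category_labels = sbs96_labels()
    with open(path, "w") as fh:
        json.dump(params.to_dict(category_labels=category_labels, meta=meta), fh, indent=1)


def load_model(path) -> MixParameters:
    with open(path) as fh:
        return MixParameters.from_dict(json.load(fh))


def write_exposures(expo: ExposureMatrix, path, signature_names=None) -> None:
    frame = expo.to_frame()
    if signature_names is not None:
        frame.columns = list(signature_names)
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")


def read_exposures(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clusters(sample_ids, assignments, posteriors, path) -> None:
    """Cluster report TSV: sample_id, cluster_index (0-based), posterior_max."""
    df = pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "cluster_index": np.asarray(assignments, dtype=int),
            "posterior_max": np.asarray(posteriors, dtype=float).max(axis=1),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_records(path) -> list[MutationRecord]:
    """Mutation records TSV: sample_id, chrom, pos (1-based), category."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    required = {"sample_id", "chrom", "pos", "category"}
    if not required.issubset(df.columns):
        raise ValueError(f"records file needs columns {sorted(required)}")
    return [
        MutationRecord(
            sample_id=row.sample_id, chrom=row.chrom, pos=int(row.pos),
            category=row.category,
        )
        for row in df.itertuples()
    ]


def write_records(records, path) -> None:
    df = pd.DataFrame(
        [
            {"sample_id": r.sample_id, "chrom": r.chrom, "pos": r.pos, "category": r.category}
            for r in records
        ],
        columns=["sample_id", "chrom", "pos", "category"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_bed(path) -> list[tuple[str, int, int]]:
    """Parse a BED file into (chrom, start, end) tuples (0-based half-open)."""
    intervals = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: BED line has fewer than 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{i}: non-integer BED coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}:{i}: start {start} >= end {end}")
        intervals.append((parts[0], start, end))
    return intervals
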