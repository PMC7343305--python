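"""Sample QC, rarefaction, presence calling, and abundant-ASV selection.

These mirror the study's preprocessing: drop samples with fewer than 1,000
reads or incomplete metadata (and, where requested, former smokers),
rarefy to a fixed depth without replacement, call "presence" at a relative
abundance of 1/5,000, and keep ASVs present in at least 10% of samples —
excluding near-universal ones from prevalence modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import FeatureTable

__all__ = [
    "filter_samples",
    "rarefy",
    "presence_matrix",
    "select_abundant",
    "PresenceMatrix",
    "RarefiedTable",
]

#: Relative-abundance threshold defining carriage of an ASV. The study set
#: it to 1/5,000, one read at the shallowest retained depth.
PRESENCE_THRESHOLD = 1.0 / 5000.0


@dataclass
class RarefiedTable:
    table: FeatureTable
    depth: int
    seed: int
    dropped: list

    @property
    def data(self) -> pd.DataFrame:
        return self.table.data


@dataclass
class PresenceMatrix:
    """Boolean samples x features matrix at a relative-abundance threshold."""

    data: pd.DataFrame
    threshold: float

    def prevalence(self) -> pd.Series:
        """Number of samples in which each feature is present."""
        return self.data.sum(axis=0)


def filter_samples(
    table: FeatureTable,
    metadata: pd.DataFrame,
    min_depth: int = 1000,
    exclusions: dict | None = None,
) -> tuple[FeatureTable, pd.DataFrame, dict]:
    """Apply sample QC; returns (table, metadata, audit log of removals).

    Rules, applied in order: sample must appear in both table and metadata;
    depth >= min_depth; metadata complete (``excluded`` flag unset); and no
    exclusion predicate matched. ``exclusions`` maps a column name to a
    value or list of excluded values, e.g. ``{"smoking": "former"}`` to
    drop former smokers.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    audit: dict[str, int] = {}
    shared = table.data.index.intersection(metadata.index)
    audit["no_metadata"] = len(table.data.index) - len(shared)
    kept = table.data.loc[shared]
    meta = metadata.loc[shared]

    depths = kept.sum(axis=1)
    low = depths < min_depth
    audit["low_depth"] = int(low.sum())
    kept, meta = kept[~low], meta[~low.to_numpy()]

    if "excluded" in meta:
        inc = meta["excluded"].astype(bool)
        audit["incomplete_metadata"] = int(inc.sum())
        kept, meta = kept[~inc.to_numpy()], meta[~inc]

    for col, values in (exclusions or {}).items():
        if not isinstance(values, (list, tuple, set)):
            values = [values]
        hit = meta[col].isin(list(values)).fillna(False)
        audit[f"excluded_{col}"] = int(hit.sum())
        kept, meta = kept[~hit.to_numpy()], meta[~hit]

    if kept.shape[0] == 0:
        raise ValueError("all samples removed by QC")
    return FeatureTable(kept), meta, audit


def rarefy(table: FeatureTable, depth: int, seed: int) -> RarefiedTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (recorded in
    ``dropped``). Sampling is multivariate hypergeometric, so rarefied
    counts never exceed the originals and row sums equal ``depth`` exactly;
    the draw is reproducible given the seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = table.counts
    totals = counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    out = np.empty((int(keep.sum()), counts.shape[1]), dtype=np.int64)
    for row, i in enumerate(np.flatnonzero(keep)):
        if totals[i] == depth:
            out[row] = counts[i]
        else:
            out[row] = rng.multivariate_hypergeometric(counts[i], depth)
    data = pd.DataFrame(
        out,
        index=[s for s, k in zip(table.sample_ids, keep) if k],
        columns=table.feature_ids,
    )
    data.index.name, data.columns.name = "sample_id", "feature_id"
    return RarefiedTable(FeatureTable(data), depth, seed, dropped)


def presence_matrix(
    table: FeatureTable,
    threshold: float = PRESENCE_THRESHOLD,
    strict: bool = False,
) -> PresenceMatrix:
    """Call presence where relative abundance >= threshold.

    ``strict=True`` switches the boundary to a strict ``>`` (the study's
    prose states "greater than 0.02%" in one place and "a relative
    abundance of 1/5,000" in another; >= is the default reading).
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    rel = table.relative_abundance()
    present = rel.gt(threshold) if strict else rel.ge(threshold)
    return PresenceMatrix(present, threshold)


def select_abundant(
    presence: PresenceMatrix,
    min_prevalence_fraction: float = 0.10,
    max_prevalence_count: int | None = None,
) -> list[str]:
    """Features present in at least ``min_prevalence_fraction`` of samples.

    For prevalence modelling, features present in more than
    ``max_prevalence_count`` samples are additionally excluded (the study
    removed ASVs present in more than 1,000 of 1,066 samples, where the
    outcome is nearly constant and a prevalence ratio is uninformative).
    """
    if not (0 < min_prevalence_fraction < 1):
        raise ValueError("min_prevalence_fraction must be in (0, 1)")
    n = presence.data.shape[0]
    prev = presence.prevalence()
    mask = prev >= min_prevalence_fraction * n
    if max_prevalence_count is not None:
        mask &= prev <= max_prevalence_count
    return list(prev.index[mask])
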