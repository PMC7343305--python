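"""Design-matrix construction shared by the adjusted models.

Categorical metadata columns expand to treatment-coded dummies (first
level dropped); numeric columns enter as-is. Every model in the pipeline
includes an intercept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["term_matrix", "build_design"]


def term_matrix(metadata: pd.DataFrame, term: str) -> pd.DataFrame:
    """Columns encoding one model term (dummies for categoricals)."""
    if term not in metadata:
        raise KeyError(f"metadata has no column {term!r}")
    col = metadata[term]
    if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object or col.dtype == bool:
        cat = col.astype("category").cat.remove_unused_categories()
        if len(cat.cat.categories) < 2:
            raise ValueError(f"term {term!r} has a single level")
        dummies = pd.get_dummies(cat, prefix=term, drop_first=True, dtype=float)
        return dummies
    if col.isna().any():
        raise ValueError(f"term {term!r} has missing values")
    return pd.DataFrame({term: col.astype(float)})


def build_design(
    metadata: pd.DataFrame, terms: list[str], add_intercept: bool = True
) -> pd.DataFrame:
    """Full design matrix for an ordered list of terms."""
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"Intercept": np.ones(len(metadata))}, index=metadata.index))
    for term in terms:
        parts.append(term_matrix(metadata, term).set_axis(metadata.index, axis=0))
    X = pd.concat(parts, axis=1)
    if X.columns.has_duplicates:
        dup = X.columns[X.columns.duplicated()].tolist()
        raise ValueError(f"duplicated design columns: {dup}")
    return X
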