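"""Read/write the standard formats the pipeline touches.

Feature tables (TSV in either orientation, or minimal BIOM-JSON), sample
metadata TSV, rooted newick phylogenies, and FASTA sequence files; plus
construction of the human-readable ASV display identifiers used throughout
the analysis (``<4 letters of lowest taxon>-<4 hex chars of MD5>``).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FeatureTable",
    "FormatError",
    "ValidationError",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "make_display_id",
    "read_tree",
    "read_fasta",
    "write_fasta",
    "AsvRecord",
]


class FormatError(ValueError):
    """The file could not be parsed as the declared format."""


class ValidationError(ValueError):
    """The file parsed, but its content violates a table invariant."""


STATUS_LEVELS = ("control", "case")
SMOKING_LEVELS = ("never", "current", "former")

#: Covariates every adjusted model in the study uses; samples missing any of
#: these are flagged for exclusion rather than silently modelled.
REQUIRED_COLUMNS = ("status", "age", "sex", "run")


@dataclass
class FeatureTable:
    """Samples x features matrix of non-negative integer counts.

    ``data`` is a pandas DataFrame indexed by sample id with feature-id
    columns. Construction validates uniqueness of ids and non-negativity,
    so any ``FeatureTable`` in the pipeline satisfies the invariants.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if values.size:
            if np.any(values < 0):
                raise ValidationError("negative counts")
            if not np.allclose(values, np.round(values)):
                raise ValidationError("non-integer counts")
        self.data = self.data.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def depths(self) -> pd.Series:
        """Sequencing depth (row sum) per sample."""
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        depths = self.depths().to_numpy(dtype=float)
        if np.any(depths == 0):
            zero = self.data.index[depths == 0].tolist()
            raise ValidationError(f"zero-depth samples: {zero}")
        return self.data.div(self.depths(), axis=0)

    def filter_samples(self, keep) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(keep)])

    def filter_features(self, keep) -> "FeatureTable":
        return FeatureTable(self.data[list(keep)])

    def drop_features(self, drop) -> "FeatureTable":
        return FeatureTable(self.data.drop(columns=list(drop)))


def read_feature_table(path, dialect: str = "features") -> FeatureTable:
    """Read a count table from TSV or BIOM-JSON.

    Parameters
    ----------
    path
        TSV file (orientation per *dialect*) or a ``.biom`` JSON file.
    dialect
        ``"features"`` (QIIME-style export: features as rows, the default),
        ``"samples"`` (samples as rows), or ``"auto"`` which looks for the
        ``#OTU ID`` / ``#ASV ID`` header sentinel and otherwise assumes
        features-as-rows.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if text.lstrip().startswith("{"):
        return _read_biom_json(text, path)

    lines = text.splitlines()
    # QIIME exports prepend a "# Constructed from biom file" comment line
    if lines and lines[0].startswith("# ") and "\t" not in lines[0]:
        lines = lines[1:]
    try:
        df = pd.read_csv(StringIO("\n".join(lines)), sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: could not parse TSV ({exc})") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no data columns")

    if dialect == "auto":
        sentinel = str(df.index.name or "").lstrip("#").strip().lower()
        dialect = "features" if sentinel in ("otu id", "asv id", "feature id", "") else "samples"
    if dialect == "features":
        df = df.T
    elif dialect != "samples":
        raise ValueError(f"unknown dialect {dialect!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name, df.columns.name = "sample_id", "feature_id"
    return FeatureTable(df)


def _read_biom_json(text: str, path: Path) -> FeatureTable:
    """Minimal BIOM 1.0 (JSON) reader: dense or sparse OTU tables."""
    try:
        obj = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    try:
        feature_ids = [r["id"] for r in obj["rows"]]
        sample_ids = [c["id"] for c in obj["columns"]]
        n_feat, n_samp = obj["shape"]
        mat = np.zeros((n_feat, n_samp))
        if obj.get("matrix_type") == "sparse":
            for i, j, v in obj["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(obj["data"])
    except (KeyError, TypeError, IndexError) as exc:
        raise FormatError(f"{path}: not a BIOM-JSON table ({exc})") from exc
    df = pd.DataFrame(mat.T, index=sample_ids, columns=feature_ids)
    df.index.name, df.columns.name = "sample_id", "feature_id"
    return FeatureTable(df)


def write_feature_table(table: FeatureTable, path, dialect: str = "features") -> None:
    df = table.data.T if dialect == "features" else table.data
    if dialect == "features":
        df = df.rename_axis("#ASV ID")
    df.to_csv(path, sep="\t")


def read_metadata(
    path,
    column_map: dict | None = None,
    case_insensitive_status: bool = True,
    required: tuple = REQUIRED_COLUMNS,
) -> pd.DataFrame:
    """Read per-sample metadata TSV into a typed DataFrame.

    The first column is the sample id. ``column_map`` renames file columns
    to the canonical names (status, age, sex, run, smoking, community,
    teeth). Samples with a missing required covariate, or missing smoking
    information, get ``excluded=True`` — the study dropped samples without
    tobacco-use information rather than imputing.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if column_map:
        df = df.rename(columns=column_map)
    if df.index.has_duplicates:
        raise ValidationError("duplicate sample ids in metadata")

    if "status" in df:
        status = df["status"].str.strip()
        if case_insensitive_status:
            status = status.str.lower()
        bad = set(status.dropna().unique()) - set(STATUS_LEVELS)
        if bad:
            raise ValidationError(f"unknown status levels: {sorted(bad)}")
        df["status"] = pd.Categorical(status, categories=STATUS_LEVELS)
    if "age" in df:
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    if "smoking" in df:
        smoking = df["smoking"].str.strip().str.lower().replace("", np.nan)
        bad = set(smoking.dropna().unique()) - set(SMOKING_LEVELS)
        if bad:
            raise ValidationError(f"unknown smoking levels: {sorted(bad)}")
        df["smoking"] = pd.Categorical(smoking, categories=SMOKING_LEVELS)
    for col in ("sex", "run", "community", "teeth"):
        if col in df:
            df[col] = pd.Categorical(df[col].astype("string").str.strip())

    excluded = pd.Series(False, index=df.index)
    for col in required:
        if col not in df:
            raise ValidationError(f"required metadata column {col!r} missing")
        excluded |= df[col].isna()
    if "smoking" in df:
        excluded |= df["smoking"].isna()
    df["excluded"] = excluded
    return df


def make_display_id(sequence: str, taxonomy) -> str:
    """Build the ASV display id: 4 letters of the lowest assigned taxon,
    a dash, and the first 4 lowercase hex characters of the sequence MD5.

    ``taxonomy`` is an ordered lineage (highest to lowest rank); undefined
    ranks (empty / "__"-style placeholders) inherit the lowest defined
    level. The MD5 is computed on the uppercased sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if isinstance(taxonomy, str):
        taxonomy = [taxonomy]
    lowest = None
    for level in taxonomy:
        name = str(level).strip()
        if "__" in name:  # greengenes-style "g__Genus"
            name = name.split("__", 1)[1].strip()
        if name:
            lowest = name
    if lowest is None:
        raise ValueError("taxonomy has no defined level")
    digest = hashlib.md5(sequence.upper().encode("ascii")).hexdigest()
    return f"{lowest[:4]}-{digest[:4]}"


@dataclass
class AsvRecord:
    """An ASV: its exact sequence, taxonomic lineage, and display id."""

    sequence: str
    taxonomy: list[str] = field(default_factory=list)
    display_id: str = ""

    def __post_init__(self) -> None:
        if not self.display_id:
            self.display_id = make_display_id(self.sequence, self.taxonomy)


def assign_display_ids(records: list[AsvRecord]) -> dict[str, AsvRecord]:
    """Index records by display id, warning on MD5-prefix collisions."""
    out: dict[str, AsvRecord] = {}
    for rec in records:
        if rec.display_id in out and out[rec.display_id].sequence != rec.sequence:
            warnings.warn(
                f"display-id collision at {rec.display_id!r}: distinct sequences"
            )
        out[rec.display_id] = rec
    return out


def read_tree(path) -> TreeNode:
    """Read a rooted newick tree; missing branch lengths become 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise FormatError(f"{path}: could not parse newick ({exc})") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError("negative branch length")
    if n_missing:
        warnings.warn(f"{n_missing} branch lengths missing; set to 0")
    tree.length = tree.length or 0.0
    return tree


def check_tree_coverage(tree: TreeNode, feature_ids) -> None:
    """Raise if any feature id lacks a tip on the tree."""
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(feature_ids) - tips)
    if missing:
        raise ValidationError(f"features missing from tree: {missing[:10]}")


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                seqs[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        elif name is not None:
            chunks.append(line.strip())
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
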