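"""Domain types and readers/writers for the formats the pipeline touches.

The pipeline works on three joint inputs: an OTU count table
(samples x OTUs), per-sample study metadata (participant, week, smoking,
health, sex, age) and a rooted phylogenetic tree over the OTUs. Tables are
read/written in two dialects: a classic tab-separated layout with OTUs as
rows and sample ids in the header, and the sparse BIOM v1 JSON schema.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

SMOKING_LEVELS = ("smoker", "nonsmoker")
HEALTH_LEVELS = ("healthy", "cold", "antibiotics")
SEX_LEVELS = ("male", "female")

METADATA_COLUMNS = ("sample_id", "participant_id", "week", "smoking",
                    "health", "sex", "age")


class ValidationError(ValueError):
    """Raised when an input violates a domain invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed under the requested dialect."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class OtuTable:
    """Integer read-count matrix (samples x OTUs) with identifiers.

    Parameters
    ----------
    counts
        Non-negative integer matrix, one row per sample.
    sample_ids, otu_ids
        Ordered, duplicate-free identifiers for rows and columns.
    taxonomy
        Optional map from otu_id to a lineage string.
    """

    counts: np.ndarray
    sample_ids: list[str]
    otu_ids: list[str]
    taxonomy: dict[str, str] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("counts must be integer-valued")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        self.counts = counts.astype(np.int64, copy=False)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.otu_ids)} OTUs)")
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.otu_ids, "otu_id")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids,
                            columns=self.otu_ids)

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        rows = [idx[s] for s in sample_ids]
        return OtuTable(self.counts[rows], list(sample_ids),
                        list(self.otu_ids), self.taxonomy)

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = {o: i for i, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in idx]
        if missing:
            raise ValidationError(f"unknown OTU ids: {missing}")
        cols = [idx[o] for o in otu_ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in otu_ids if o in self.taxonomy}
        return OtuTable(self.counts[:, cols], list(self.sample_ids),
                        list(otu_ids), tax)


@dataclass
class StudyMetadata:
    """Per-sample study labels: participant, week and disturbance status.

    The six participant states discussed in the analysis are the cross of
    smoking (smoker / nonsmoker, a press perturbation that stays in place)
    with health (healthy / cold / antibiotics, pulse perturbations).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["participant_id"] = df["participant_id"].astype(str)
        try:
            df["week"] = df["week"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-integer week value: {exc}") from exc
        if (df["week"] < 0).any():
            raise ValidationError("week must be >= 0")
        for col, levels in (("smoking", SMOKING_LEVELS),
                            ("health", HEALTH_LEVELS), ("sex", SEX_LEVELS)):
            bad = sorted(set(df[col]) - set(levels))
            if bad:
                raise ValidationError(
                    f"unknown {col} level(s) {bad}; expected one of {levels}")
        _check_unique(df["sample_id"], "sample_id")
        dup = df.duplicated(subset=["participant_id", "week"])
        if dup.any():
            pairs = df.loc[dup, ["participant_id", "week"]].values.tolist()
            raise ValidationError(f"duplicate (participant, week) pairs: {pairs}")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def participants(self) -> list[str]:
        return sorted(set(self.table["participant_id"]))

    def for_participant(self, participant_id: str) -> pd.DataFrame:
        """Rows for one participant, ordered by week (the time axis)."""
        sub = self.table[self.table["participant_id"] == participant_id]
        if sub.empty:
            raise ValidationError(f"unknown participant: {participant_id!r}")
        return sub.sort_values("week").reset_index(drop=True)

    def subset(self, sample_ids) -> "StudyMetadata":
        keep = self.table[self.table["sample_id"].isin(set(sample_ids))]
        return StudyMetadata(keep)


@dataclass
class PhyloTree:
    """Rooted phylogenetic tree over OTUs with non-negative branch lengths."""

    tree: TreeNode

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if any(n is None for n in names):
            raise ValidationError("tree has unlabelled leaves")
        _check_unique(names, "leaf label")
        defaulted = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                defaulted += 1
            elif node.length < 0:
                raise ValidationError(
                    f"negative branch length on {node.name!r}")
        if defaulted:
            logger.warning("tree: %d missing branch lengths set to 0", defaulted)
        if self.tree.length is None:
            self.tree.length = 0.0

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def patristic_distances(self, leaf_order: list[str]) -> np.ndarray:
        """Dense leaf-by-leaf patristic (branch-length-sum) distance matrix."""
        dm = self.tree.tip_tip_distances()
        missing = [x for x in leaf_order if x not in dm.ids]
        if missing:
            raise ValidationError(f"tree is missing leaves: {missing}")
        return dm.filter(leaf_order).data.copy()


@dataclass
class DissimilarityMatrix:
    """Square symmetric sample-by-sample dissimilarity matrix."""

    values: np.ndarray
    ids: list[str]
    metric: str

    _BOUNDS = {"bray_curtis": 1.0, "unifrac_unweighted": 1.0,
               "unifrac_weighted": 1.0, "hellinger": math.sqrt(2.0)}

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape/id mismatch")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValidationError("dissimilarity diagonal must be zero")
        if np.max(np.abs(v - v.T), initial=0.0) > 1e-12:
            raise ValidationError("dissimilarity matrix must be symmetric")
        if np.any(v < 0):
            raise ValidationError("dissimilarities must be >= 0")
        upper = self._BOUNDS.get(self.metric)
        if upper is not None and np.any(v > upper + 1e-9):
            raise ValidationError(
                f"{self.metric} values exceed upper bound {upper}")
        self.values = v
        self.ids = [str(s) for s in self.ids]

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy 'condensed' (pdist) order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]


# ---------------------------------------------------------------------------
# Readers / writers


def read_otu_table(path, dialect: str = "tsv",
                   samples_in_rows: bool = False) -> OtuTable:
    """Read an OTU table.

    ``tsv`` is the classic layout: OTUs as rows, first column OTU ids,
    header row of sample ids (flip with ``samples_in_rows``). ``biom_json``
    is the BIOM v1 JSON schema, sparse or dense.
    """
    if dialect == "tsv":
        return _read_tsv(path, samples_in_rows)
    if dialect == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_tsv(path, samples_in_rows: bool) -> OtuTable:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"cannot parse TSV table {path}: {exc}") from exc
    if df.empty:
        raise ParseError(f"empty table: {path}")
    values = df.to_numpy()
    if not np.all(np.isfinite(values.astype(float))):
        raise ParseError(f"non-finite counts in {path}")
    if samples_in_rows:
        sample_ids, otu_ids = list(df.index), list(df.columns)
    else:
        values = values.T
        sample_ids, otu_ids = list(df.columns), list(df.index)
    try:
        return OtuTable(values, sample_ids, otu_ids)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_otu_table(table: OtuTable, path, dialect: str = "tsv",
                    samples_in_rows: bool = False) -> None:
    if dialect == "tsv":
        df = table.to_dataframe()
        if not samples_in_rows:
            df = df.T
            df.index.name = "otu_id"
        else:
            df.index.name = "sample_id"
        df.to_csv(path, sep="\t")
    elif dialect == "biom_json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def _read_biom_json(path) -> OtuTable:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise ParseError(f"{path}: BIOM document missing field {key!r}")
    n_rows, n_cols = doc["shape"]
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(otu_ids) != n_rows or len(sample_ids) != n_cols:
        raise ParseError(f"{path}: shape does not match rows/columns")
    dense = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "sparse":
        for entry in doc["data"]:
            if len(entry) != 3:
                raise ParseError(f"{path}: bad sparse triple {entry!r}")
            i, j, v = entry
            dense[int(i), int(j)] = v
    elif doc["matrix_type"] == "dense":
        arr = np.asarray(doc["data"], dtype=float)
        if arr.shape != (n_rows, n_cols):
            raise ParseError(f"{path}: dense data shape mismatch")
        dense = arr
    else:
        raise ParseError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    taxonomy = None
    if any(r.get("metadata") and "taxonomy" in r["metadata"] for r in doc["rows"]):
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            if "taxonomy" in md:
                tax = md["taxonomy"]
                taxonomy[r["id"]] = (
                    "; ".join(tax) if isinstance(tax, list) else str(tax))
    try:
        return OtuTable(dense.T, sample_ids, otu_ids, taxonomy)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _write_biom_json(table: OtuTable, path) -> None:
    data = []
    mat = table.counts.T  # BIOM rows are observations (OTUs)
    for i, j in zip(*np.nonzero(mat)):
        data.append([int(i), int(j), int(mat[i, j])])
    rows = []
    for o in table.otu_ids:
        md = None
        if table.taxonomy and o in table.taxonomy:
            md = {"taxonomy": table.taxonomy[o]}
        rows.append({"id": o, "metadata": md})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "microstab",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_otus, table.n_samples],
        "rows": rows,
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_tree(path) -> PhyloTree:
    """Read a rooted Newick tree; missing branch lengths default to 0."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"cannot parse Newick file {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def read_metadata(path) -> StudyMetadata:
    """Read the per-sample metadata CSV (extra columns kept but ignored)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse metadata CSV {path}: {exc}") from exc
    return StudyMetadata(df)


def write_metadata(meta: StudyMetadata, path) -> None:
    meta.table.to_csv(path, index=False)


def validate_joint(table: OtuTable, metadata: StudyMetadata | None = None,
                   tree: PhyloTree | None = None) -> None:
    """Check that table, metadata and tree refer to the same entities.

    Mismatches raise; nothing is silently pruned.
    """
    if metadata is not None:
        meta_ids = set(metadata.sample_ids)
        missing = [s for s in table.sample_ids if s not in meta_ids]
        if missing:
            raise ValidationError(
                f"samples without metadata rows: {missing[:10]}")
    if tree is not None:
        leaves = set(tree.leaf_names)
        missing = [o for o in table.otu_ids if o not in leaves]
        if missing:
            raise ValidationError(
                f"OTUs missing from the tree: {missing[:10]}")
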