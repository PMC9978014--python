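"""Readers, writers and the domain containers shared by every pipeline stage.

All downstream modules consume only the types defined here: :class:`OtuTable`
(integer count matrix, samples x OTUs), :class:`RelAbundanceTable`
(row-stochastic proportions), :class:`Phylogeny` (rooted tree with branch
lengths whose tips are OTU ids) and :class:`EnvTable` (per-sample
environmental variables).

Id matching is exact and case-sensitive throughout: silent case-folding hides
upstream errors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("ecoassembly")

__all__ = [
    "FormatError",
    "AlignmentError",
    "DegenerateInputError",
    "OtuTable",
    "RelAbundanceTable",
    "Phylogeny",
    "EnvTable",
    "read_otu_table",
    "read_biom_json",
    "read_tree",
    "read_env_table",
    "read_matrix_tsv",
    "write_results",
]


class FormatError(ValueError):
    """A file does not conform to its expected external format."""


class AlignmentError(ValueError):
    """Sample or OTU ids do not line up between two inputs."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but too degenerate for the operation."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class OtuTable:
    """Integer OTU count matrix with samples as rows and OTUs as columns.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns OTU ids, non-negative
        integers. Every sample must have a positive total.
    taxonomy
        Optional mapping ``otu_id -> lineage string``.
    habitat
        Optional mapping ``sample_id -> group label`` (e.g. fruiting body
        vs mycosphere).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, str] | None = None
    habitat: dict[str, str] | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise FormatError("duplicated sample ids")
        if counts.columns.has_duplicates:
            raise FormatError("duplicated OTU ids")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric counts")
        if np.any(values < 0):
            raise FormatError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise FormatError("counts must be integers")
        self.counts = counts.astype(np.int64)
        totals = self.counts.sum(axis=1)
        if (totals <= 0).any():
            empty = list(totals.index[totals <= 0])
            raise DegenerateInputError(f"samples with zero total counts: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> "RelAbundanceTable":
        """Row-normalize counts to proportions (each row sums to 1)."""
        totals = self.counts.sum(axis=1)
        return RelAbundanceTable(self.counts.div(totals, axis=0))

    def subset(
        self,
        sample_ids: Sequence[str] | None = None,
        otu_ids: Sequence[str] | None = None,
        drop_empty_otus: bool = True,
    ) -> "OtuTable":
        """Restrict to the given samples/OTUs, dropping all-zero OTU columns.

        Samples that end up empty are rejected (they cannot be normalized).
        """
        counts = self.counts
        if sample_ids is not None:
            missing = set(sample_ids) - set(counts.index)
            if missing:
                raise AlignmentError(f"unknown sample ids: {sorted(missing)}")
            counts = counts.loc[list(sample_ids)]
        if otu_ids is not None:
            missing = set(otu_ids) - set(counts.columns)
            if missing:
                raise AlignmentError(f"unknown OTU ids: {sorted(missing)}")
            counts = counts[list(otu_ids)]
        if drop_empty_otus:
            counts = counts.loc[:, counts.sum(axis=0) > 0]
        taxonomy = (
            {o: self.taxonomy[o] for o in counts.columns if o in self.taxonomy}
            if self.taxonomy
            else None
        )
        habitat = (
            {s: self.habitat[s] for s in counts.index if s in self.habitat}
            if self.habitat
            else None
        )
        return OtuTable(counts.copy(), taxonomy=taxonomy, habitat=habitat)


@dataclass
class RelAbundanceTable:
    """Row-stochastic relative-abundance matrix (same axes as OtuTable)."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.proportions.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise FormatError("proportions must lie in [0, 1]")
        row_sums = values.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise FormatError("each sample's proportions must sum to 1")
        self.proportions = self.proportions.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.proportions.columns)


class Phylogeny:
    """Rooted tree with non-negative branch lengths; tips are OTU ids.

    Thin wrapper around a :class:`dendropy.Tree` adding validation and a
    cached patristic (path-length) distance matrix.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise FormatError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate tip labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise FormatError("negative branch length in tree")
        self._tip_labels = labels
        self._pdm_cache: pd.DataFrame | None = None

    @property
    def tip_labels(self) -> list[str]:
        return list(self._tip_labels)

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def patristic_matrix(self, otu_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Pairwise tip-to-tip path-length distances.

        Symmetric with zero diagonal. ``otu_ids`` selects/orders a subset;
        ids missing from the tree raise :class:`AlignmentError`.
        """
        if self._pdm_cache is None:
            pdm = self.tree.phylogenetic_distance_matrix()
            taxa = list(self.tree.taxon_namespace)
            labels = [t.label for t in taxa]
            n = len(labels)
            mat = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    d = pdm.patristic_distance(taxa[i], taxa[j])
                    mat[i, j] = mat[j, i] = d
            self._pdm_cache = pd.DataFrame(mat, index=labels, columns=labels)
        full = self._pdm_cache
        if otu_ids is None:
            return full
        missing = [o for o in otu_ids if o not in full.index]
        if missing:
            raise AlignmentError(f"OTUs missing from tree: {missing}")
        return full.loc[list(otu_ids), list(otu_ids)]

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class EnvTable:
    """Per-sample environmental variables (soil chemistry, VOCs, climate...).

    ``units`` documents the unit of each column when known.
    """

    values: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicated sample ids in environmental table")
        all_missing = [c for c in self.values.columns if self.values[c].isna().all()]
        if all_missing:
            raise FormatError(f"all-missing environmental columns: {all_missing}")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def align_to(self, sample_ids: Sequence[str]) -> "EnvTable":
        """Reorder to the given samples; error if there is no overlap."""
        overlap = [s for s in sample_ids if s in self.values.index]
        if not overlap:
            raise AlignmentError(
                "no overlap between environmental table and OTU table sample ids"
            )
        return EnvTable(self.values.loc[overlap].copy(), units=dict(self.units))


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _orient_samples_by_rows(df: pd.DataFrame, orientation: str) -> pd.DataFrame:
    if orientation == "otus_as_rows":
        return df.T
    if orientation == "samples_as_rows":
        return df
    if orientation != "auto":
        raise ValueError(f"unknown orientation: {orientation!r}")

    # Auto-detection. Label hints ("OTU..." ids) win; otherwise community
    # surveys have many more OTUs than samples, so a strongly longer axis is
    # taken as OTUs; near-square tables fall back to the conventional
    # OTUs-as-rows layout.
    def _otu_like(labels) -> bool:
        hits = sum(1 for x in labels if str(x).lower().startswith("otu"))
        return hits >= 0.9 * len(labels)

    rows_otu, cols_otu = _otu_like(df.index), _otu_like(df.columns)
    if rows_otu and not cols_otu:
        return df.T
    if cols_otu and not rows_otu:
        return df
    if df.shape[0] > df.shape[1]:
        return df.T
    if df.shape[1] >= 3 * df.shape[0]:
        return df
    return df.T


def read_otu_table(
    path: str | Path,
    min_count: int = 2,
    taxonomy_column: str | None = None,
    orientation: str = "auto",
) -> OtuTable:
    """Read a tab-separated OTU table and drop low-count OTUs.

    The conventional layout has the first column holding OTU ids and the
    header row holding sample ids; a transposed file is detected and
    normalized (``orientation='auto'``). OTUs whose total count across all
    samples is below ``min_count`` are removed; the default of 2 removes
    singletons, the usual filter applied when OTU tables are built.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    taxonomy = None
    if taxonomy_column is not None:
        axis = 0 if taxonomy_column in df.columns else None
        if axis is None:
            raise FormatError(f"taxonomy column {taxonomy_column!r} not found")
        taxonomy = df[taxonomy_column].astype(str).to_dict()
        df = df.drop(columns=[taxonomy_column])
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in OTU table: {exc}") from exc
    df = _orient_samples_by_rows(df, orientation)
    table = OtuTable(df, taxonomy=taxonomy)
    keep = table.counts.sum(axis=0) >= min_count
    counts = table.counts.loc[:, keep]
    if counts.shape[1] == 0 or (counts.sum(axis=1) <= 0).any():
        raise DegenerateInputError(
            f"sample(s) left empty after min_count={min_count} filtering"
        )
    return OtuTable(counts, taxonomy=taxonomy)


def read_biom_json(path: str | Path, min_count: int = 2) -> OtuTable:
    """Read a BIOM 1.0 (JSON) table; supports dense and sparse matrices."""
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if doc.get("matrix_type") == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        mat[:] = np.asarray(doc["data"], dtype=float)
    taxonomy = None
    if any(r.get("metadata") and r["metadata"].get("taxonomy") for r in doc["rows"]):
        taxonomy = {}
        for r in doc["rows"]:
            md = r.get("metadata") or {}
            tax = md.get("taxonomy")
            if tax is not None:
                taxonomy[r["id"]] = "; ".join(tax) if isinstance(tax, list) else str(tax)
    df = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids)
    table = OtuTable(df, taxonomy=taxonomy)
    keep = table.counts.sum(axis=0) >= min_count
    return OtuTable(table.counts.loc[:, keep], taxonomy=taxonomy)


def read_tree(path: str | Path) -> Phylogeny:
    """Read a rooted newick tree with branch lengths."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"malformed newick file: {exc}") from exc
    return Phylogeny(tree)


def tree_from_string(newick: str) -> Phylogeny:
    """Parse a newick string (convenience used by tests and the simulator)."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"malformed newick string: {exc}") from exc
    return Phylogeny(tree)


def read_env_table(path: str | Path) -> EnvTable:
    """Read a CSV of per-sample environmental variables (rows = samples).

    Non-numeric cells become missing values with a logged warning; downstream
    operations use pairwise-complete handling, never silent imputation.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    coerced = df.apply(pd.to_numeric, errors="coerce")
    n_bad = int((coerced.isna() & df.notna()).sum().sum())
    if n_bad:
        logger.warning(
            "read_env_table: %d non-numeric cell(s) converted to missing", n_bad
        )
    env = EnvTable(coerced)
    for col in env.variables:
        series = env.values[col].dropna()
        if len(series) > 1 and series.nunique() == 1:
            logger.warning("read_env_table: column %r has zero variance", col)
    return env


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a square labelled matrix (e.g. a betaNTI matrix) from TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_FLOAT_SIG_DIGITS = 6


def _round_sig(x: float, sig: int = _FLOAT_SIG_DIGITS) -> float:
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _jsonify(obj: Any) -> Any:
    """Recursively convert results to deterministic JSON-serializable form."""
    if isinstance(obj, Mapping):
        return {str(k): _jsonify(obj[k]) for k in obj}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else _round_sig(v)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.Series):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return {
            "index": [str(i) for i in obj.index],
            "columns": [str(c) for c in obj.columns],
            "data": _jsonify(obj.to_numpy().tolist()),
        }
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if hasattr(obj, "to_dict"):
        return _jsonify(obj.to_dict())
    return obj


def write_results(result: Any, path: str | Path, format: str = "json") -> None:
    """Write a result object deterministically (sorted keys, 6 sig digits).

    ``format`` is one of ``json`` (any result exposing ``to_dict`` or a
    mapping), ``tsv`` (DataFrame/Series) or ``graphml`` (networkx graphs).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonify(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif format == "tsv":
        if isinstance(result, pd.Series):
            result = result.to_frame()
        if not isinstance(result, pd.DataFrame):
            raise ValueError("tsv output requires a DataFrame or Series")
        result.to_csv(path, sep="\t", float_format=f"%.{_FLOAT_SIG_DIGITS}g")
    elif format == "graphml":
        import networkx as nx

        if not isinstance(result, nx.Graph):
            raise ValueError("graphml output requires a networkx graph")
        nx.write_graphml(result, path)
    else:
        raise ValueError(f"unsupported output format: {format!r}")
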