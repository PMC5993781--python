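"""Cohort file I/O and cross-validation.

Canonical on-disk dialect: tab-separated tables with a header row and the
first column as row label; trees are newick. Counts are non-negative
integers keyed by sample id; metadata carries the infant id, the day of
life (day 1 = first day of life) and, optionally, the preservation method
of the specimen. Missing values in real-valued tables are written as "NA";
counts may never be missing.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

PRESERVATION_VALUES = ("frozen", "ethanol", "unknown")
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")

MAX_DAY = 400
MIN_SAMPLES_PER_INFANT = 4


class TableParseError(ValueError):
    """A table could not be parsed into the expected numeric form."""


class CohortValidationError(ValueError):
    """The loaded tables are mutually inconsistent or violate invariants."""


@dataclasses.dataclass
class Cohort:
    """A cross-validated bundle of counts, taxonomy, sample metadata and tree.

    ``counts`` is samples x OTUs (integer), rows ordered by
    (infant_id, day_since_birth, sample_id); ``taxonomy`` is indexed by OTU id
    with the ranked lineage columns; ``meta`` is indexed by sample id, aligned
    row-for-row with ``counts``; ``tree`` is an optional rooted phylogeny whose
    leaves cover the count-table OTUs.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    meta: pd.DataFrame
    tree: TreeNode | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def infant_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for inf in self.meta["infant_id"]:
            seen.setdefault(inf, None)
        return list(seen)

    def require_tree(self) -> TreeNode:
        if self.tree is None:
            raise CohortValidationError(
                "this operation requires a phylogeny but the cohort was loaded without one"
            )
        return self.tree


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", index_col=0, comment="#", na_values=["NA"])


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a samples x OTUs count table, enforcing non-negative integers."""
    df = _read_tsv(path)
    if df.isna().any().any():
        row, col = _first_offender(df.isna())
        raise TableParseError(f"missing count at sample {row!r}, OTU {col!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        row, col = _first_offender(bad)
        raise TableParseError(f"non-numeric count at sample {row!r}, OTU {col!r}")
    if (values < 0).any():
        row, col = _first_offender(df < 0)
        raise TableParseError(f"negative count at sample {row!r}, OTU {col!r}")
    if np.any(values != np.floor(values)):
        row, col = _first_offender(df != np.floor(df))
        raise TableParseError(f"non-integer count at sample {row!r}, OTU {col!r}")
    out = df.astype(np.int64)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    out.index.name = "sample_id"
    return out


def _first_offender(mask: pd.DataFrame) -> tuple[str, str]:
    stacked = mask.stack()
    row, col = stacked[stacked].index[0]
    return str(row), str(col)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read an OTU -> ranked-lineage table; lower ranks default to 'unclassified'."""
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    df.index.name = "otu_id"
    missing = [r for r in TAXONOMY_RANKS if r not in df.columns]
    if missing:
        raise TableParseError(f"taxonomy table lacks rank columns: {missing}")
    for rank in TAXONOMY_RANKS:
        df[rank] = df[rank].fillna("unclassified").astype(str)
    if "assignment_probability" in df.columns:
        prob = df["assignment_probability"].astype(float)
        if ((prob < 0) | (prob > 1)).any():
            raise TableParseError("assignment_probability outside [0, 1]")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, infant_id, day_since_birth[, preservation])."""
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    for col in ("infant_id", "day_since_birth"):
        if col not in df.columns:
            raise TableParseError(f"metadata lacks required column {col!r}")
    day = df["day_since_birth"]
    if day.isna().any() or np.any(day.to_numpy() != np.floor(day.to_numpy())):
        raise TableParseError("day_since_birth must be integral")
    df["day_since_birth"] = day.astype(np.int64)
    df["infant_id"] = df["infant_id"].astype(str)
    if "preservation" not in df.columns:
        df["preservation"] = "unknown"
    df["preservation"] = df["preservation"].fillna("unknown").astype(str)
    bad = sorted(set(df["preservation"]) - set(PRESERVATION_VALUES))
    if bad:
        raise TableParseError(f"unknown preservation values: {bad}")
    return df


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise CohortValidationError(f"negative branch length on node {node.name!r}")
    return tree


def validate_cohort(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    tree: TreeNode | None = None,
) -> Cohort:
    """Cross-validate the tables and return a row-ordered :class:`Cohort`.

    Rows are sorted by (infant_id, day_since_birth, sample_id) so loading is
    order-stable regardless of on-disk row order.
    """
    if meta.index.has_duplicates:
        dups = sorted(meta.index[meta.index.duplicated()].unique())
        raise CohortValidationError(f"duplicate sample ids in metadata: {dups}")
    count_samples = set(counts.index)
    meta_samples = set(meta.index)
    if count_samples != meta_samples:
        only_counts = sorted(count_samples - meta_samples)
        only_meta = sorted(meta_samples - count_samples)
        raise CohortValidationError(
            "sample ids disagree between counts and metadata; "
            f"counts-only={only_counts[:10]}, metadata-only={only_meta[:10]}"
        )
    missing_tax = sorted(set(counts.columns) - set(taxonomy.index))
    if missing_tax:
        raise CohortValidationError(
            f"OTUs present in counts but absent from taxonomy: {missing_tax[:10]}"
        )
    day = meta["day_since_birth"]
    if ((day < 0) | (day > MAX_DAY)).any():
        bad = sorted(meta.index[(day < 0) | (day > MAX_DAY)])
        raise CohortValidationError(f"day_since_birth outside [0, {MAX_DAY}]: {bad[:10]}")
    zero = counts.sum(axis=1) == 0
    if zero.any():
        raise CohortValidationError(
            f"all-zero sample rows: {sorted(counts.index[zero])[:10]}"
        )
    per_infant = meta.groupby("infant_id")["day_since_birth"]
    too_few = [
        inf
        for inf, days in per_infant
        if len(days) < MIN_SAMPLES_PER_INFANT or days.nunique() < 2
    ]
    if too_few:
        raise CohortValidationError(
            f"infants with < {MIN_SAMPLES_PER_INFANT} samples or < 2 distinct days: {too_few}"
        )
    if tree is not None:
        leaves = {leaf.name for leaf in tree.tips()}
        missing_leaves = sorted(set(counts.columns) - leaves)
        if missing_leaves:
            raise CohortValidationError(
                f"count-table OTUs missing from tree leaves: {missing_leaves[:10]}"
            )
    order = meta.sort_values(
        ["infant_id", "day_since_birth"], kind="mergesort"
    ).index
    # mergesort is stable; equal (infant, day) pairs fall back to index order,
    # which we make deterministic by a secondary sort on sample id
    order = (
        meta.assign(_sid=meta.index)
        .sort_values(["infant_id", "day_since_birth", "_sid"], kind="mergesort")
        .index
    )
    meta = meta.loc[order]
    counts = counts.loc[order]
    return Cohort(counts=counts, taxonomy=taxonomy, meta=meta, tree=tree)


def load_cohort(
    counts_path: str | Path,
    taxonomy_path: str | Path,
    metadata_path: str | Path,
    tree_path: str | Path | None = None,
) -> Cohort:
    """Load and cross-validate the full input bundle from TSV/newick files."""
    counts = read_counts(counts_path)
    taxonomy = read_taxonomy(taxonomy_path)
    meta = read_metadata(metadata_path)
    tree = read_tree(tree_path) if tree_path is not None else None
    cohort = validate_cohort(counts, taxonomy, meta, tree)
    logger.info(
        "loaded cohort: %d samples, %d OTUs, %d infants, tree=%s",
        len(cohort.counts),
        len(cohort.counts.columns),
        len(cohort.infant_ids),
        "yes" if tree is not None else "no",
    )
    return cohort


# ---------------------------------------------------------------------------
# matrix / series round-trip I/O (12 significant digits)

_FLOAT_FMT = "%.12g"


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    """Write a labeled square distance matrix as TSV (12 significant digits)."""
    if d.shape[0] == 0:
        raise ValueError("refusing to write an empty distance matrix")
    df = pd.DataFrame(d.data, index=d.ids, columns=d.ids)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="id")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = _read_tsv(path)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_series_table(values: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled rectangular table of reals as TSV; NaN becomes "NA"."""
    values = _as_rectangular_frame(values)
    values.to_csv(path, sep="\t", float_format=_FLOAT_FMT, na_rep="NA")


def read_series_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _as_rectangular_frame(values) -> pd.DataFrame:
    if isinstance(values, pd.DataFrame):
        return values
    if isinstance(values, pd.Series):
        return values.to_frame().T
    rows = list(values)
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged input: row lengths {sorted(lengths)}")
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write counts/taxonomy/metadata (and tree when present) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
    }
    cohort.counts.to_csv(paths["counts"], sep="\t")
    cohort.taxonomy.to_csv(paths["taxonomy"], sep="\t")
    cohort.meta.to_csv(paths["metadata"], sep="\t")
    if cohort.tree is not None:
        paths["tree"] = out / "tree.nwk"
        cohort.tree.write(str(paths["tree"]), format="newick")
    return paths


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logs to stderr, used by the CLI and analysis drivers."""
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
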