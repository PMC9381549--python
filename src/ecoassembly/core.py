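"""Core data containers, file I/O and table-level filters and transforms.

The canonical in-memory layout is *samples as rows, taxa as columns*; files on
disk may use either orientation.  Counts are non-negative integers (amplicon
sequence variant read counts); relative-abundance tables carry per-sample
proportions obtained by total-sum scaling.  Trees are rooted
:class:`skbio.TreeNode` objects with non-negative branch lengths, and sample
distance matrices are :class:`skbio.DistanceMatrix` objects throughout.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

ORIENT_SAMPLES = "samples-as-rows"
ORIENT_TAXA = "taxa-as-rows"


def _check_unique(labels: Iterable[str], what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValueError(f"duplicate {what} id(s): {dups}")


@dataclass(frozen=True)
class CountTable:
    """Integer abundance table, samples as rows and taxa as columns.

    Invariants enforced on construction: unique sample and taxon ids, at least
    one of each, and non-negative integer counts.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValueError("a count table needs at least one sample and one taxon")
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "taxon")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("counts must be numeric")
        bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"count at sample {df.index[i]!r}, taxon {df.columns[j]!r} "
                f"is not a non-negative integer: {values[i, j]!r}"
            )
        if not np.issubdtype(values.dtype, np.integer):
            object.__setattr__(self, "data", df.astype(np.int64))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def write(self, path: str | Path, orientation: str = ORIENT_SAMPLES) -> None:
        df = self.data if orientation == ORIENT_SAMPLES else self.data.T
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample proportions on the same axes as :class:`CountTable`.

    Every row sums to 1 (zero-total rows are forbidden upstream).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "sample")
        _check_unique(df.columns, "taxon")
        values = df.to_numpy(dtype=float)
        if ((values < 0) | (values > 1)).any():
            raise ValueError("relative abundances must lie in [0, 1]")
        sums = values.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = df.index[np.argmax(np.abs(sums - 1.0))]
            raise ValueError(f"row {bad!r} does not sum to 1 (got {sums.max():.6g})")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)


class PrevalenceFilterReport(NamedTuple):
    n_taxa_removed: int
    removed_taxon_fraction: float
    removed_read_fraction: float


class RarefactionResult(NamedTuple):
    table: CountTable
    dropped_samples: tuple[str, ...]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path, orientation: str = ORIENT_SAMPLES) -> CountTable:
    """Read a tab-separated count table; ``orientation`` names the file layout."""
    if orientation not in (ORIENT_SAMPLES, ORIENT_TAXA):
        raise ValueError(f"orientation must be {ORIENT_SAMPLES!r} or {ORIENT_TAXA!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == ORIENT_TAXA:
        df = df.T
    return CountTable(df)


def read_tree(source: str | Path) -> TreeNode:
    """Read a rooted Newick tree and validate branch lengths.

    A missing length on the root edge is treated as 0; any other missing or
    negative length is an error.
    """
    try:
        tree = TreeNode.read(str(source), format="newick")
    except Exception as exc:  # skbio raises format-specific parse errors
        raise ValueError(f"could not parse Newick tree from {source}: {exc}") from exc
    return validate_tree(tree)


def parse_tree(newick: str) -> TreeNode:
    """Parse a Newick string (convenience counterpart of :func:`read_tree`)."""
    try:
        tree = TreeNode.read([newick], format="newick")
    except Exception as exc:
        raise ValueError(f"could not parse Newick string: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: TreeNode) -> TreeNode:
    if tree.length is None:
        tree.length = 0.0
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise ValueError("tree has unnamed tips")
    _check_unique(names, "tip")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"branch above {node.name or 'an internal node'} has no length")
        if node.length < 0:
            raise ValueError(
                f"negative branch length {node.length} above {node.name or 'an internal node'}"
            )
    return tree


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV keyed on its first column (sample id)."""
    md = pd.read_csv(path, sep="\t", index_col=0)
    md.index = md.index.astype(str)
    _check_unique(md.index, "sample")
    return md


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    """Read a taxonomy TSV keyed on its first column (taxon id), ranks as columns."""
    tax = pd.read_csv(path, sep="\t", index_col=0)
    tax.index = tax.index.astype(str)
    _check_unique(tax.index, "taxon")
    return tax


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.write(str(path), format="lsmat")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    return DistanceMatrix.read(str(path), format="lsmat")


# ---------------------------------------------------------------------------
# filters and transforms
# ---------------------------------------------------------------------------

def filter_by_taxonomy(
    table: CountTable,
    taxonomy: pd.DataFrame,
    exclude_patterns: Sequence[tuple[str, str]],
    strict: bool = True,
) -> CountTable:
    """Remove taxa whose lineage matches any ``(rank, value)`` pattern.

    Matching is case-insensitive on the full rank value (e.g. remove
    chloroplast/mitochondrial/archaeal reads before analysis).  Taxa missing
    from the taxonomy raise in strict mode and are kept in lenient mode.
    Samples are retained even if they end up empty.
    """
    missing = [t for t in table.taxon_ids if t not in taxonomy.index]
    if missing and strict:
        raise ValueError(f"taxa absent from taxonomy table: {missing[:10]}")
    drop: set[str] = set()
    for rank, value in exclude_patterns:
        if rank not in taxonomy.columns:
            continue
        col = taxonomy[rank].astype(str).str.casefold()
        drop.update(taxonomy.index[col == str(value).casefold()])
    keep = [t for t in table.taxon_ids if t not in drop]
    if not keep:
        raise ValueError("taxonomy filter removed every taxon")
    return CountTable(table.data[keep])


def filter_low_prevalence(
    table: CountTable, min_total_reads: int
) -> tuple[CountTable, PrevalenceFilterReport]:
    """Drop taxa whose total read count across samples is *strictly below*
    ``min_total_reads`` (taxa exactly at the threshold are kept)."""
    if min_total_reads < 0:
        raise ValueError("min_total_reads must be >= 0")
    totals = table.taxon_totals()
    keep = totals.index[totals >= min_total_reads]
    if len(keep) == 0:
        raise ValueError(f"no taxon reaches {min_total_reads} reads; table would be empty")
    removed_reads = float(totals.sum() - totals[keep].sum())
    report = PrevalenceFilterReport(
        n_taxa_removed=len(totals) - len(keep),
        removed_taxon_fraction=(len(totals) - len(keep)) / len(totals),
        removed_read_fraction=removed_reads / float(totals.sum()) if totals.sum() else 0.0,
    )
    return CountTable(table.data[list(keep)]), report


def rarefy(table: CountTable, depth: int, seed: int) -> RarefactionResult:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped (with a warning naming
    them), mirroring standard rarefaction practice.  The draw is multivariate
    hypergeometric and deterministic given ``seed``.
    """
    if depth < 1:
        raise ValueError("rarefaction depth must be >= 1")
    totals = table.sample_totals()
    keep = totals.index[totals >= depth]
    dropped = tuple(totals.index[totals < depth])
    if len(keep) == 0:
        raise ValueError(f"rarefaction depth {depth} exceeds every sample total")
    if dropped:
        logger.warning(
            "rarefaction at depth %d dropped %d sample(s): %s", depth, len(dropped), list(dropped)
        )
    rng = np.random.default_rng(seed)
    out = np.empty((len(keep), table.shape[1]), dtype=np.int64)
    data = table.data.loc[keep].to_numpy()
    for i in range(len(keep)):
        out[i] = rng.multivariate_hypergeometric(data[i], depth)
    rarefied = CountTable(pd.DataFrame(out, index=keep, columns=table.data.columns))
    return RarefactionResult(rarefied, dropped)


def to_relative_abundance(table: CountTable) -> RelAbundanceTable:
    """Total-sum scaling: divide each sample's counts by its total."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero)}")
    return RelAbundanceTable(table.data.div(totals, axis=0))


def align_table_and_tree(table: CountTable, tree: TreeNode) -> tuple[CountTable, TreeNode]:
    """Prune the tree to the table's taxa; error if any table taxon lacks a tip."""
    tips = {t.name for t in tree.tips()}
    missing = [t for t in table.taxon_ids if t not in tips]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing[:10]}")
    if tips == set(table.taxon_ids):
        return table, tree
    pruned = tree.shear(table.taxon_ids)
    pruned.prune()
    if pruned.length is None:
        pruned.length = 0.0
    return table, pruned
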