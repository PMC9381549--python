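"""α-diversity (richness, Shannon, Faith's PD) and β-diversity (Bray–Curtis,
abundance-weighted βMNTD).

Conventions: Shannon entropy uses the natural log; Faith's phylogenetic
diversity is *rooted* PD (the branch path from the present tips up to the
root is included, so the PD of the full community equals the tree's total
branch length).  βMNTD between communities k and m is

    0.5 * [ Σ_{i∈k} f_ik · min_{j∈m} d(i, j)  +  Σ_{j∈m} f_jm · min_{i∈k} d(j, i) ]

with f the within-sample relative abundances and d the patristic distance;
a taxon present in both communities has nearest-relative distance 0, so
βMNTD of a community with itself is 0.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .core import CountTable, RelAbundanceTable

logger = logging.getLogger(__name__)


def _abundance_frame(table: CountTable | RelAbundanceTable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(table, (CountTable, RelAbundanceTable)):
        return table.data
    return table


def alpha_diversity(
    table: CountTable | RelAbundanceTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon index (nats) and Faith's PD.

    Accepts counts or relative abundances (Shannon is scale invariant).  An
    empty sample yields (0, 0, 0) with a logged warning rather than an error.
    Faith's PD requires ``tree`` to cover every taxon in the table.
    """
    df = _abundance_frame(table)
    x = df.to_numpy(dtype=float)
    totals = x.sum(axis=1)
    empty = totals == 0
    if empty.any():
        logger.warning("empty sample(s): %s", list(df.index[empty]))
    present = x > 0
    richness = present.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals[:, None] > 0, x / np.where(totals[:, None] == 0, 1, totals[:, None]), 0.0)
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    out = pd.DataFrame({"richness": richness, "shannon": shannon}, index=df.index)
    if tree is not None:
        out["faith_pd"] = _faith_pd(present, list(df.columns), tree)
    return out


def _faith_pd(presence: np.ndarray, taxa: list[str], tree: TreeNode) -> np.ndarray:
    """Rooted Faith's PD for each presence row (branch × tip membership matrix)."""
    tip_index = {t: i for i, t in enumerate(taxa)}
    missing = [t.name for t in tree.tips() if t.name not in tip_index]
    extra = set(tip_index) - {t.name for t in tree.tips()}
    if extra:
        raise ValueError(f"taxa missing from the tree: {sorted(extra)[:10]}")
    if missing:
        raise ValueError(
            f"tree has tips absent from the table (align first): {missing[:10]}"
        )
    branches: list[tuple[float, np.ndarray]] = []
    membership: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=False):
        if node.is_tip():
            mask = np.zeros(len(taxa), dtype=bool)
            mask[tip_index[node.name]] = True
        else:
            mask = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                mask |= membership[id(child)]
        membership[id(node)] = mask
        branches.append((float(node.length or 0.0), mask))
    lengths = np.array([b[0] for b in branches])
    masks = np.array([b[1] for b in branches])  # (branches, taxa)
    covered = presence @ masks.T > 0  # (samples, branches)
    return covered @ lengths


def bray_curtis(rel_table: RelAbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity on total-sum-scaled abundances, in [0, 1]."""
    if not isinstance(rel_table, RelAbundanceTable):
        raise TypeError("bray_curtis expects a RelAbundanceTable (total-sum-scale first)")
    x = rel_table.data.to_numpy(dtype=float)
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(d, ids=rel_table.sample_ids)


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Sum of branch lengths along the unique path between every tip pair."""
    return tree.tip_tip_distances()


def _beta_mntd_from_arrays(F: np.ndarray, P: np.ndarray, D: np.ndarray) -> np.ndarray:
    """βMNTD for all sample pairs.

    F: (S, T) relative abundances; P: (S, T) presence; D: (T, T) patristic.
    Uses, per sample m, the vector of distances from every taxon to its
    nearest member of m; the pair statistic is then a weighted dot product.
    """
    S, T = F.shape
    mins = np.empty((S, T))
    for m in range(S):
        cols = P[m]
        if not cols.any():
            raise ValueError(f"sample index {m} has no taxa present")
        mins[m] = D[:, cols].min(axis=1)
    B = F @ mins.T  # B[k, m] = sum_i f_ik * min_{j in m} d(i, j)
    return 0.5 * (B + B.T)


def beta_mntd(rel_table: RelAbundanceTable, tree: TreeNode) -> DistanceMatrix:
    """Abundance-weighted β mean-nearest-taxon distance between all sample pairs."""
    taxa = rel_table.taxon_ids
    pat = patristic_distances(tree)
    missing = [t for t in taxa if t not in pat.ids]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing[:10]}")
    order = [pat.ids.index(t) for t in taxa]
    D = pat.data[np.ix_(order, order)]
    F = rel_table.data.to_numpy(dtype=float)
    P = F > 0
    empty = ~P.any(axis=1)
    if empty.any():
        raise ValueError(f"empty sample(s): {list(rel_table.data.index[empty])}")
    out = _beta_mntd_from_arrays(F, P, D)
    np.fill_diagonal(out, 0.0)
    return DistanceMatrix(out, ids=rel_table.sample_ids)
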