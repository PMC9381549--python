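"""Per-pair quantification of community assembly processes.

The workflow follows the phylogenetic null-model framework widely used for
microbial communities:

* βNTI — the observed abundance-weighted βMNTD of each sample pair is
  compared with a null distribution obtained by shuffling the taxon↔tip
  assignment across the phylogeny (names and abundances move together;
  topology and branch lengths are fixed).  βNTI is the z-score
  (obs − null mean) / null sd.  |βNTI| > 2 indicates deterministic
  selection: βNTI < −2 homogeneous selection, βNTI > +2 variable selection.
* RC_Bray — for pairs not dominated by selection, the observed Bray–Curtis
  dissimilarity is ranked within a probabilistic null that reassembles each
  sample at its observed richness and read depth, drawing taxa with
  probability proportional to regional occupancy and filling reads with
  probability proportional to regional relative abundance.  The rank is
  rescaled to [−1, 1]; beyond ±0.95 indicates dispersal-driven structure
  (< −0.95 homogenizing dispersal, > +0.95 dispersal limitation), otherwise
  the pair is undominated (drift).

Threshold comparisons are strict; values exactly at a threshold fall through
to the next rule.  Pairs whose null βMNTD distribution has zero spread are
flagged degenerate and excluded from process fractions.
"""
from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import CountTable, RelAbundanceTable, to_relative_abundance
from .diversity import _beta_mntd_from_arrays, patristic_distances

logger = logging.getLogger(__name__)

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "homogenizing_dispersal",
    "dispersal_limitation",
    "undominated",
)


def _pair_index(sample_ids: list[str]) -> pd.MultiIndex:
    ii, jj = np.triu_indices(len(sample_ids), k=1)
    return pd.MultiIndex.from_arrays(
        [np.asarray(sample_ids)[ii], np.asarray(sample_ids)[jj]],
        names=("sample_a", "sample_b"),
    )


def bnti(
    rel_table: RelAbundanceTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """β-nearest taxon index for every unordered sample pair.

    One taxon↔tip permutation is drawn per null iteration (a single shared
    stream serves all pairs of that iteration) from
    ``numpy.random.default_rng(seed)``; βMNTD is recomputed for all pairs on
    the permuted patristic lookup.  Returns a frame indexed by
    (sample_a, sample_b) with columns ``bmntd_obs``, ``null_mean``,
    ``null_sd``, ``bnti`` and ``degenerate``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    taxa = rel_table.taxon_ids
    pat = patristic_distances(tree)
    missing = [t for t in taxa if t not in pat.ids]
    if missing:
        raise ValueError(f"taxa missing from the tree: {missing[:10]}")
    order = [pat.ids.index(t) for t in taxa]
    D = pat.data[np.ix_(order, order)]
    F = rel_table.data.to_numpy(dtype=float)
    P = F > 0
    S, T = F.shape
    obs = _beta_mntd_from_arrays(F, P, D)
    rng = np.random.default_rng(seed)
    mean = np.zeros((S, S))
    m2 = np.zeros((S, S))
    for it in range(n_null):
        perm = rng.permutation(T)
        null = _beta_mntd_from_arrays(F, P, D[np.ix_(perm, perm)])
        delta = null - mean
        mean += delta / (it + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / n_null)  # population sd of the null distribution
    ii, jj = np.triu_indices(S, k=1)
    obs_p, mean_p, sd_p = obs[ii, jj], mean[ii, jj], sd[ii, jj]
    degenerate = sd_p == 0
    z = np.zeros_like(obs_p)
    ok = ~degenerate
    z[ok] = (obs_p[ok] - mean_p[ok]) / sd_p[ok]
    # degenerate pairs: 0 when obs equals the constant null, +/-inf sentinel otherwise
    same = degenerate & np.isclose(obs_p, mean_p)
    z[degenerate & ~same] = np.sign(obs_p - mean_p)[degenerate & ~same] * np.inf
    if degenerate.any():
        logger.warning("%d pair(s) have a degenerate (zero-sd) null distribution", degenerate.sum())
    return pd.DataFrame(
        {
            "bmntd_obs": obs_p,
            "null_mean": mean_p,
            "null_sd": sd_p,
            "bnti": z,
            "degenerate": degenerate,
        },
        index=_pair_index(rel_table.sample_ids),
    )


def _null_assemblages(
    richness: int,
    depth: int,
    occupancy_p: np.ndarray,
    abundance: np.ndarray,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n_null`` probabilistic null communities for one sample.

    Taxa are drawn without replacement with probability ∝ occupancy; each
    drawn taxon receives one read and the remaining reads are assigned
    multinomially with probability ∝ regional relative abundance among the
    drawn taxa.
    """
    T = occupancy_p.size
    out = np.zeros((n_null, T), dtype=np.int64)
    for i in range(n_null):
        chosen = rng.choice(T, size=richness, replace=False, p=occupancy_p, shuffle=False)
        out[i, chosen] = 1
        rest = depth - richness
        if rest > 0:
            p = abundance[chosen]
            out[i, chosen] += rng.multinomial(rest, p / p.sum())
    return out


def rc_bray(
    table: CountTable, n_null: int = 999, seed: int | None = None
) -> pd.DataFrame:
    """Bray–Curtis-based Raup–Crick score for every unordered sample pair.

    The regional pool is the full input table: occupancy = fraction of
    samples a taxon occupies, regional abundance = its share of total reads.
    Each sample's null assemblages are generated once from a per-sample
    substream (seeded by (seed, sample index)) and reused across its pairs.
    RC = 2·([#(null < obs) + ½·#(null = obs)] / n_null − ½) ∈ [−1, 1].
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    counts = table.data.to_numpy()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(f"zero-total sample(s): {list(table.data.index[totals == 0])}")
    S, T = counts.shape
    occupancy = (counts > 0).mean(axis=0)
    pool = occupancy > 0
    occ_p = np.where(pool, occupancy, 0.0)
    occ_p = occ_p / occ_p.sum()
    abundance = counts.sum(axis=0).astype(float)
    abundance = np.where(pool, abundance, 0.0)

    nulls = []
    rel_nulls = []
    for s in range(S):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed or 0, spawn_key=(s,)))
        richness = int((counts[s] > 0).sum())
        ns = _null_assemblages(richness, int(totals[s]), occ_p, abundance, n_null, rng)
        nulls.append(ns)
        rel_nulls.append(ns / ns.sum(axis=1, keepdims=True))

    rel_obs = counts / totals[:, None]
    ii, jj = np.triu_indices(S, k=1)
    rc = np.empty(ii.size)
    bc_obs = np.empty(ii.size)
    for p, (k, m) in enumerate(zip(ii, jj)):
        x, y = rel_obs[k], rel_obs[m]
        obs = np.abs(x - y).sum() / (x + y).sum()
        xn, yn = rel_nulls[k], rel_nulls[m]
        null_bc = np.abs(xn - yn).sum(axis=1) / (xn + yn).sum(axis=1)
        less = (null_bc < obs - 1e-12).sum()
        ties = (np.abs(null_bc - obs) <= 1e-12).sum()
        rc[p] = 2.0 * ((less + 0.5 * ties) / n_null - 0.5)
        bc_obs[p] = obs
    return pd.DataFrame(
        {"bc_obs": bc_obs, "rc_bray": rc}, index=_pair_index(table.sample_ids)
    )


def classify_assembly(
    pairwise: pd.DataFrame,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Five-way process classification from per-pair βNTI and RC_Bray.

    Strict inequalities: βNTI > 2 → variable selection; βNTI < −2 →
    homogeneous selection; otherwise RC > 0.95 → dispersal limitation,
    RC < −0.95 → homogenizing dispersal, else undominated.  Degenerate
    pairs receive the label ``degenerate`` and are excluded from fractions.
    """
    req = {"bnti", "rc_bray"}
    if not req <= set(pairwise.columns):
        raise ValueError(f"pairwise frame must have columns {sorted(req)}")
    out = pairwise.copy()
    z = out["bnti"].to_numpy()
    rc = out["rc_bray"].to_numpy()
    label = np.where(
        z > bnti_threshold,
        "variable_selection",
        np.where(
            z < -bnti_threshold,
            "homogeneous_selection",
            np.where(
                rc > rc_threshold,
                "dispersal_limitation",
                np.where(rc < -rc_threshold, "homogenizing_dispersal", "undominated"),
            ),
        ),
    )
    if "degenerate" in out.columns:
        label = np.where(out["degenerate"].to_numpy(), "degenerate", label)
    out["process"] = label
    return out


def summarize_processes(
    classified: pd.DataFrame,
    grouping: Mapping[tuple[str, str], str] | Callable[[str, str], str] | None = None,
) -> pd.DataFrame:
    """Per-group fractions of pairs assigned to each process.

    ``grouping`` maps a (sample_a, sample_b) pair to a group label (mapping or
    callable); ``None`` puts every pair in one group, ``"all"``.  Degenerate
    pairs are excluded from the fractions and reported in ``n_degenerate``.
    Fractions over the five process labels sum to 1 per group.
    """
    if "process" not in classified.columns:
        raise ValueError("run classify_assembly first")
    pairs = classified.index.to_list()
    if grouping is None:
        groups = ["all"] * len(pairs)
    elif callable(grouping):
        groups = [grouping(a, b) for a, b in pairs]
    else:
        groups = [grouping[(a, b)] for a, b in pairs]
    df = classified.assign(group=groups)
    rows = []
    for g, sub in df.groupby("group", sort=True):
        counted = sub[sub["process"] != "degenerate"]
        if len(counted) == 0:
            logger.warning("group %r has no classifiable pairs; omitted", g)
            continue
        row = {"group": g, "n_pairs": len(counted), "n_degenerate": int((sub["process"] == "degenerate").sum())}
        for lab in PROCESS_LABELS:
            row[lab] = float((counted["process"] == lab).mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def quantify_assembly(
    table: CountTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int | None = None,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Convenience pipeline: βNTI (on total-sum-scaled counts) + RC_Bray (on
    counts) + classification, one row per unordered sample pair."""
    rel = to_relative_abundance(table)
    z = bnti(rel, tree, n_null=n_null, seed=seed)
    rc = rc_bray(table, n_null=n_null, seed=seed)
    merged = z.join(rc)
    return classify_assembly(merged, bnti_threshold=bnti_threshold, rc_threshold=rc_threshold)
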