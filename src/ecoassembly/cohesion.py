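"""Null-model-corrected co-occurrence strength (connectedness and cohesion).

Following the Herren & McMahon procedure: pairwise Pearson correlations of
taxon relative abundances across samples are corrected by the expected
correlation under a "taxa shuffle" null (each taxon's abundance vector
permuted independently across samples, correlations averaged over
iterations).  Per taxon, connectedness is the mean of the strictly positive
(resp. strictly negative) corrected correlations with the other taxa; per
sample, cohesion is the abundance-weighted sum of connectedness, so positive
cohesion lies in [0, 1] and negative cohesion in [−1, 0].

Corrected correlations are clipped to [−1, 1] so those ranges hold on every
input; the expected correlations are near zero in practice, so the clip is
inactive on realistic data.
"""
from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountTable, RelAbundanceTable, filter_low_prevalence, to_relative_abundance

logger = logging.getLogger(__name__)


def _corr_with_constant_zero(x: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of columns; constant columns correlate 0."""
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant taxon vector(s); correlations set to 0", constant.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def observed_correlations(rel_table: RelAbundanceTable | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of taxon relative abundances across samples."""
    df = rel_table.data if isinstance(rel_table, RelAbundanceTable) else rel_table
    if df.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate taxa")
    r = _corr_with_constant_zero(df.to_numpy(dtype=float))
    return pd.DataFrame(r, index=df.columns, columns=df.columns)


def null_expected_correlations(
    rel_table: RelAbundanceTable | pd.DataFrame,
    iterations: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Expected correlations under the taxa-shuffle null.

    Each iteration independently permutes every taxon's abundance vector
    across samples and recomputes all pairwise correlations; the expected
    matrix is the mean over iterations.  Deterministic given ``seed``.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    df = rel_table.data if isinstance(rel_table, RelAbundanceTable) else rel_table
    x = df.to_numpy(dtype=float)
    # one substream per taxon, keyed by its id: the expected matrix is exactly
    # invariant to taxon ordering and stable when unrelated taxa are dropped
    gens = [
        np.random.default_rng(
            np.random.SeedSequence(entropy=0 if seed is None else seed,
                                   spawn_key=(zlib.crc32(str(name).encode()),))
        )
        for name in df.columns
    ]
    acc = np.zeros((x.shape[1], x.shape[1]))
    shuffled = np.empty_like(x)
    for _ in range(iterations):
        for j, gen in enumerate(gens):
            shuffled[:, j] = x[gen.permutation(x.shape[0]), j]
        acc += _corr_with_constant_zero(shuffled)
    acc /= iterations
    np.fill_diagonal(acc, 1.0)
    return pd.DataFrame(acc, index=df.columns, columns=df.columns)


def connectedness(observed: pd.DataFrame, expected: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon mean positive and mean negative corrected correlation.

    corrected = observed − expected (clipped to [−1, 1], diagonal excluded);
    a taxon with no strictly positive (negative) corrected value gets 0.
    """
    if observed.shape != expected.shape or list(observed.columns) != list(expected.columns):
        raise ValueError("observed and expected matrices are not conformable")
    corrected = np.clip(observed.to_numpy() - expected.to_numpy(), -1.0, 1.0)
    np.fill_diagonal(corrected, 0.0)
    T = corrected.shape[0]
    pos = np.zeros(T)
    neg = np.zeros(T)
    for i in range(T):
        row = np.delete(corrected[i], i)
        p = row[row > 0]
        n = row[row < 0]
        pos[i] = p.mean() if p.size else 0.0
        neg[i] = n.mean() if n.size else 0.0
    return pd.DataFrame({"positive": pos, "negative": neg}, index=observed.columns)


def cohesion(
    rel_table: RelAbundanceTable | pd.DataFrame, connectedness_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample abundance-weighted sum of connectedness.

    Returns positive cohesion, negative cohesion and the absolute value of
    negative cohesion (the display form in which more negative co-occurrence
    means a larger value).
    """
    df = rel_table.data if isinstance(rel_table, RelAbundanceTable) else rel_table
    conn = connectedness_table.reindex(df.columns)
    if conn.isna().any().any():
        raise ValueError("connectedness does not cover every taxon in the table")
    pos = df.to_numpy(dtype=float) @ conn["positive"].to_numpy()
    neg = df.to_numpy(dtype=float) @ conn["negative"].to_numpy()
    return pd.DataFrame(
        {"positive": pos, "negative": neg, "abs_negative": np.abs(neg)}, index=df.index
    )


@dataclass
class CohesionResult:
    connectedness: pd.DataFrame  # per retained taxon
    cohesion: pd.DataFrame  # per sample
    provenance: dict = field(default_factory=dict)


def persistence_filter(table: CountTable, cutoff: float) -> CountTable:
    """Keep taxa present (count > 0) in at least ``cutoff`` fraction of samples."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("persistence cutoff must lie in [0, 1]")
    frac = (table.data > 0).mean(axis=0)
    keep = list(frac.index[frac >= cutoff])
    if not keep:
        raise ValueError("persistence filter removed every taxon")
    return CountTable(table.data[keep])


def compute_cohesion(
    table: CountTable,
    min_total_reads: int = 150,
    persistence_cutoff: float = 0.1,
    iterations: int = 200,
    seed: int | None = None,
) -> CohesionResult:
    """Full cohesion pipeline on a count table.

    Read-count prefilter (taxa with fewer than ``min_total_reads`` reads
    dropped) → persistence filter → total-sum scaling → observed and
    null-expected correlations → connectedness → per-sample cohesion.
    """
    if table.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    filtered, prefilter_report = filter_low_prevalence(table, min_total_reads)
    filtered = persistence_filter(filtered, persistence_cutoff)
    rel = to_relative_abundance(filtered)
    obs = observed_correlations(rel)
    exp = null_expected_correlations(rel, iterations=iterations, seed=seed)
    conn = connectedness(obs, exp)
    coh = cohesion(rel, conn)
    prov = {
        "min_total_reads": min_total_reads,
        "persistence_cutoff": persistence_cutoff,
        "iterations": iterations,
        "seed": seed,
        "n_taxa_retained": filtered.shape[1],
        "prefilter": prefilter_report._asdict(),
        "correlations_on": "relative abundances after filtering",
    }
    return CohesionResult(conn, coh, prov)
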