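"""Unconstrained and constrained ordination linking community structure to
predictors.

* PCoA with the Cailliez correction: Gower double-centering of −½D²,
  eigendecomposition; the Cailliez constant is the smallest additive constant
  on off-diagonal distances making the configuration Euclidean, found as the
  largest eigenvalue of the standard 2n×2n companion problem.
* PERMANOVA (McArdle–Anderson): sequential (Type-I) sums of squares of the
  Gower-centered inner-product matrix against hat matrices of the cumulative
  design, pseudo-F per term, p-values by row/column permutation of the
  centered matrix with the (1 + exceedances)/(1 + n_perm) estimator.
* Multivariate dispersion homogeneity (betadisper): distances to group
  centroids in the Cailliez-corrected principal-coordinate space.
* VIF pruning, distance-based RDA / classical RDA with Ezekiel-adjusted R²
  and permutation tests, and variance partitioning of adjusted R² among up
  to four predictor groups by inclusion–exclusion.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orth
from skbio import DistanceMatrix
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-8


def _as_distance(dist: DistanceMatrix | np.ndarray, ids=None) -> DistanceMatrix:
    if isinstance(dist, DistanceMatrix):
        return dist
    try:
        return DistanceMatrix(np.asarray(dist, dtype=float), ids=ids)
    except Exception as exc:
        raise ValueError(f"not a valid distance matrix: {exc}") from exc


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ (-0.5 * d_squared) @ j


def cailliez_constant(dist: DistanceMatrix | np.ndarray) -> float:
    """Smallest constant c such that D + c (off-diagonal) is Euclidean."""
    d = _as_distance(dist).data
    n = d.shape[0]
    delta1 = _gower_center(d**2)
    if np.linalg.eigvalsh(delta1).min() >= -_EIG_TOL * max(1.0, np.abs(delta1).max()):
        return 0.0
    delta2 = _gower_center(d)
    sp = np.block([[np.zeros((n, n)), 2.0 * delta1], [-np.eye(n), -4.0 * delta2]])
    eigs = np.linalg.eigvals(sp)
    return float(np.max(eigs.real))


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding.

    ``coordinates`` holds one column per retained (positive-eigenvalue) axis,
    scaled by the square root of its eigenvalue; ``eigenvalues`` includes the
    full spectrum; ``proportions`` are the positive eigenvalues as fractions
    of their sum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportions: np.ndarray
    cailliez_constant_: float = 0.0

    @property
    def ids(self) -> list[str]:
        return list(self.coordinates.index)


def pcoa(dist: DistanceMatrix | np.ndarray, correction: str = "cailliez") -> OrdinationResult:
    """Principal coordinate analysis, optionally Cailliez corrected."""
    dm = _as_distance(dist)
    if correction not in ("none", "cailliez"):
        raise ValueError("correction must be 'none' or 'cailliez'")
    d = dm.data
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    c = 0.0
    if correction == "cailliez":
        c = cailliez_constant(dm)
        if c > 0:
            d = d + c
            np.fill_diagonal(d, 0.0)
    g = _gower_center(d**2)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(1.0, np.abs(eigval).max())
    pos = eigval > _EIG_TOL * scale
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    proportions = eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PCo{i + 1}" for i in range(int(pos.sum()))]
    )
    return OrdinationResult(frame, eigval, proportions, c)


# ---------------------------------------------------------------------------
# PERMANOVA and dispersion
# ---------------------------------------------------------------------------


def _design_block(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValueError(f"term {col.name!r} has a single level")
    return dummies.to_numpy(dtype=float)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms, Residual, Total
    n_perm: int


def permanova(
    dist: DistanceMatrix | np.ndarray,
    metadata: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    Terms are fitted in the caller's order (Type-I sums of squares); factors
    are dummy-coded, numeric covariates used as-is.  p-values come from
    unrestricted permutation of the Gower-centered matrix.
    """
    dm = _as_distance(dist)
    md = metadata.loc[list(dm.ids)]
    n = len(dm.ids)
    g = _gower_center(dm.data**2)
    ss_total = float(np.trace(g))

    blocks = [_design_block(md[t]) for t in terms]
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    cum = np.ones((n, 1))
    prev_rank = 1
    for b in blocks:
        cum = np.hstack([cum, b])
        q = orth(cum)
        hats.append(q @ q.T)
        dfs.append(q.shape[1] - prev_rank)
        prev_rank = q.shape[1]
    df_res = n - prev_rank
    if df_res < 1:
        raise ValueError("not enough residual degrees of freedom for the model")
    if any(d < 1 for d in dfs):
        raise ValueError("a term adds no degrees of freedom (aliased with earlier terms)")

    eps = 1e-12 * max(ss_total, 1.0)
    dfs_arr = np.array(dfs, dtype=float)

    def term_stats(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        cumss = np.array([np.sum(h * gmat) for h in hats])
        ss_terms = np.diff(np.r_[0.0, cumss])
        ss_res = float(np.trace(gmat)) - cumss[-1]
        return ss_terms, max(ss_res, 0.0)

    def f_stats(ss_t: np.ndarray, ss_r: float) -> np.ndarray:
        if ss_r <= eps:  # perfect separation: residual SS is numerically zero
            return np.where(ss_t > eps, np.inf, 0.0)
        return (ss_t / dfs_arr) / (ss_r / df_res)

    ss_terms, ss_res = term_stats(g)
    f_obs = f_stats(ss_terms, ss_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_t, ss_r = term_stats(gp)
        exceed += f_stats(ss_t, ss_r) >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for t, df_t, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append({"term": t, "df": df_t, "sum_sq": ss, "r2": ss / ss_total, "pseudo_f": f, "p_value": p})
    rows.append({"term": "Residual", "df": df_res, "sum_sq": ss_res, "r2": ss_res / ss_total,
                 "pseudo_f": np.nan, "p_value": np.nan})
    rows.append({"term": "Total", "df": n - 1, "sum_sq": ss_total, "r2": 1.0,
                 "pseudo_f": np.nan, "p_value": np.nan})
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)


@dataclass
class BetadisperResult:
    distances: pd.Series  # per-sample distance to its group centroid
    f_statistic: float
    p_value: float | None
    degenerate: bool = False


def betadisper(
    dist: DistanceMatrix | np.ndarray,
    groups: pd.Series | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> BetadisperResult:
    """Homogeneity of multivariate dispersions around group centroids.

    Samples are embedded by Cailliez-corrected PCoA (all axes real), each
    sample's distance to its group centroid is computed, and group equality
    of mean dispersion is tested with a permutation F test.  Groups of size 1
    are excluded with a warning.
    """
    dm = _as_distance(dist)
    grp = pd.Series(groups, index=list(dm.ids)) if not isinstance(groups, pd.Series) else groups.loc[list(dm.ids)]
    sizes = grp.value_counts()
    singletons = sizes.index[sizes < 2]
    if len(singletons):
        logger.warning("excluding singleton group(s): %s", list(singletons))
        keep = grp.index[~grp.isin(singletons)]
        dm = dm.filter(keep)
        grp = grp.loc[list(dm.ids)]
    coords = pcoa(dm, correction="cailliez").coordinates.to_numpy()
    labels = grp.to_numpy()
    dists = np.empty(len(labels))
    for g in np.unique(labels):
        mask = labels == g
        centroid = coords[mask].mean(axis=0)
        dists[mask] = np.linalg.norm(coords[mask] - centroid, axis=1)

    def f_stat(d: np.ndarray, lab: np.ndarray) -> float:
        groups_ = np.unique(lab)
        k = len(groups_)
        grand = d.mean()
        ssb = sum((lab == g).sum() * (d[lab == g].mean() - grand) ** 2 for g in groups_)
        ssw = sum(((d[lab == g] - d[lab == g].mean()) ** 2).sum() for g in groups_)
        if ssw <= 1e-300:
            return np.inf if ssb > 1e-300 else np.nan
        return (ssb / (k - 1)) / (ssw / (len(d) - k))

    f_obs = f_stat(dists, labels)
    if np.isnan(f_obs):
        return BetadisperResult(pd.Series(dists, index=grp.index), np.nan, None, degenerate=True)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_p = f_stat(dists, rng.permutation(labels))
        if not np.isnan(f_p) and f_p >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_perm)
    return BetadisperResult(pd.Series(dists, index=grp.index), float(f_obs), p)


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------


@dataclass
class VifPruneResult:
    retained: list[str]
    removed: list[tuple[str, float]]  # (predictor, VIF at removal)
    final_vifs: pd.Series


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    if (sd == 0).any():
        raise ValueError(f"constant predictor(s): {list(sd.index[sd == 0])}")
    return (df - df.mean()) / sd


def vif_prune(predictors: pd.DataFrame, threshold: float = 10.0) -> VifPruneResult:
    """Iteratively drop the predictor with the highest variance inflation
    factor until all VIF < threshold (perfect collinearity sorts first)."""
    x = _zscore(predictors.astype(float))
    removed: list[tuple[str, float]] = []
    while True:
        cols = list(x.columns)
        if len(cols) == 1:
            vifs = pd.Series([1.0], index=cols)
        else:
            exog = np.hstack([np.ones((len(x), 1)), x.to_numpy()])
            with np.errstate(divide="ignore", invalid="ignore"):
                raw = [variance_inflation_factor(exog, j + 1) for j in range(len(cols))]
            vifs = pd.Series([np.inf if (not np.isfinite(v) or v < 0) else v for v in raw], index=cols)
        if (vifs < threshold).all():
            return VifPruneResult(cols, removed, vifs)
        worst = vifs.idxmax()
        removed.append((worst, float(vifs[worst])))
        x = x.drop(columns=[worst])
        if x.shape[1] == 0:
            raise ValueError("VIF pruning removed every predictor")


# ---------------------------------------------------------------------------
# constrained ordination
# ---------------------------------------------------------------------------


def ezekiel_adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel adjustment: 1 − (1 − R²)(n − 1)/(n − m − 1)."""
    if n - m - 1 <= 0:
        raise ValueError("adjustment undefined: n - m - 1 must be positive")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class ConstrainedOrdinationResult:
    sample_scores: pd.DataFrame  # samples × constrained axes
    eigenvalues: np.ndarray  # constrained axis sums of squares, non-increasing
    r2: float
    adjusted_r2: float
    p_overall: float | None
    axis_p_values: np.ndarray | None
    predictors: list[str]
    biplot_scores: pd.DataFrame = field(default_factory=pd.DataFrame)


def _constrained_fit(
    y: np.ndarray,
    x: pd.DataFrame,
    ids: Sequence[str],
    n_perm: int,
    seed: int | None,
) -> ConstrainedOrdinationResult:
    n = y.shape[0]
    xz = _zscore(x.astype(float)).to_numpy()
    q = orth(xz)
    m = q.shape[1]
    if m >= n - 1:
        raise ValueError("saturated model: need fewer predictors than samples - 1")
    yc = y - y.mean(axis=0)
    qty = q.T @ yc
    yhat = q @ qty
    ss_tot = float((yc**2).sum())
    ss_fit = float((yhat**2).sum())
    ss_res = ss_tot - ss_fit
    r2 = ss_fit / ss_tot if ss_tot > 0 else 0.0
    adj = ezekiel_adjusted_r2(r2, n, m)

    u, s, _ = np.linalg.svd(yhat, full_matrices=False)
    rank = int((s > 1e-10 * max(1.0, s.max(initial=0.0))).sum())
    eigvals = s[:rank] ** 2
    scores = pd.DataFrame(
        u[:, :rank] * s[:rank], index=list(ids),
        columns=[f"CAP{i + 1}" for i in range(rank)],
    )
    biplot = pd.DataFrame(
        np.array([[np.corrcoef(xz[:, j], scores.iloc[:, i])[0, 1] if scores.iloc[:, i].std() > 0 else 0.0
                   for i in range(rank)] for j in range(xz.shape[1])]),
        index=list(x.columns), columns=scores.columns,
    ) if rank else pd.DataFrame(index=list(x.columns))

    p_overall = None
    axis_p = None
    if n_perm and n_perm > 0:
        df_res = n - m - 1
        f_obs = (ss_fit / m) / (ss_res / df_res) if ss_res > 0 else np.inf
        rng = np.random.default_rng(seed)
        exceed = 0
        axis_exceed = np.zeros(rank)
        for _ in range(n_perm):
            yp = yc[rng.permutation(n)]
            qtyp = q.T @ yp
            ss_fit_p = float((qtyp**2).sum())
            ss_res_p = ss_tot - ss_fit_p
            f_p = (ss_fit_p / m) / (ss_res_p / df_res) if ss_res_p > 0 else np.inf
            if f_p >= f_obs:
                exceed += 1
            if rank:
                sp = np.linalg.svd(qtyp, compute_uv=False)
                lam_p = np.zeros(rank)
                lam_p[: min(rank, sp.size)] = sp[:rank] ** 2
                axis_exceed += lam_p >= eigvals
        p_overall = (1.0 + exceed) / (1.0 + n_perm)
        axis_p = (1.0 + axis_exceed) / (1.0 + n_perm)
    return ConstrainedOrdinationResult(
        scores, eigvals, r2, adj, p_overall, axis_p, list(x.columns), biplot
    )


def db_rda(
    dist: DistanceMatrix | np.ndarray,
    predictors: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ConstrainedOrdinationResult:
    """Distance-based redundancy analysis.

    The response is the full set of positive-eigenvalue axes of the
    Cailliez-corrected PCoA (total inertia preserved); predictors are z-score
    standardized (prune with :func:`vif_prune` beforehand).  Overall and
    per-axis significance by row permutation.
    """
    dm = _as_distance(dist)
    x = predictors.loc[list(dm.ids)]
    coords = pcoa(dm, correction="cailliez").coordinates.to_numpy()
    return _constrained_fit(coords, x, list(dm.ids), n_perm, seed)


def rda(
    response: pd.DataFrame,
    predictors: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ConstrainedOrdinationResult:
    """Classical redundancy analysis on z-scored numeric responses."""
    y = _zscore(response.astype(float)).to_numpy()
    x = predictors.loc[response.index]
    return _constrained_fit(y, x, list(response.index), n_perm, seed)


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------


@dataclass
class VarPartResult:
    """Venn-cell decomposition of the full-model adjusted R².

    ``cells`` maps a frozenset of group names to the adjusted-R² fraction of
    the region belonging to exactly those groups; negative cells are retained
    (display layers may suppress them).  Cells sum to ``total_adjusted_r2``;
    ``residual`` is 1 − total.
    """

    cells: dict[frozenset, float]
    total_adjusted_r2: float
    residual: float
    subset_adjusted_r2: dict[frozenset, float]

    def unique(self, group: str) -> float:
        return self.cells[frozenset([group])]

    def table(self) -> pd.DataFrame:
        rows = [
            {"groups": "+".join(sorted(k)), "fraction": v}
            for k, v in sorted(self.cells.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
        ]
        rows.append({"groups": "Residual", "fraction": self.residual})
        return pd.DataFrame(rows).set_index("groups")


def variance_partition(
    dist: DistanceMatrix | np.ndarray,
    predictors: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
) -> VarPartResult:
    """Partition dbRDA adjusted R² among 2–4 disjoint predictor groups.

    Fits a dbRDA for every non-empty union of groups and solves the
    inclusion–exclusion system f(S) = Σ_{cells touching S} cell for the Venn
    cells, so the cells always sum to the full-model adjusted R².
    """
    names = list(groups)
    if not 1 <= len(names) <= 4:
        raise ValueError("variance partitioning supports 1-4 predictor groups")
    seen: set[str] = set()
    for g, cols in groups.items():
        overlap = seen & set(cols)
        if overlap:
            raise ValueError(f"predictor(s) in more than one group: {sorted(overlap)}")
        seen |= set(cols)
    dm = _as_distance(dist)
    subsets = [
        frozenset(c)
        for r in range(1, len(names) + 1)
        for c in itertools.combinations(names, r)
    ]
    adj: dict[frozenset, float] = {}
    for sub in subsets:
        cols = [c for g in sub for c in groups[g]]
        adj[sub] = db_rda(dm, predictors[cols], n_perm=0).adjusted_r2
    # solve f(S) = sum over cells C with C ∩ S != ∅
    a = np.array([[1.0 if cell & s else 0.0 for cell in subsets] for s in subsets])
    x = np.linalg.solve(a, np.array([adj[s] for s in subsets]))
    cells = dict(zip(subsets, x))
    total = adj[frozenset(names)]
    return VarPartResult(cells, total, 1.0 - total, adj)
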