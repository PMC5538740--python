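"""Phylogenetic beta diversity: PhyloSor, its null model, and Mantel tests.

PhyloSor is a Sørensen-like similarity between two assemblages,

    PhyloSor(A, B) = 2·BL_shared / (PD_A + PD_B),

where PD_X is root-inclusive Faith's PD and BL_shared is the total length
of edges lying in both root-inclusive spanning subtrees.  Phylogenetic beta
diversity is 1 − PhyloSor: 0 means complete phylogenetic homogenization,
1 complete turnover.  Because the spanning subtrees are root-inclusive, a
pair of disjoint clades reaches dissimilarity 1 only when the edges they
share toward the root (typically the root edge itself) have zero length.

The SES null shuffles tip labels with both assemblages' membership — hence
the presence/absence matrix — held fixed: one permutation is applied to
both species sets, preserving their intersection structure.

Temporal beta compares each island's pre-European and current assemblages
on the same regional chronogram; spatial beta compares islands within one
period.  Mantel tests correlate beta matrices with great-circle distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .alpha import TreeMetrics
from .community import (
    AssemblageSpec,
    IslandMeta,
    OccurrenceMatrix,
    Period,
    Scope,
    assemble,
)
from .nullses import SESResult, _make_result
from .stats import TTestResult, one_sample_t
from .treeio import Phylogeny

__all__ = [
    "BetaMatrix",
    "MantelResult",
    "TemporalBetaResult",
    "phylosor",
    "phylo_beta",
    "ses_phylosor",
    "temporal_beta",
    "spatial_beta",
    "great_circle_km",
    "geo_distance_matrix",
    "mantel",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class BetaMatrix:
    """Symmetric matrix of 1 − PhyloSor among assemblages (+ optional SES)."""

    labels: list[str]
    values: np.ndarray
    ses_values: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("beta matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("beta matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("beta matrix diagonal must be 0")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("1 − PhyloSor values must lie in [0, 1]")
        self.values = v

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass(frozen=True)
class MantelResult:
    """Permutation Mantel test between two distance matrices."""

    r: float
    p: float
    n_perm: int
    alternative: str
    degenerate: bool = False


@dataclass(frozen=True)
class TemporalBetaResult:
    """Per-island 1 − PhyloSor between periods, with the μ = 0 contrast."""

    islands: list[str]
    values: list[float]
    mean: float
    se: float
    ttest: TTestResult
    skipped: list[str] = field(default_factory=list)


# -- PhyloSor ------------------------------------------------------------


def _shared_and_pd(
    tm: TreeMetrics, idx_a: np.ndarray, idx_b: np.ndarray
) -> tuple[float, float, float]:
    cov_a = tm.spanning_edges_idx(idx_a)
    cov_b = tm.spanning_edges_idx(idx_b)
    shared = float(tm.edge_lengths[cov_a & cov_b].sum())
    return shared, float(tm.edge_lengths[cov_a].sum()), float(tm.edge_lengths[cov_b].sum())


def phylosor(
    tree: Phylogeny | TreeMetrics, taxa_a: Iterable[str], taxa_b: Iterable[str]
) -> float:
    """PhyloSor similarity in [0, 1]: shared fraction of branch length."""
    tm = tree if isinstance(tree, TreeMetrics) else TreeMetrics(tree)
    a, b = set(taxa_a), set(taxa_b)
    if not a or not b:
        raise ValueError("phylosor: both assemblages must be nonempty")
    shared, pd_a, pd_b = _shared_and_pd(tm, tm.indices(a), tm.indices(b))
    return 2.0 * shared / (pd_a + pd_b)


def phylo_beta(
    tree: Phylogeny | TreeMetrics, taxa_a: Iterable[str], taxa_b: Iterable[str]
) -> float:
    """Phylogenetic beta diversity, 1 − PhyloSor."""
    return 1.0 - phylosor(tree, taxa_a, taxa_b)


def ses_phylosor(
    tree: Phylogeny | TreeMetrics,
    taxa_a: Iterable[str],
    taxa_b: Iterable[str],
    n_rand: int = 999,
    rng_seed: int | np.random.Generator = 0,
) -> SESResult:
    """SES of 1 − PhyloSor under the matrix-preserving tip-shuffle null.

    Each randomization applies one label permutation to both assemblages,
    so their sizes and overlap — the presence/absence matrix — are
    maintained.  |SES| < 1.96 indicates no deviation from chance.
    """
    tm = tree if isinstance(tree, TreeMetrics) else TreeMetrics(tree)
    a, b = set(taxa_a), set(taxa_b)
    if not a or not b:
        raise ValueError("ses_phylosor: both assemblages must be nonempty")
    idx_a, idx_b = tm.indices(a), tm.indices(b)
    observed = 1.0 - phylosor(tm, a, b)
    rng = np.random.default_rng(rng_seed)
    n = len(tm.tip_labels)
    null = np.empty(n_rand)
    for r in range(n_rand):
        perm = rng.permutation(n)
        pa, pb = perm[idx_a], perm[idx_b]
        shared, pd_a, pd_b = _shared_and_pd(tm, pa, pb)
        null[r] = 1.0 - 2.0 * shared / (pd_a + pd_b)
    return _make_result("phylo_beta", observed, null, 1.96)


# -- period comparisons ---------------------------------------------------


def temporal_beta(
    tree: Phylogeny | TreeMetrics,
    matrix: OccurrenceMatrix,
    scope: Scope | str = Scope.COMPLETE,
) -> TemporalBetaResult:
    """1 − PhyloSor between each island's pre-European and current flora.

    Islands with an empty assemblage in either period are skipped with a
    warning.  The summary contrasts the mean against μ = 0 with a
    two-tailed one-sample t-test (degenerate when all values are equal,
    e.g. the no-change system where every value is 0).
    """
    tm = tree if isinstance(tree, TreeMetrics) else TreeMetrics(tree)
    scope = Scope(scope)
    pre_spec = AssemblageSpec(Period.PRE_EUROPEAN, Scope.COMPLETE
                              if scope is Scope.COMPLETE else scope)
    cur_spec = AssemblageSpec(Period.CURRENT, scope)
    islands, values, skipped = [], [], []
    for island in matrix.island_names:
        pre = assemble(matrix, island, pre_spec)
        cur = assemble(matrix, island, cur_spec)
        if not pre or not cur:
            logger.warning("temporal_beta: skipping %r (empty assemblage)", island)
            skipped.append(island)
            continue
        islands.append(island)
        values.append(phylo_beta(tm, pre, cur))
    v = np.asarray(values)
    mean = float(v.mean()) if len(v) else math.nan
    se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    ttest = one_sample_t(values, mu=0.0) if len(v) > 1 else TTestResult(
        None, None, max(len(v) - 1, 0), degenerate=True
    )
    return TemporalBetaResult(islands, values, mean, se, ttest, skipped)


def spatial_beta(
    tree: Phylogeny | TreeMetrics,
    matrix: OccurrenceMatrix,
    spec: AssemblageSpec,
    n_rand: int | None = None,
    rng_seed: int | np.random.Generator = 0,
) -> BetaMatrix:
    """Pairwise 1 − PhyloSor among islands within one period/scope.

    With ``n_rand`` set, a matching matrix of SES values is computed under
    the matrix-preserving null (one shuffle sequence per pair, derived from
    ``rng_seed``).
    """
    tm = tree if isinstance(tree, TreeMetrics) else TreeMetrics(tree)
    names = matrix.island_names
    sets = {i: assemble(matrix, i, spec) for i in names}
    empty = [i for i, s in sets.items() if not s]
    if empty:
        raise ValueError(f"empty assemblages for islands {empty} under {spec}")
    n = len(names)
    values = np.zeros((n, n))
    ses_values = np.full((n, n), np.nan) if n_rand else None
    rng = np.random.default_rng(rng_seed)
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = phylo_beta(tm, sets[names[i]], sets[names[j]])
            if n_rand:
                res = ses_phylosor(
                    tm, sets[names[i]], sets[names[j]], n_rand=n_rand, rng_seed=rng
                )
                s = res.ses if res.ses is not None else np.nan
                ses_values[i, j] = ses_values[j, i] = s
    if ses_values is not None:
        np.fill_diagonal(ses_values, 0.0)
    return BetaMatrix(list(names), values, ses_values)


# -- geography ------------------------------------------------------------


def great_circle_km(a: IslandMeta, b: IslandMeta) -> float:
    """Haversine great-circle distance in km (Earth radius 6371 km)."""
    lat1, lon1 = math.radians(a.latitude), math.radians(a.longitude)
    lat2, lon2 = math.radians(b.latitude), math.radians(b.longitude)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geo_distance_matrix(islands: Sequence[IslandMeta]) -> np.ndarray:
    n = len(islands)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = great_circle_km(islands[i], islands[j])
    return d


# -- Mantel ---------------------------------------------------------------


def _condensed(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel(
    x: BetaMatrix | np.ndarray,
    y: np.ndarray,
    n_perm: int = 999,
    rng_seed: int | np.random.Generator = 0,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test: Pearson r of off-diagonal entries, permutation p-value.

    ``p = (1 + #{permuted r ≥ observed r}) / (1 + n_perm)`` under joint
    row/column permutation of ``y``.  One-tailed ("greater", the distance-
    decay hypothesis) by default; "two-sided" compares |r|.
    """
    xm = x.values if isinstance(x, BetaMatrix) else np.asarray(x, dtype=float)
    ym = np.asarray(y, dtype=float)
    if xm.shape != ym.shape or xm.shape[0] != xm.shape[1]:
        raise ValueError("mantel: matrices must be square with equal shapes")
    n = xm.shape[0]
    if n < 3:
        raise ValueError("mantel: need at least 3 assemblages")
    if not (np.allclose(xm, xm.T) and np.allclose(ym, ym.T)):
        raise ValueError("mantel: matrices must be symmetric")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    xv = _condensed(xm)
    if xv.std() == 0 or _condensed(ym).std() == 0:
        return MantelResult(math.nan, math.nan, n_perm, alternative, degenerate=True)

    xv = (xv - xv.mean()) / xv.std()

    def corr(mat: np.ndarray) -> float:
        yv = _condensed(mat)
        sd = yv.std()
        if sd == 0:
            return math.nan
        return float((xv * (yv - yv.mean()) / sd).mean())

    r_obs = corr(ym)
    rng = np.random.default_rng(rng_seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_perm = corr(ym[np.ix_(p, p)])
        if alternative == "greater":
            hits += r_perm >= r_obs
        else:
            hits += abs(r_perm) >= abs(r_obs)
    p_val = (1 + hits) / (1 + n_perm)
    return MantelResult(r_obs, float(p_val), n_perm, alternative)
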