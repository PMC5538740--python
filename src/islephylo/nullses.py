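"""Standardized effect sizes of PD/MPD/MNTD under a tip-label shuffle null.

The null model permutes the phylogeny's tip labels while the assemblage
membership (and hence the occurrence matrix, with any spatial structure it
carries) stays fixed.  Because the image of a fixed species set under a
uniform label permutation is a uniform random tip subset of the same size,
the null distribution is generated by re-evaluating the index on random tip
subsets — identical in law to re-labelling the tree, and much cheaper.

SES = (observed − null mean) / null sd.  Negative SES of MPD/MNTD means
the assemblage is more closely related than chance (phylogenetic
clustering); the sign-flipped conventions NRI = −SES(MPD) and
NTI = −SES(MNTD) are reported alongside.  Classification uses |SES| > 1.96,
the two-sided 5% normal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alpha import TreeMetrics
from .treeio import Phylogeny

__all__ = [
    "SESResult",
    "PooledSES",
    "tip_shuffle",
    "ses",
    "ses_profile",
    "pooled_interval",
    "classify",
]

THRESHOLD = 1.96  # two-sided 5% significance threshold in sd units


@dataclass(frozen=True)
class SESResult:
    """Observed index vs a tip-shuffle null distribution.

    ``ses`` is None (and ``degenerate`` True) when the null distribution has
    zero spread, e.g. for the full tip set, where every relabelling yields
    the same index.
    """

    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float | None
    n_randomizations: int
    classification: str  # clustered | overdispersed | indistinct
    degenerate: bool = False

    @property
    def nri_or_nti(self) -> float | None:
        """Sign-flipped SES (NRI for MPD, NTI for MNTD); positive = clustered."""
        return None if self.ses is None else -self.ses


def classify(ses_value: float | None, threshold: float = THRESHOLD) -> str:
    """Raw-SES classification: below −threshold clustered, above overdispersed."""
    if ses_value is None:
        return "indistinct"
    if ses_value < -threshold:
        return "clustered"
    if ses_value > threshold:
        return "overdispersed"
    return "indistinct"


def tip_shuffle(tree: Phylogeny, rng_seed: int | np.random.Generator) -> Phylogeny:
    """Return a copy of ``tree`` with tip labels permuted uniformly at random.

    Topology and branch lengths are untouched; only the label-to-position
    assignment changes.  Seeded runs are reproducible.
    """
    rng = np.random.default_rng(rng_seed)
    out = tree.copy()
    tips = [n for n in out.iter_postorder() if n.is_leaf]
    labels = [t.name for t in tips]
    for tip, k in zip(tips, rng.permutation(len(tips))):
        tip.name = labels[k]
    return Phylogeny(out.root)


def _null_distribution(
    tm: TreeMetrics, metric: str, k: int, n_rand: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(tm.tip_labels)
    out = np.empty(n_rand)
    for r in range(n_rand):
        idx = rng.choice(n, size=k, replace=False)
        out[r] = tm.metric_idx(metric, idx)
    return out


def _make_result(
    metric: str, observed: float, null: np.ndarray, threshold: float
) -> SESResult:
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if len(null) > 1 else 0.0
    scale = max(abs(null_mean), abs(observed), 1.0)
    if null_sd <= 1e-12 * scale:
        return SESResult(
            metric, observed, null_mean, null_sd, None, len(null), "indistinct",
            degenerate=True,
        )
    s = (observed - null_mean) / null_sd
    return SESResult(
        metric, observed, null_mean, null_sd, s, len(null), classify(s, threshold)
    )


def ses(
    tree: Phylogeny | TreeMetrics,
    taxa: Iterable[str],
    metric: str = "mpd",
    n_rand: int = 999,
    rng_seed: int | np.random.Generator = 0,
    threshold: float = THRESHOLD,
) -> SESResult:
    """SES of one index for one assemblage under the tip-shuffle null."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    tm = tree if isinstance(tree, TreeMetrics) else TreeMetrics(tree)
    taxa = set(taxa)
    if metric in ("mpd", "mntd") and len(taxa) < 2:
        raise ValueError(f"{metric} requires at least 2 species")
    idx = tm.indices(taxa)
    observed = tm.metric_idx(metric, idx)
    rng = np.random.default_rng(rng_seed)
    null = _null_distribution(tm, metric, len(idx), n_rand, rng)
    return _make_result(metric, observed, null, threshold)


def ses_profile(
    tree: Phylogeny | TreeMetrics,
    assemblages: Mapping[str, Iterable[str]],
    metrics: Sequence[str] = ("pd", "mpd", "mntd"),
    n_rand: int = 999,
    rng_seed: int | np.random.Generator = 0,
    threshold: float = THRESHOLD,
) -> dict[str, dict[str, SESResult]]:
    """SES for several assemblages sharing one sequence of label shuffles.

    One permutation of the tip labels is drawn per randomization and applied
    to every assemblage, mirroring a single relabelled regional tree being
    scored against the whole (fixed) occurrence matrix.
    """
    tm = tree if isinstance(tree, TreeMetrics) else TreeMetrics(tree)
    rng = np.random.default_rng(rng_seed)
    n = len(tm.tip_labels)
    index_sets = {name: tm.indices(set(taxa)) for name, taxa in assemblages.items()}
    nulls = {
        name: {m: np.empty(n_rand) for m in metrics} for name in assemblages
    }
    for r in range(n_rand):
        perm = rng.permutation(n)
        for name, idx in index_sets.items():
            shuffled = perm[idx]
            for m in metrics:
                if m in ("mpd", "mntd") and len(idx) < 2:
                    nulls[name][m][r] = np.nan
                    continue
                nulls[name][m][r] = tm.metric_idx(m, shuffled)
    out: dict[str, dict[str, SESResult]] = {}
    for name, idx in index_sets.items():
        out[name] = {}
        for m in metrics:
            if m in ("mpd", "mntd") and len(idx) < 2:
                continue
            observed = tm.metric_idx(m, idx)
            out[name][m] = _make_result(m, observed, nulls[name][m], threshold)
    return out


@dataclass(frozen=True)
class PooledSES:
    """Mean ± 1.96·SE of SES values pooled over assemblages."""

    mean: float
    se: float
    lower: float
    upper: float
    n: int
    classification: str

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "PooledSES":
        v = np.asarray([x for x in values if x is not None], dtype=float)
        if len(v) == 0:
            raise ValueError("no SES values to pool")
        mean = float(v.mean())
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        lower, upper = mean - THRESHOLD * se, mean + THRESHOLD * se
        if upper < -THRESHOLD:
            cls_label = "clustered"
        elif lower > THRESHOLD:
            cls_label = "overdispersed"
        else:
            cls_label = "indistinct"
        return cls(mean, se, lower, upper, len(v), cls_label)


def pooled_interval(values: Sequence[float]) -> PooledSES:
    """The pooled-islands 95% interval check (mean ± 1.96·SE of SES values)."""
    return PooledSES.from_values(values)
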