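"""Synthetic chronograms and island flora systems for end-to-end testing.

The generator emulates the study design of a six-island oceanic system:
a regional species pool (natives plus exotics) on an ultrametric Yule
chronogram, natives scattered over islands by per-island occupancy
probabilities, a fraction of each island's natives driven extinct, and
per-island batches of exotic introductions.  Extinctions and introductions
can be concentrated in one clade (``clade_bias``) to emulate the
clade-structured invasions (grasses, daisies, legumes) and extinctions the
real floras show.

Defaults are the envelope of the real system: 6 islands, 205-species
native pool, 756-species exotic pool, per-island native richness from 9 to
100, up to 35% native extinction, and 6–477 exotic additions per island,
on a 140-My-old angiosperm chronogram.

All randomness flows from a single seed through one numpy Generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .community import IslandMeta, OccurrenceMatrix, SpeciesRecord, Status
from .treeio import Node, Phylogeny, write_newick_file

__all__ = [
    "DEFAULT_ISLANDS",
    "SimConfig",
    "yule_tree",
    "simulate_tree",
    "simulate_system",
    "write_system",
]

#: The six real islands (decimal degrees; south and west negative).
DEFAULT_ISLANDS = (
    IslandMeta("San Felix", -26.2833, -80.0833),
    IslandMeta("San Ambrosio", -26.3333, -79.8833),
    IslandMeta("Easter", -27.1000, -109.3333),
    IslandMeta("Robinson Crusoe", -33.6333, -78.8333),
    IslandMeta("Santa Clara", -33.7000, -78.9333),
    IslandMeta("Alejandro Selkirk", -33.7500, -80.7833),
)

_NATIVE_RICHNESS = (9, 19, 40, 100, 12, 71)  # per island, pre-European
_EXTINCTION_FRACTION = (0.0, 0.0, 0.35, 0.02, 0.0, 0.03)
_INTRODUCTION_COUNT = (6, 6, 340, 477, 41, 148)


@dataclass
class SimConfig:
    """Parameters of one synthetic island system.

    ``occupancy_probability`` is each island's chance of holding any given
    native; the default reproduces the observed native richness spectrum
    (expected richness = probability × pool size).  ``clade_bias`` ≥ 0
    weights extinction/introduction draws by ``exp(clade_bias)`` for
    members of one randomly chosen clade of roughly 10% of the pool
    (0 = uniform draws).
    """

    n_islands: int = 6
    native_pool_size: int = 205
    exotic_pool_size: int = 756
    tree_model: str = "yule"
    birth_rate: float | None = None  # lineages/My; None = shape from n, depth from root_age
    root_age: float = 140.0  # My, angiosperm crown age scale
    occupancy_probability: tuple[float, ...] = tuple(
        r / 205 for r in _NATIVE_RICHNESS
    )
    extinction_fraction: tuple[float, ...] = _EXTINCTION_FRACTION
    introduction_count: tuple[int, ...] = _INTRODUCTION_COUNT
    clade_bias: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.tree_model != "yule":
            raise ValueError("only the Yule tree model is supported")
        if self.native_pool_size < 2 or self.exotic_pool_size < 0:
            raise ValueError("native pool must have >= 2 species")
        for name in ("occupancy_probability", "extinction_fraction",
                     "introduction_count"):
            vals = getattr(self, name)
            if np.isscalar(vals):
                vals = (vals,) * self.n_islands
                setattr(self, name, vals)
            if len(vals) != self.n_islands:
                raise ValueError(f"{name} must have one entry per island")
        if any(not 0 <= p <= 1 for p in self.occupancy_probability):
            raise ValueError("occupancy probabilities must lie in [0, 1]")
        if any(not 0 <= f <= 1 for f in self.extinction_fraction):
            raise ValueError("extinction fractions must lie in [0, 1]")
        if any(c < 0 for c in self.introduction_count):
            raise ValueError("introduction counts must be >= 0")
        if max(self.introduction_count, default=0) > self.exotic_pool_size:
            raise ValueError(
                "introduction_count exceeds the exotic pool on some island"
            )
        if self.clade_bias < 0:
            raise ValueError("clade_bias must be >= 0")


# -- tree simulation ------------------------------------------------------


def yule_tree(
    rng: np.random.Generator,
    n_tips: int | None = None,
    duration: float | None = None,
    birth_rate: float = 1.0,
    root_age: float | None = None,
    labels: list[str] | None = None,
) -> Phylogeny:
    """Ultrametric pure-birth (Yule) tree, crown-started with 2 lineages.

    Exactly one of ``n_tips`` / ``duration`` selects the stopping rule:
    grow to a fixed tip count (then optionally rescale the crown to
    ``root_age``), or grow for a fixed time at ``birth_rate`` so that the
    expected lineage count at time t is 2·e^(birth_rate·t).
    """
    if (n_tips is None) == (duration is None):
        raise ValueError("specify exactly one of n_tips or duration")
    split_times: list[float] = [0.0]  # crown split at t = 0
    t = 0.0
    if n_tips is not None:
        if n_tips < 2:
            raise ValueError("need at least 2 tips")
        k = 2
        while k < n_tips:
            t += rng.exponential(1.0 / (birth_rate * k))
            split_times.append(t)
            k += 1
        total = t + rng.exponential(1.0 / (birth_rate * k))
    else:
        k = 2
        while True:
            w = rng.exponential(1.0 / (birth_rate * k))
            if t + w > duration:
                break
            t += w
            split_times.append(t)
            k += 1
        total = duration
    if root_age is not None:
        scale = root_age / total
        split_times = [s * scale for s in split_times]
        total = root_age

    # grow the topology: each split bisects a uniformly chosen active tip
    root = Node()
    active: list[Node] = []
    birth_time: dict[int, float] = {root.uid: split_times[0]}
    for child_i in range(2):
        active.append(root.add_child(Node()))
        birth_time[active[-1].uid] = split_times[0]
    for s in split_times[1:]:
        parent = active.pop(int(rng.integers(len(active))))
        parent.length = s - birth_time[parent.uid]
        for _ in range(2):
            child = parent.add_child(Node())
            birth_time[child.uid] = s
            active.append(child)
    names = labels if labels is not None else [
        f"sp{i + 1:04d}" for i in range(len(active))
    ]
    if len(names) != len(active):
        raise ValueError("label count does not match tip count")
    order = rng.permutation(len(active))
    for tip, name in zip(active, (names[i] for i in order)):
        tip.name = name
        tip.length = total - birth_time[tip.uid]
    return Phylogeny(root)


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None) -> Phylogeny:
    """Yule chronogram for the whole species pool (natives + exotics)."""
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.native_pool_size + config.exotic_pool_size
    return yule_tree(
        rng,
        n_tips=n,
        birth_rate=config.birth_rate or 1.0,
        root_age=config.root_age,
    )


# -- system simulation ----------------------------------------------------


def _clade_weights(
    tree: Phylogeny, names: list[str], bias: float, rng: np.random.Generator
) -> np.ndarray:
    """Sampling weights concentrating draws in one ~10%-of-pool clade."""
    if bias == 0:
        return np.ones(len(names))
    target = max(2, round(0.10 * tree.n_tips))
    # choose among internal nodes by clade size closest to ~10% of the pool
    sizes = []
    clades = []
    for node in tree.iter_postorder():
        if node.is_leaf:
            continue
        tips = {t.name for t in _clade_tips(node)}
        sizes.append(len(tips))
        clades.append(tips)
    gaps = np.abs(np.array(sizes) - target)
    candidates = np.flatnonzero(gaps == gaps.min())
    chosen = clades[int(rng.choice(candidates))]
    member = np.array([name in chosen for name in names])
    return np.where(member, np.exp(bias), 1.0)


def _clade_tips(node: Node):
    stack = [node]
    while stack:
        cur = stack.pop()
        if cur.is_leaf:
            yield cur
        else:
            stack.extend(cur.children)


def _weighted_subset(
    rng: np.random.Generator, candidates: np.ndarray, k: int, weights: np.ndarray
) -> np.ndarray:
    if k == 0:
        return np.empty(0, dtype=int)
    p = weights / weights.sum()
    return rng.choice(candidates, size=k, replace=False, p=p)


def simulate_system(
    config: SimConfig,
) -> tuple[Phylogeny, OccurrenceMatrix]:
    """One synthetic two-period island system ready for the full pipeline.

    Natives are assigned to islands independently with the per-island
    occupancy probability (a native landing on no island is placed on one
    random island, keeping the pool size exact).  Extinct natives are drawn
    per island at the configured fraction of that island's natives and
    flagged globally.  Exotics are drawn per island from the exotic pool.
    Extinctions and introductions use the clade-biased weights.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_native, n_exotic = config.native_pool_size, config.exotic_pool_size
    native_names = [f"native{i + 1:04d}" for i in range(n_native)]
    exotic_names = [f"exotic{i + 1:04d}" for i in range(n_exotic)]
    all_names = native_names + exotic_names
    tree = yule_tree(
        rng,
        n_tips=len(all_names),
        birth_rate=config.birth_rate or 1.0,
        root_age=config.root_age,
        labels=all_names,
    )

    n_isl = config.n_islands
    presence = np.zeros((n_isl, len(all_names)), dtype=bool)
    # natives: independent Bernoulli occupancy, at least one island each
    occ = np.array(config.occupancy_probability)
    draws = rng.random((n_isl, n_native)) < occ[:, None]
    for j in np.flatnonzero(~draws.any(axis=0)):
        draws[rng.integers(n_isl), j] = True
    presence[:, :n_native] = draws

    ext_w = _clade_weights(tree, native_names, config.clade_bias, rng)
    extinct = np.zeros(n_native, dtype=bool)
    for i in range(n_isl):
        present = np.flatnonzero(presence[i, :n_native])
        k = round(config.extinction_fraction[i] * len(present))
        if k:
            chosen = _weighted_subset(rng, present, k, ext_w[present])
            extinct[chosen] = True

    intro_w = _clade_weights(tree, exotic_names, config.clade_bias, rng)
    for i in range(n_isl):
        k = config.introduction_count[i]
        chosen = _weighted_subset(rng, np.arange(n_exotic), k, intro_w)
        presence[i, n_native + chosen] = True

    # drop exotics that landed nowhere (they exist only in the regional pool)
    used = presence.any(axis=0)
    used[:n_native] = True
    species = [
        SpeciesRecord(native_names[j], Status.NATIVE, bool(extinct[j]))
        for j in range(n_native)
    ] + [
        SpeciesRecord(exotic_names[j], Status.EXOTIC)
        for j in range(n_exotic)
        if used[n_native + j]
    ]
    keep = np.flatnonzero(used)
    matrix = OccurrenceMatrix(
        list(DEFAULT_ISLANDS[:n_isl])
        if n_isl <= len(DEFAULT_ISLANDS)
        else [IslandMeta(f"island{i + 1}", 0.0, 0.0) for i in range(n_isl)],
        species,
        presence[:, keep],
    )
    return tree, matrix


def write_system(
    out_dir, tree: Phylogeny, matrix: OccurrenceMatrix, config: SimConfig
) -> None:
    """Write Newick + flora/metadata CSVs + a manifest recording the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick_file(tree, out / "tree.nwk")
    matrix.to_csv(out / "flora.csv", out / "islands.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config": asdict(config)}, fh, indent=2, default=list)
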