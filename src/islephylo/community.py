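"""Island x species occurrence data and period-specific flora assembly.

The occurrence matrix records, per species, a status flag (native or
exotic), a global extinct flag (meaningful only for natives) and presence
on each island.  Two time slices are derived from it:

* **pre-European** flora: the native species present on an island,
  *including* those that later went extinct;
* **current** flora: the surviving (non-extinct) natives plus the
  naturalized exotic species.

Extinction is a species-level attribute: a species flagged extinct is
excluded from the current flora of every island it occurred on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Status",
    "Period",
    "Scope",
    "SpeciesRecord",
    "IslandMeta",
    "AssemblageSpec",
    "OccurrenceMatrix",
    "assemble",
    "occurrence_spectrum",
]


class Status(str, enum.Enum):
    NATIVE = "native"
    EXOTIC = "exotic"


class Period(str, enum.Enum):
    PRE_EUROPEAN = "pre_european"
    CURRENT = "current"


class Scope(str, enum.Enum):
    COMPLETE = "complete"
    NATIVE_ONLY = "native_only"
    EXOTIC_ONLY = "exotic_only"


@dataclass(frozen=True)
class SpeciesRecord:
    name: str
    status: Status
    extinct: bool = False

    def __post_init__(self):
        if not self.name:
            raise ValueError("empty species name")
        object.__setattr__(self, "status", Status(self.status))
        if self.status is Status.EXOTIC and self.extinct:
            raise ValueError(f"{self.name!r}: an exotic species cannot be extinct")


@dataclass(frozen=True)
class IslandMeta:
    name: str
    latitude: float  # decimal degrees, south negative
    longitude: float  # decimal degrees, west negative

    def __post_init__(self):
        if not self.name:
            raise ValueError("empty island name")
        if abs(self.latitude) > 90:
            raise ValueError(f"{self.name!r}: |latitude| > 90")
        if abs(self.longitude) > 180:
            raise ValueError(f"{self.name!r}: |longitude| > 180")


@dataclass(frozen=True)
class AssemblageSpec:
    """Which time slice and which status subset of a flora to assemble."""

    period: Period
    scope: Scope = Scope.COMPLETE

    def __post_init__(self):
        object.__setattr__(self, "period", Period(self.period))
        object.__setattr__(self, "scope", Scope(self.scope))
        if self.period is Period.PRE_EUROPEAN and self.scope is Scope.EXOTIC_ONLY:
            raise ValueError(
                "pre-European exotic flora is empty by construction"
            )


class OccurrenceMatrix:
    """Presence/absence of species across islands, with status flags."""

    def __init__(
        self,
        islands: list[IslandMeta],
        species: list[SpeciesRecord],
        presence: np.ndarray,
    ):
        presence = np.asarray(presence, dtype=bool)
        if presence.shape != (len(islands), len(species)):
            raise ValueError(
                f"presence shape {presence.shape} != "
                f"({len(islands)} islands, {len(species)} species)"
            )
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        inames = [i.name for i in islands]
        if len(set(inames)) != len(inames):
            raise ValueError("duplicate island names")
        orphans = [names[j] for j in np.flatnonzero(~presence.any(axis=0))]
        if orphans:
            raise ValueError(f"species present on no island: {orphans[:5]}")
        self.islands = list(islands)
        self.species = list(species)
        self.presence = presence
        self._island_index = {m.name: i for i, m in enumerate(self.islands)}
        self._species_index = {s.name: j for j, s in enumerate(self.species)}

    # -- convenience -----------------------------------------------------

    @property
    def island_names(self) -> list[str]:
        return [m.name for m in self.islands]

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def island(self, name: str) -> IslandMeta:
        try:
            return self.islands[self._island_index[name]]
        except KeyError:
            raise KeyError(
                f"unknown island {name!r}; known: {self.island_names}"
            ) from None

    def _select(self, spec: AssemblageSpec) -> np.ndarray:
        """Boolean mask over species selected by period and scope."""
        native = np.array([s.status is Status.NATIVE for s in self.species])
        extinct = np.array([s.extinct for s in self.species])
        if spec.period is Period.PRE_EUROPEAN:
            return native  # includes later-extinct natives; scope has no exotics
        if spec.scope is Scope.COMPLETE:
            return ~extinct  # surviving natives + exotics
        if spec.scope is Scope.NATIVE_ONLY:
            return native & ~extinct
        return ~native

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, flora_path, islands_path=None) -> "OccurrenceMatrix":
        """Read ``species,status,extinct,<island...>`` plus optional metadata CSV."""
        df = pd.read_csv(flora_path)
        fixed = ["species", "status", "extinct"]
        if list(df.columns[:3]) != fixed:
            raise ValueError(f"flora CSV must start with columns {fixed}")
        island_cols = list(df.columns[3:])
        if islands_path is not None:
            meta_df = pd.read_csv(islands_path)
            meta = {
                str(r["island"]): IslandMeta(str(r["island"]), r["lat"], r["lon"])
                for _, r in meta_df.iterrows()
            }
            unknown = [c for c in island_cols if c not in meta]
            if unknown:
                raise ValueError(f"islands missing from metadata: {unknown}")
            islands = [meta[c] for c in island_cols]
        else:
            islands = [IslandMeta(c, 0.0, 0.0) for c in island_cols]
        species = [
            SpeciesRecord(str(r["species"]), Status(r["status"]), bool(r["extinct"]))
            for _, r in df.iterrows()
        ]
        presence = df[island_cols].to_numpy(dtype=int).astype(bool).T
        return cls(islands, species, presence)

    def to_csv(self, flora_path, islands_path=None) -> None:
        data = {
            "species": self.species_names,
            "status": [s.status.value for s in self.species],
            "extinct": [int(s.extinct) for s in self.species],
        }
        for i, name in enumerate(self.island_names):
            data[name] = self.presence[i].astype(int)
        pd.DataFrame(data).to_csv(flora_path, index=False)
        if islands_path is not None:
            pd.DataFrame(
                {
                    "island": self.island_names,
                    "lat": [m.latitude for m in self.islands],
                    "lon": [m.longitude for m in self.islands],
                }
            ).to_csv(islands_path, index=False)


def assemble(
    matrix: OccurrenceMatrix, island: str, spec: AssemblageSpec
) -> set[str]:
    """Species set of one island's flora for a period/scope."""
    i = matrix._island_index.get(island)
    if i is None:
        raise KeyError(f"unknown island {island!r}; known: {matrix.island_names}")
    mask = matrix.presence[i] & matrix._select(spec)
    return {matrix.species[j].name for j in np.flatnonzero(mask)}


def occurrence_spectrum(
    matrix: OccurrenceMatrix, spec: AssemblageSpec
) -> dict[int, float]:
    """Distribution of island occupancy among the species selected by ``spec``.

    Returns ``{k: fraction of selected species occurring on exactly k
    islands}``; fractions sum to 1.
    """
    mask = matrix._select(spec)
    if not mask.any():
        return {}
    counts = matrix.presence[:, mask].sum(axis=0)
    ks, freq = np.unique(counts, return_counts=True)
    total = freq.sum()
    return {int(k): float(f) / total for k, f in zip(ks, freq)}
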