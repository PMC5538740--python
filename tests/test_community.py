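"""Occurrence matrix handling and period-specific flora assembly."""

import numpy as np
import pytest

import islephylo as ip
from islephylo.community import Status


def small_matrix():
    """One island with natives {a, b(extinct), c} and exotic {x}; a second
    island so occupancy spectra have something to count."""
    islands = [ip.IslandMeta("I1", -27.0, -109.0), ip.IslandMeta("I2", -33.0, -78.0)]
    species = [
        ip.SpeciesRecord("a", "native"),
        ip.SpeciesRecord("b", "native", extinct=True),
        ip.SpeciesRecord("c", "native"),
        ip.SpeciesRecord("x", "exotic"),
    ]
    presence = np.array(
        [
            [1, 1, 1, 1],
            [1, 0, 0, 0],
        ],
        dtype=bool,
    )
    return ip.OccurrenceMatrix(islands, species, presence)


class TestAssemble:
    def test_period_rules(self):
        m = small_matrix()
        pre = ip.assemble(m, "I1", ip.AssemblageSpec("pre_european", "complete"))
        cur = ip.assemble(m, "I1", ip.AssemblageSpec("current", "complete"))
        nat = ip.assemble(m, "I1", ip.AssemblageSpec("current", "native_only"))
        exo = ip.assemble(m, "I1", ip.AssemblageSpec("current", "exotic_only"))
        assert pre == {"a", "b", "c"}  # extinct included pre-European
        assert cur == {"a", "c", "x"}  # extinct excluded, exotics included
        assert nat == {"a", "c"}
        assert exo == {"x"}

    def test_partition_identity(self):
        m = small_matrix()
        cur = ip.assemble(m, "I1", ip.AssemblageSpec("current", "complete"))
        nat = ip.assemble(m, "I1", ip.AssemblageSpec("current", "native_only"))
        exo = ip.assemble(m, "I1", ip.AssemblageSpec("current", "exotic_only"))
        assert len(cur) - len(nat) == len(exo)
        assert nat | exo == cur and not nat & exo

    def test_easter_counts_from_richness_fixture(self):
        # matrix encoding the Easter-like richness pattern: 40 natives of
        # which 14 extinct, plus 340 exotics
        natives = [
            ip.SpeciesRecord(f"n{i}", "native", extinct=i < 14) for i in range(40)
        ]
        exotics = [ip.SpeciesRecord(f"e{i}", "exotic") for i in range(340)]
        islands = [ip.IslandMeta("Easter", -27.1, -109.3)]
        m = ip.OccurrenceMatrix(
            islands, natives + exotics, np.ones((1, 380), dtype=bool)
        )
        pre = ip.assemble(m, "Easter", ip.AssemblageSpec("pre_european", "complete"))
        cur = ip.assemble(m, "Easter", ip.AssemblageSpec("current", "complete"))
        nat = ip.assemble(m, "Easter", ip.AssemblageSpec("current", "native_only"))
        exo = ip.assemble(m, "Easter", ip.AssemblageSpec("current", "exotic_only"))
        assert (len(pre), len(cur), len(nat), len(exo)) == (40, 366, 26, 340)

    def test_unknown_island(self):
        with pytest.raises(KeyError):
            ip.assemble(small_matrix(), "Atlantis",
                        ip.AssemblageSpec("current", "complete"))


class TestSpectrum:
    def test_all_singletons(self):
        islands = [ip.IslandMeta("I1", 0, 0), ip.IslandMeta("I2", 0, 0)]
        species = [ip.SpeciesRecord(f"s{i}", "native") for i in range(4)]
        presence = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=bool)
        m = ip.OccurrenceMatrix(islands, species, presence)
        spec = ip.AssemblageSpec("pre_european", "complete")
        assert ip.occurrence_spectrum(m, spec) == {1: 1.0}

    def test_half_and_half(self):
        islands = [ip.IslandMeta("I1", 0, 0), ip.IslandMeta("I2", 0, 0)]
        species = [ip.SpeciesRecord("s1", "native"), ip.SpeciesRecord("s2", "native")]
        presence = np.array([[1, 1], [0, 1]], dtype=bool)
        m = ip.OccurrenceMatrix(islands, species, presence)
        spec = ip.AssemblageSpec("pre_european", "complete")
        assert ip.occurrence_spectrum(m, spec) == {1: 0.5, 2: 0.5}

    def test_native_pool_occupancy_spectrum(self):
        # 205 natives: 166 on one island, 35 on two, 4 on three -> 81/17/2 %
        islands = [ip.IslandMeta(f"I{k}", 0, 0) for k in range(3)]
        species = [ip.SpeciesRecord(f"s{i}", "native") for i in range(205)]
        presence = np.zeros((3, 205), dtype=bool)
        presence[0, :] = True
        presence[1, 166:205] = True
        presence[2, 201:205] = True
        m = ip.OccurrenceMatrix(islands, species, presence)
        spec = ip.occurrence_spectrum(
            m, ip.AssemblageSpec("pre_european", "complete")
        )
        assert sum(spec.values()) == pytest.approx(1.0)
        assert round(100 * spec[1]) == 81
        assert round(100 * spec[2]) == 17
        assert round(100 * spec[3]) == 2


class TestValidation:
    def test_exotic_extinct_forbidden(self):
        with pytest.raises(ValueError):
            ip.SpeciesRecord("weed", "exotic", extinct=True)

    def test_pre_european_exotics_rejected(self):
        with pytest.raises(ValueError):
            ip.AssemblageSpec("pre_european", "exotic_only")

    def test_coordinates_validated(self):
        with pytest.raises(ValueError):
            ip.IslandMeta("nowhere", -95.0, 10.0)

    def test_orphan_species_rejected(self):
        islands = [ip.IslandMeta("I1", 0, 0)]
        species = [ip.SpeciesRecord("a", "native"), ip.SpeciesRecord("b", "native")]
        with pytest.raises(ValueError):
            ip.OccurrenceMatrix(islands, species, np.array([[1, 0]], dtype=bool))


def test_csv_round_trip(tmp_path):
    m = small_matrix()
    flora, meta = tmp_path / "flora.csv", tmp_path / "islands.csv"
    m.to_csv(flora, meta)
    again = ip.OccurrenceMatrix.from_csv(flora, meta)
    assert again.island_names == m.island_names
    assert again.species_names == m.species_names
    assert np.array_equal(again.presence, m.presence)
    assert [s.status for s in again.species] == [s.status for s in m.species]
    assert again.island("I1").latitude == pytest.approx(-27.0)
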