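"""Experimental design for the diatom microcosm study.

The design crosses community assemblages (subsets of an 8-species pool
drawn at five richness levels) with a herbicide-stress gradient and
replication.  The reference configuration is 39 assemblages
(8 monocultures, 10 random assemblages at richness 2, 3 and 4, and the
full 8-species community) at three atrazine concentrations
(0, 25 and 250 ug/l) in triplicate: 351 experimental units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

DEFAULT_SPECIES_POOL = [
    "Bacillaria",
    "Coscinodiscus",
    "Ditylum",
    "Guinardia",
    "Gyrosigma",
    "Odontella",
    "Thalassiosira_A",
    "Thalassiosira_B",
]

DEFAULT_ASSEMBLAGE_COUNTS = {1: 8, 2: 10, 3: 10, 4: 10, 8: 1}
DEFAULT_STRESS_LEVELS = (0.0, 25.0, 250.0)
DEFAULT_SAMPLING_DAYS = (7, 14, 21, 28)
DEFAULT_INITIAL_TOTAL_BIOVOLUME = 1e7


@dataclass(frozen=True)
class Design:
    """A full-factorial microcosm design: assemblages x stress x replicates.

    Attributes
    ----------
    species_pool : list of str
        Identifiers of the available species.
    assemblages : dict
        Maps stable assemblage ids (``"R{richness}_{index}"``) to the
        tuple of member species.
    stress_levels : tuple of float
        Stressor concentrations in ug/l.
    replicates : int
        Number of replicate microcosms per assemblage x stress cell.
    sampling_days : tuple of int
        Days since inoculation at which densities are observed.
    initial_total_biovolume : float
        Total inoculated biovolume density, split equally among the
        members of each assemblage.
    """

    species_pool: list[str]
    assemblages: dict[str, tuple[str, ...]]
    stress_levels: tuple[float, ...] = DEFAULT_STRESS_LEVELS
    replicates: int = 3
    sampling_days: tuple[int, ...] = DEFAULT_SAMPLING_DAYS
    initial_total_biovolume: float = DEFAULT_INITIAL_TOTAL_BIOVOLUME
    richness_levels: tuple[int, ...] = field(init=False, default=())

    def __post_init__(self):
        for aid, members in self.assemblages.items():
            if not members:
                raise ValueError(f"assemblage {aid!r} is empty")
            unknown = set(members) - set(self.species_pool)
            if unknown:
                raise ValueError(
                    f"assemblage {aid!r} contains unknown species {sorted(unknown)}"
                )
        levels = tuple(sorted({len(m) for m in self.assemblages.values()}))
        object.__setattr__(self, "richness_levels", levels)

    @property
    def n_units(self) -> int:
        """Total number of experimental units (microcosms)."""
        return len(self.assemblages) * len(self.stress_levels) * self.replicates

    def richness(self, assemblage_id: str) -> int:
        return len(self.assemblages[assemblage_id])

    def monoculture_id(self, species: str) -> str | None:
        """Assemblage id of the monoculture of `species`, if one exists."""
        for aid, members in self.assemblages.items():
            if members == (species,):
                return aid
        return None

    def initial_densities(self, assemblage_id: str) -> dict[str, float]:
        """Equal-proportion inoculation densities for one assemblage."""
        members = self.assemblages[assemblage_id]
        per_species = self.initial_total_biovolume / len(members)
        return {sp: per_species for sp in members}

    def mixed_assemblages(self) -> list[str]:
        """Ids of assemblages with at least two species."""
        return [a for a, m in self.assemblages.items() if len(m) >= 2]


def build_design(
    seed: int,
    pool_size: int = 8,
    assemblage_counts: dict[int, int] | None = None,
    species_pool: list[str] | None = None,
    **kwargs,
) -> Design:
    """Draw a randomised assemblage design.

    Within each richness level, assemblages are distinct random subsets of
    the species pool drawn without replacement.  When the requested count
    at richness 1 equals the pool size, every monoculture is included.

    Parameters
    ----------
    seed : int
        Seed for the assemblage draw; the design is reproducible per seed.
    pool_size : int
        Number of species in the pool.
    assemblage_counts : dict richness -> count
        How many assemblages to draw at each richness level.
    species_pool : list of str, optional
        Species names; defaults to the 8 diatom genera, or generic names
        for other pool sizes.
    kwargs
        Forwarded to :class:`Design` (stress_levels, replicates, ...).
    """
    if assemblage_counts is None:
        assemblage_counts = dict(DEFAULT_ASSEMBLAGE_COUNTS)
    if species_pool is None:
        if pool_size == len(DEFAULT_SPECIES_POOL):
            species_pool = list(DEFAULT_SPECIES_POOL)
        else:
            species_pool = [f"sp{i + 1}" for i in range(pool_size)]
    if len(species_pool) != pool_size:
        raise ValueError("species_pool length must equal pool_size")

    rng = np.random.default_rng(seed)
    assemblages: dict[str, tuple[str, ...]] = {}
    for richness in sorted(assemblage_counts):
        count = assemblage_counts[richness]
        n_possible = comb(pool_size, richness)
        if count > n_possible:
            raise ValueError(
                f"richness {richness}: requested {count} assemblages but only "
                f"{n_possible} distinct subsets exist for a pool of {pool_size}"
            )
        if count == n_possible:
            # exhaustive: includes all monocultures at richness 1
            subsets = [tuple(c) for c in combinations(species_pool, richness)]
        else:
            chosen: set[tuple[str, ...]] = set()
            while len(chosen) < count:
                idx = rng.choice(pool_size, size=richness, replace=False)
                chosen.add(tuple(species_pool[i] for i in sorted(idx)))
            subsets = sorted(chosen)
        for i, members in enumerate(subsets, start=1):
            assemblages[f"R{richness}_{i}"] = members

    return Design(species_pool=species_pool, assemblages=assemblages, **kwargs)
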