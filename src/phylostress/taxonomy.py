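"""Focal-species lineage model: ordered phylostrata and divergence ranks.

A phylostratigraphic lineage is the chain of internodes (phylostrata) on the
path from the root of cellular life to the focal species.  Every stratum
carries an integer rank — the PAI value genes founded at that level receive —
and the set of species whose lineages split from the focal lineage at that
internode.  Strata with a single daughter taxon contribute no phylogenetic
information and can be collapsed, either keeping the surviving ranks
untouched (so published PAI values stay comparable) or renumbering the chain
compactly from 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Phylostratum:
    """One internode of the focal lineage.

    Parameters
    ----------
    name : str
        Taxon name, unique within a lineage.
    rank : int
        The PAI value assigned to genes founded at this level (0 = root).
    species : frozenset of str
        Identifiers of species that diverge from the focal lineage here.
    """

    name: str
    rank: int
    species: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError(f"stratum rank must be >= 0, got {self.rank}")
        object.__setattr__(self, "species", frozenset(self.species))


@dataclass(frozen=True)
class Lineage:
    """Ordered root-to-focal chain of phylostrata.

    Invariants: ranks strictly increase root to terminal, names are unique,
    the terminal stratum contains the focal species, and every species
    identifier occurs in exactly one stratum.
    """

    strata: tuple
    focal_species: str

    def __post_init__(self) -> None:
        strata = tuple(self.strata)
        object.__setattr__(self, "strata", strata)
        if not strata:
            raise ValueError("lineage must contain at least one stratum")
        ranks = [s.rank for s in strata]
        if any(b <= a for a, b in zip(ranks, ranks[1:])):
            raise ValueError(f"ranks must strictly increase root to focal: {ranks}")
        names = [s.name for s in strata]
        if len(set(names)) != len(names):
            raise ValueError("stratum names must be unique")
        if self.focal_species not in strata[-1].species:
            raise ValueError(
                f"terminal stratum {strata[-1].name!r} must contain focal species "
                f"{self.focal_species!r}"
            )
        seen: dict = {}
        for s in strata:
            for sp in s.species:
                if sp in seen:
                    raise ValueError(
                        f"species {sp!r} assigned to both {seen[sp]!r} and {s.name!r}"
                    )
                seen[sp] = s.name
        object.__setattr__(self, "_species_rank", {})
        for s in strata:
            for sp in s.species:
                self._species_rank[sp] = s.rank

    @property
    def terminal(self) -> Phylostratum:
        return self.strata[-1]

    @property
    def terminal_rank(self) -> int:
        return self.strata[-1].rank

    @property
    def ranks(self) -> tuple:
        return tuple(s.rank for s in self.strata)

    @property
    def names(self) -> tuple:
        return tuple(s.name for s in self.strata)

    def species_rank(self, species: str) -> int:
        try:
            return self._species_rank[species]
        except KeyError:
            raise KeyError(f"species {species!r} not assigned to any stratum") from None

    def __len__(self) -> int:
        return len(self.strata)


def collapse_single_child(lineage: Lineage, drop_names, mode: str = "keep_ranks") -> Lineage:
    """Remove strata (typically single-daughter internodes) from a lineage.

    Parameters
    ----------
    lineage : Lineage
    drop_names : set of str
        Names of strata to remove.  The terminal stratum may not be dropped.
    mode : {"keep_ranks", "compact_ranks"}
        ``keep_ranks`` leaves the surviving ranks untouched (gaps allowed) so
        that previously published PAI values remain directly comparable;
        ``compact_ranks`` renumbers the survivors 0..K-1 preserving order.

    Species assigned to a dropped stratum are reassigned to its parent (the
    nearest surviving stratum toward the root), which preserves the
    basal-most-shared-taxon semantics of divergence ranks; if the root itself
    is dropped, its species move to the new root.
    """
    drop = set(drop_names)
    if mode not in ("keep_ranks", "compact_ranks"):
        raise ValueError(f"unknown mode {mode!r}")
    unknown = drop - set(lineage.names)
    if unknown:
        raise KeyError(f"unknown stratum name(s) in drop set: {sorted(unknown)}")
    if lineage.terminal.name in drop:
        raise ValueError("cannot drop the terminal (focal) stratum")
    if not drop:
        return lineage

    survivors: list = []
    orphaned: list = []  # species waiting for the next surviving root-ward stratum
    for s in lineage.strata:
        if s.name in drop:
            orphaned.extend(s.species)
            continue
        if survivors and orphaned:
            # mid-chain drop: orphans attach to the parent already emitted
            parent = survivors[-1]
            survivors[-1] = Phylostratum(
                parent.name, parent.rank, parent.species | frozenset(orphaned)
            )
            orphaned = []
        if not survivors and orphaned:
            # dropped root: orphans attach to the new root
            s = Phylostratum(s.name, s.rank, s.species | frozenset(orphaned))
            orphaned = []
        survivors.append(s)

    if mode == "compact_ranks":
        survivors = [
            Phylostratum(s.name, i, s.species) for i, s in enumerate(survivors)
        ]
    return Lineage(tuple(survivors), lineage.focal_species)


def divergence_rank(species: str, lineage: Lineage) -> int:
    """Rank of the stratum holding *species*: the most basal taxon shared by
    the focal and subject species on the focal lineage.

    Raises ``KeyError`` if the species is absent from every stratum.
    """
    return lineage.species_rank(species)
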