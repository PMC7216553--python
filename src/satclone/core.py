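"""Domain types for multilocus microsatellite genotypes.

The analysis operates on diploid hybrid parthenogens: every individual
carries, at each microsatellite locus, one allele inherited from the
maternal bisexual species and one from the paternal species.  An allele is
described by the lengths of its variable repeat tracts plus the states of a
set of flanking single-nucleotide / indel sites; species-diagnostic flanking
sites are what allow each allele to be phased to a parental side.

Allele identity is *structural*: two :class:`AlleleRecord` objects are equal
whenever locus, tract lengths and full SNP profile agree, regardless of
catalog labels.  Everything downstream (phasing, clone calling, allele
counts, network coding) relies on this equality.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

GAP = "-"
#: states permitted at a flanking site; the gap is an ordinary fifth state
SITE_STATES = ("A", "C", "G", "T", GAP)


class Species(str, enum.Enum):
    """Which of the three species an individual or catalog allele belongs to."""

    PARTHENOGEN = "parthenogen"
    MATERNAL = "maternal_sp"
    PATERNAL = "paternal_sp"


class SatcloneError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class LocusDef:
    """Definition of a microsatellite locus.

    Parameters
    ----------
    name:
        Locus identifier (e.g. ``"Du281"``).
    motif:
        Repeat unit of the microsatellite (e.g. ``"GATA"`` for a
        tetranucleotide locus).  Informational only.
    variable_tracts:
        Ordered identifiers of the homogeneous repeat runs whose length
        varies among alleles.
    snp_positions:
        Ordered identifiers of flanking sites scored for each allele.
    """

    name: str
    motif: str
    variable_tracts: tuple[str, ...]
    snp_positions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "variable_tracts", tuple(self.variable_tracts))
        object.__setattr__(self, "snp_positions", tuple(self.snp_positions))
        if len(set(self.variable_tracts)) != len(self.variable_tracts):
            raise ValueError(f"locus {self.name}: duplicate tract identifiers")
        if len(set(self.snp_positions)) != len(self.snp_positions):
            raise ValueError(f"locus {self.name}: duplicate SNP site identifiers")
        if not self.variable_tracts and not self.snp_positions:
            raise ValueError(
                f"locus {self.name}: needs at least one variable tract or SNP site"
            )


@dataclass(frozen=True, eq=False)
class AlleleRecord:
    """One microsatellite allele: repeat-tract lengths + flanking SNP profile.

    Equality and hashing are structural over ``(locus, tract_lengths,
    snp_profile)``; ``allele_id``, ``source_species`` and ``sequence`` are
    bookkeeping and never influence identity.
    """

    locus: str
    tract_lengths: Mapping[str, int]
    snp_profile: Mapping[str, str] = field(default_factory=dict)
    allele_id: Optional[str] = None
    source_species: Optional[Species] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tract_lengths", dict(self.tract_lengths))
        object.__setattr__(self, "snp_profile", dict(self.snp_profile))
        for tract, length in self.tract_lengths.items():
            if int(length) < 0:
                raise ValueError(f"negative tract length at {self.locus}:{tract}")
        for site, state in self.snp_profile.items():
            if state not in SITE_STATES:
                raise ValueError(
                    f"invalid state {state!r} at {self.locus}:{site}; "
                    f"allowed: {SITE_STATES}"
                )

    def key(self) -> tuple:
        """Canonical hashable identity of this allele."""
        return (
            self.locus,
            tuple(sorted(self.tract_lengths.items())),
            tuple(sorted(self.snp_profile.items())),
        )

    def validate_against(self, locus: LocusDef) -> None:
        """Check that this allele's fields cover exactly the locus definition."""
        if self.locus != locus.name:
            raise ValueError(f"allele labelled {self.locus}, locus is {locus.name}")
        if set(self.tract_lengths) != set(locus.variable_tracts):
            raise ValueError(
                f"{locus.name}: tract keys {sorted(self.tract_lengths)} != "
                f"defined tracts {list(locus.variable_tracts)}"
            )
        if set(self.snp_profile) != set(locus.snp_positions):
            raise ValueError(
                f"{locus.name}: SNP keys {sorted(self.snp_profile)} != "
                f"defined sites {list(locus.snp_positions)}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleRecord):
            return NotImplemented
        return self.key() == other.key()

    def __hash__(self) -> int:
        return hash(self.key())

    def __repr__(self) -> str:  # compact, stable
        tracts = ",".join(str(v) for _, v in sorted(self.tract_lengths.items()))
        snps = "".join(v for _, v in sorted(self.snp_profile.items()))
        label = f" id={self.allele_id}" if self.allele_id is not None else ""
        return f"<Allele {self.locus}{label} tracts={tracts} snps={snps}>"


@dataclass(frozen=True, eq=False)
class UnphasedGenotype:
    """An individual's two alleles at one locus, with no parental order."""

    individual_id: str
    locus: str
    alleles: tuple[AlleleRecord, AlleleRecord]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("a genotype holds exactly two alleles")
        for a in self.alleles:
            if a.locus != self.locus:
                raise ValueError(
                    f"allele at {a.locus} in genotype for locus {self.locus}"
                )

    def allele_multiset(self) -> tuple:
        return tuple(sorted(a.key() for a in self.alleles))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnphasedGenotype):
            return NotImplemented
        return (
            self.individual_id == other.individual_id
            and self.locus == other.locus
            and self.allele_multiset() == other.allele_multiset()
        )

    def __hash__(self) -> int:
        return hash((self.individual_id, self.locus, self.allele_multiset()))


@dataclass
class Individual:
    """One sampled animal: population, species and per-locus genotypes."""

    individual_id: str
    population: str
    species: Species
    genotypes: dict[str, UnphasedGenotype] = field(default_factory=dict)
    mt_haplotype: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"{self.individual_id}: empty population name")
        for locus, g in self.genotypes.items():
            if g.locus != locus:
                raise ValueError(
                    f"{self.individual_id}: genotype keyed {locus} is for {g.locus}"
                )


@dataclass
class Cohort:
    """A set of individuals of one species scored over a shared locus panel."""

    species: Species
    individuals: list[Individual]
    loci: list[LocusDef]

    def __post_init__(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")
        defined = {l.name: l for l in self.loci}
        for ind in self.individuals:
            for locus, g in ind.genotypes.items():
                if locus not in defined:
                    raise ValueError(
                        f"{ind.individual_id}: genotype at undefined locus {locus}"
                    )
                for a in g.alleles:
                    a.validate_against(defined[locus])

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.population, None)
        return list(seen)

    def locus(self, name: str) -> LocusDef:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(f"locus {name} not defined in cohort")

    def by_population(self, population: str) -> list[Individual]:
        out = [i for i in self.individuals if i.population == population]
        if not out:
            raise KeyError(f"no individuals in population {population!r}")
        return out

    def complete_individuals(self) -> list[Individual]:
        """Individuals genotyped at every defined locus."""
        names = set(self.locus_names)
        return [i for i in self.individuals if names <= set(i.genotypes)]

    def __len__(self) -> int:
        return len(self.individuals)


# A catalog maps locus name -> the alleles known for one parental species.
Catalog = Mapping[str, Sequence[AlleleRecord]]


def catalog_from_cohort(cohort: Cohort) -> dict[str, list[AlleleRecord]]:
    """Distinct alleles per locus observed in a cohort, in order of appearance."""
    catalog: dict[str, list[AlleleRecord]] = {l.name: [] for l in cohort.loci}
    seen: dict[str, set] = {l.name: set() for l in cohort.loci}
    for ind in cohort.individuals:
        for locus, g in ind.genotypes.items():
            for a in g.alleles:
                if a.key() not in seen[locus]:
                    seen[locus].add(a.key())
                    catalog[locus].append(a)
    return catalog


def distinct_alleles(alleles: Iterable[AlleleRecord]) -> list[AlleleRecord]:
    """Deduplicate alleles structurally, keeping first occurrences."""
    seen: set = set()
    out: list[AlleleRecord] = []
    for a in alleles:
        if a.key() not in seen:
            seen.add(a.key())
            out.append(a)
    return out
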