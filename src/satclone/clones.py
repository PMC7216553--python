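"""Clone delineation and clonal-diversity tables.

A clone is an equivalence class of individuals sharing an identical phased
multilocus genotype (structural allele equality at every locus, maternal
and paternal side).  Clones are named C1, C2, … by descending total count,
ties broken by lexicographic order of the composition; a reference mapping
can restore externally published clone labels.

Per population, clonal diversity is ``100 · k / n`` with ``k`` clones
observed among ``n`` individuals.  Percentages are half-up rounded to one
decimal for display; the exact rationals are always retained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping, NamedTuple, Optional, Union

import pandas as pd

from .core import AlleleRecord, SatcloneError
from .phasing import PhasedCohort


def round_half_up(value: Union[Fraction, float], ndigits: int) -> float:
    """Decimal half-up rounding (3/109 → 0.028 at 3 d.p., 4/34·100 → 11.8 at 1 d.p.)."""
    if isinstance(value, Fraction):
        dec = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        dec = Decimal(repr(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(dec.quantize(q, rounding=ROUND_HALF_UP))


def composition_key(
    genotypes: Mapping[str, tuple[AlleleRecord, AlleleRecord]], locus_order: list[str]
) -> tuple:
    """Canonical hashable key for a phased multilocus genotype."""
    return tuple(
        (locus, genotypes[locus][0].key(), genotypes[locus][1].key())
        for locus in locus_order
    )


@dataclass
class CloneRecord:
    """One clone: name, representative composition, members and counts."""

    name: str
    genotypes: dict[str, tuple[AlleleRecord, AlleleRecord]]
    members: list[str]
    population_counts: dict[str, int]
    total: int
    frequency: Fraction

    def key(self, locus_order: list[str]) -> tuple:
        return composition_key(self.genotypes, locus_order)


class PopulationSummary(NamedTuple):
    n_individuals: int
    n_clones: int
    diversity_percent: Fraction  # exact 100k/n


class DiversityValue(NamedTuple):
    percent: float  # half-up, 1 d.p.
    exact: Fraction


@dataclass
class CloneTable:
    """Clones with per-population counts plus per-population summaries."""

    clones: list[CloneRecord]
    locus_order: list[str]
    populations: list[str]
    population_summaries: dict[str, PopulationSummary]
    excluded: list[str] = field(default_factory=list)  # individuals lacking loci

    @property
    def n_total(self) -> int:
        return sum(c.total for c in self.clones)

    def clone(self, name: str) -> CloneRecord:
        for c in self.clones:
            if c.name == name:
                return c
        raise KeyError(f"no clone named {name}")

    def membership(self) -> dict[str, str]:
        """individual id -> clone name."""
        return {m: c.name for c in self.clones for m in c.members}

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clones:
            row = {"clone": c.name}
            row.update({pop: c.population_counts.get(pop, 0) for pop in self.populations})
            row["total"] = c.total
            row["frequency"] = round_half_up(c.frequency, 3)
            rows.append(row)
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "population": pop,
                "n_individuals": s.n_individuals,
                "n_clones": s.n_clones,
                "clonal_diversity_percent": round_half_up(s.diversity_percent, 1),
            }
            for pop, s in self.population_summaries.items()
        ]
        return pd.DataFrame(rows)

    def write(self, directory, prefix: str = "clones") -> None:
        """Export clone × population counts, population summary, JSON digest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.counts_frame().to_csv(directory / f"{prefix}_by_population.tsv", sep="\t", index=False)
        self.summary_frame().to_csv(directory / f"{prefix}_population_summary.tsv", sep="\t", index=False)
        digest = {
            "n_individuals": self.n_total,
            "n_clones": len(self.clones),
            "clones": [
                {
                    "name": c.name,
                    "total": c.total,
                    "frequency": round_half_up(c.frequency, 3),
                    "populations": {p: n for p, n in sorted(c.population_counts.items()) if n},
                }
                for c in self.clones
            ],
            "excluded_individuals": self.excluded,
        }
        with open(directory / f"{prefix}_summary.json", "w", encoding="utf-8") as fh:
            json.dump(digest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def call_clones(phased: PhasedCohort) -> CloneTable:
    """Delineate clones as unique phased multilocus genotypes.

    Individuals not phased at every locus are excluded (with a warning) and
    listed in ``CloneTable.excluded``.
    """
    cohort = phased.cohort
    locus_order = cohort.locus_names
    callable_ids = set(phased.phased_individuals())
    excluded = [
        ind.individual_id for ind in cohort.individuals
        if ind.individual_id not in callable_ids
    ]
    if excluded:
        warnings.warn(
            f"{len(excluded)} individual(s) lack a complete phased genotype and "
            f"were excluded from clone calling: {excluded[:5]}...",
            stacklevel=2,
        )

    population_of = {i.individual_id: i.population for i in cohort.individuals}
    groups: dict[tuple, dict] = {}
    for ind in cohort.individuals:  # cohort order; membership order-stable
        ind_id = ind.individual_id
        if ind_id not in callable_ids:
            continue
        genos = {
            locus: (pg.maternal_allele, pg.paternal_allele)
            for locus, pg in phased.genotypes[ind_id].items()
        }
        key = composition_key(genos, locus_order)
        g = groups.setdefault(key, {"genotypes": genos, "members": []})
        g["members"].append(ind_id)

    n_total = sum(len(g["members"]) for g in groups.values())
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]["members"]), kv[0]))

    populations = []
    for ind in cohort.individuals:
        if ind.population not in populations:
            populations.append(ind.population)

    clones = []
    for rank, (key, g) in enumerate(ordered, start=1):
        members = g["members"]
        pop_counts: dict[str, int] = {}
        for m in members:
            pop_counts[population_of[m]] = pop_counts.get(population_of[m], 0) + 1
        clones.append(
            CloneRecord(
                name=f"C{rank}",
                genotypes=g["genotypes"],
                members=members,
                population_counts=pop_counts,
                total=len(members),
                frequency=Fraction(len(members), n_total) if n_total else Fraction(0),
            )
        )

    summaries: dict[str, PopulationSummary] = {}
    for pop in populations:
        n = sum(c.population_counts.get(pop, 0) for c in clones)
        k = sum(1 for c in clones if c.population_counts.get(pop, 0) > 0)
        if n:
            summaries[pop] = PopulationSummary(n, k, Fraction(100 * k, n))
    return CloneTable(clones, locus_order, populations, summaries, excluded)


def clonal_diversity(table: CloneTable, population: str) -> DiversityValue:
    """Clonal diversity of one population: 100 · clones / individuals."""
    if population not in table.population_summaries:
        raise SatcloneError(f"population {population!r} not in clone table")
    s = table.population_summaries[population]
    if s.n_individuals == 0:
        raise SatcloneError(f"population {population!r} is empty")
    return DiversityValue(round_half_up(s.diversity_percent, 1), s.diversity_percent)


def map_to_reference_names(
    table: CloneTable,
    reference: Union[Mapping[tuple, str], list[tuple[tuple, str]]],
    unmatched_suffix: str = "*",
) -> CloneTable:
    """Rename clones to match a reference composition → name mapping.

    Clones matching a reference composition take its name; unmatched clones
    keep their canonical names with ``unmatched_suffix`` appended (kept
    distinct from every reference name).  Raises if two references share a
    composition.
    """
    if not isinstance(reference, Mapping):
        seen: dict[tuple, str] = {}
        for comp, name in reference:
            if comp in seen:
                raise SatcloneError(
                    f"reference names {seen[comp]!r} and {name!r} share one composition"
                )
            seen[comp] = name
        reference = seen

    taken = set(reference.values())
    new_clones = []
    for c in table.clones:
        key = c.key(table.locus_order)
        if key in reference:
            name = reference[key]
        elif not reference:  # nothing to collide with: keep canonical names
            name = c.name
        else:
            name = c.name + unmatched_suffix
            while name in taken:
                name += unmatched_suffix
        taken.add(name)
        new_clones.append(
            CloneRecord(name, c.genotypes, c.members, c.population_counts, c.total, c.frequency)
        )
    return CloneTable(
        new_clones, table.locus_order, table.populations,
        table.population_summaries, table.excluded,
    )
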