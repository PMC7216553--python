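"""Bundled reference dataset: *Darevskia unisexualis* clone survey.

The parthenogenetic Caucasian rock lizard *D. unisexualis* arose from
hybridization of female *D. raddei nairensis* (maternal) and male
*D. valentini* (paternal).  The reference dataset covers 109 individuals
from seven Armenian populations (Artavaz, Hrazdan, Kuchak, Lchap, Noratus,
Sevan, Tsovak) genotyped at four tetranucleotide microsatellite loci
(Du215, Du281, Du323, Du47G), falling into 12 multilocus clones (C1–C12),
together with allele catalogs for the two parental species.

Each allele is modelled as one variable repeat tract plus flanking sites:

* one species-diagnostic site per locus (``diag1``), fixed within each
  parental species and differing between them — the basis of parental
  phasing and of the single-origin test;
* the polymorphic flanking indel sites that, together with repeat counts,
  distinguish the catalog alleles (``site1`` … ``site6``; the gap ``-`` is
  an ordinary fifth state).

Clone composition is written ``Du281(3 + 6)``: maternal-species allele
label 3 plus paternal-species allele label 6.  Labels are catalog
bookkeeping; allele identity is structural, and under this encoding the
cohort carries 14 structurally distinct alleles (3 at Du215, 6 at Du281,
2 at Du323, 3 at Du47G).
"""

from __future__ import annotations

from typing import NamedTuple

from .core import AlleleRecord, Cohort, GAP, Individual, LocusDef, Species, UnphasedGenotype

POPULATIONS = ["Artavaz", "Hrazdan", "Kuchak", "Lchap", "Noratus", "Sevan", "Tsovak"]

UNISEXUALIS_LOCI = [
    LocusDef("Du215", "GATA", ("t1",), ("diag1", "site1")),
    LocusDef("Du281", "GATA", ("t1",), ("diag1", "site2", "site3", "site4", "site5")),
    LocusDef("Du323", "GATA", ("t1",), ("diag1",)),
    LocusDef("Du47G", "GATA", ("t1",), ("diag1", "site6")),
]

# Diagnostic flanking states: fixed within each parental species, disjoint
# between them.  The published survey gives only that the combinations are
# parent-specific; two arbitrary distinct states stand in for them.
_MAT_DIAG = "C"
_PAT_DIAG = "T"


def _mat(locus: str, label: str, tract: int, **sites: str) -> AlleleRecord:
    locus_def = {l.name: l for l in UNISEXUALIS_LOCI}[locus]
    profile = {s: GAP for s in locus_def.snp_positions}
    profile["diag1"] = _MAT_DIAG
    profile.update(sites)
    return AlleleRecord(locus, {"t1": tract}, profile, allele_id=label,
                        source_species=Species.MATERNAL)


def _pat(locus: str, label: str, tract: int, **sites: str) -> AlleleRecord:
    locus_def = {l.name: l for l in UNISEXUALIS_LOCI}[locus]
    profile = {s: GAP for s in locus_def.snp_positions}
    profile["diag1"] = _PAT_DIAG
    profile.update(sites)
    return AlleleRecord(locus, {"t1": tract}, profile, allele_id=label,
                        source_species=Species.PATERNAL)


# Maternal-species (D. raddei nairensis) allele catalog.  Du281 labels 4 and
# 5 are structurally identical (no scored site separates them); they are
# distinct catalog labels only.
_MATERNAL_ALLELES: dict[str, dict[str, AlleleRecord]] = {
    "Du215": {"1": _mat("Du215", "1", 4)},
    "Du281": {
        "1": _mat("Du281", "1", 12, site2="A", site3="A", site4="A"),
        "2": _mat("Du281", "2", 11, site2="A", site3="A"),
        "3": _mat("Du281", "3", 10, site2="A"),
        "4": _mat("Du281", "4", 9),
        "5": _mat("Du281", "5", 9),
    },
    "Du323": {"1": _mat("Du323", "1", 7)},
    "Du47G": {"1": _mat("Du47G", "1", 5)},
}

# Paternal-species (D. valentini) catalog; Du281 labels 4 and 5 likewise
# coincide structurally.
_PATERNAL_ALLELES: dict[str, dict[str, AlleleRecord]] = {
    "Du215": {
        "2": _pat("Du215", "2", 10, site1="A"),
        "3": _pat("Du215", "3", 9),
    },
    "Du281": {
        "4": _pat("Du281", "4", 10, site5="A"),
        "5": _pat("Du281", "5", 10, site5="A"),
        "6": _pat("Du281", "6", 9),
    },
    "Du323": {"2": _pat("Du323", "2", 2)},
    "Du47G": {
        "2": _pat("Du47G", "2", 4, site6="A"),
        "3": _pat("Du47G", "3", 3),
    },
}

#: clone -> per-locus (maternal label, paternal label)
CLONE_COMPOSITIONS: dict[str, dict[str, tuple[str, str]]] = {
    "C1": {"Du215": ("1", "3"), "Du281": ("3", "6"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C2": {"Du215": ("1", "2"), "Du281": ("5", "6"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C3": {"Du215": ("1", "3"), "Du281": ("3", "4"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C4": {"Du215": ("1", "3"), "Du281": ("1", "6"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C5": {"Du215": ("1", "2"), "Du281": ("3", "6"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C6": {"Du215": ("1", "3"), "Du281": ("3", "6"), "Du323": ("1", "2"), "Du47G": ("1", "2")},
    "C7": {"Du215": ("1", "3"), "Du281": ("4", "5"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C8": {"Du215": ("1", "2"), "Du281": ("5", "6"), "Du323": ("1", "2"), "Du47G": ("1", "2")},
    "C9": {"Du215": ("1", "3"), "Du281": ("5", "6"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C10": {"Du215": ("1", "3"), "Du281": ("3", "4"), "Du323": ("1", "2"), "Du47G": ("1", "2")},
    "C11": {"Du215": ("1", "3"), "Du281": ("2", "6"), "Du323": ("1", "2"), "Du47G": ("1", "3")},
    "C12": {"Du215": ("1", "3"), "Du281": ("1", "6"), "Du323": ("1", "2"), "Du47G": ("1", "2")},
}

#: clone -> per-population individual counts (populations in POPULATIONS order)
CLONE_COUNTS: dict[str, tuple[int, ...]] = {
    "C1": (1, 4, 4, 2, 1, 2, 23),
    "C2": (28, 0, 0, 0, 0, 0, 0),
    "C3": (0, 0, 4, 10, 0, 0, 0),
    "C4": (0, 0, 0, 0, 14, 0, 0),
    "C5": (3, 0, 0, 0, 0, 1, 0),
    "C6": (0, 0, 0, 1, 0, 0, 2),
    "C7": (0, 0, 2, 0, 0, 0, 0),
    "C8": (2, 0, 0, 0, 0, 0, 0),
    "C9": (0, 1, 1, 0, 0, 0, 0),
    "C10": (0, 0, 1, 0, 0, 0, 0),
    "C11": (0, 0, 0, 0, 1, 0, 0),
    "C12": (0, 0, 0, 0, 1, 0, 0),
}


class UnisexualisDataset(NamedTuple):
    """The bundled reference dataset and its clone composition map."""

    parthenogen: Cohort
    maternal_panel: Cohort
    paternal_panel: Cohort
    clone_names: dict[tuple, str]  # composition key -> published clone name


def clone_genotypes(name: str) -> dict[str, tuple[AlleleRecord, AlleleRecord]]:
    """Per-locus (maternal allele, paternal allele) records for one clone."""
    comp = CLONE_COMPOSITIONS[name]
    return {
        locus: (_MATERNAL_ALLELES[locus][m], _PATERNAL_ALLELES[locus][p])
        for locus, (m, p) in comp.items()
    }


def composition_key(genotypes: dict[str, tuple[AlleleRecord, AlleleRecord]],
                    locus_order: list[str]) -> tuple:
    """Canonical hashable key of a phased multilocus genotype."""
    return tuple(
        (locus, genotypes[locus][0].key(), genotypes[locus][1].key())
        for locus in locus_order
    )


def _parthenogen_cohort() -> Cohort:
    locus_order = [l.name for l in UNISEXUALIS_LOCI]
    counters = {pop: 0 for pop in POPULATIONS}
    individuals: list[Individual] = []
    for clone in CLONE_COMPOSITIONS:
        genos = clone_genotypes(clone)
        for pop, count in zip(POPULATIONS, CLONE_COUNTS[clone]):
            for _ in range(count):
                counters[pop] += 1
                ind_id = f"{pop}-{counters[pop]:02d}"
                genotypes = {
                    locus: UnphasedGenotype(ind_id, locus, genos[locus])
                    for locus in locus_order
                }
                individuals.append(
                    Individual(ind_id, pop, Species.PARTHENOGEN, genotypes)
                )
    individuals.sort(key=lambda i: (POPULATIONS.index(i.population), i.individual_id))
    return Cohort(Species.PARTHENOGEN, individuals, list(UNISEXUALIS_LOCI))


def _panel(species: Species, alleles: dict[str, dict[str, AlleleRecord]],
           pairs: list[dict[str, tuple[str, str]]], pop: str) -> Cohort:
    individuals = []
    for i, locus_pairs in enumerate(pairs, start=1):
        ind_id = f"{pop}-{i:02d}"
        genotypes = {}
        for locus, (a, b) in locus_pairs.items():
            genotypes[locus] = UnphasedGenotype(
                ind_id, locus, (alleles[locus][a], alleles[locus][b])
            )
        individuals.append(Individual(ind_id, pop, species, genotypes))
    return Cohort(species, individuals, list(UNISEXUALIS_LOCI))


def load_unisexualis_dataset() -> UnisexualisDataset:
    """Build the bundled reference dataset.

    Returns the 109-individual parthenogen cohort, small parental panels
    that carry every catalog allele referenced by the clone compositions,
    and the mapping from phased multilocus composition to published clone
    name (C1–C12).
    """
    parthenogen = _parthenogen_cohort()

    maternal_pairs = [
        {"Du215": ("1", "1"), "Du281": ("1", "2"), "Du323": ("1", "1"), "Du47G": ("1", "1")},
        {"Du215": ("1", "1"), "Du281": ("3", "4"), "Du323": ("1", "1"), "Du47G": ("1", "1")},
        {"Du215": ("1", "1"), "Du281": ("5", "3"), "Du323": ("1", "1"), "Du47G": ("1", "1")},
    ]
    paternal_pairs = [
        {"Du215": ("2", "3"), "Du281": ("4", "5"), "Du323": ("2", "2"), "Du47G": ("2", "3")},
        {"Du215": ("3", "3"), "Du281": ("6", "6"), "Du323": ("2", "2"), "Du47G": ("3", "3")},
    ]
    maternal_panel = _panel(Species.MATERNAL, _MATERNAL_ALLELES, maternal_pairs, "nairensis_panel")
    paternal_panel = _panel(Species.PATERNAL, _PATERNAL_ALLELES, paternal_pairs, "valentini_panel")

    locus_order = [l.name for l in UNISEXUALIS_LOCI]
    clone_names = {
        composition_key(clone_genotypes(name), locus_order): name
        for name in CLONE_COMPOSITIONS
    }
    return UnisexualisDataset(parthenogen, maternal_panel, paternal_panel, clone_names)
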