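"""Parental phasing of alleles via species-diagnostic flanking SNPs.

In a diploid hybrid parthenogen every locus carries one allele from each
parental species.  Flanking sites whose observed states are disjoint
between the two parental catalogs are *diagnostic*: the state of a query
allele at such sites identifies its parental side regardless of repeat
mutations accumulated since the founding hybridization.  Side assignment
therefore uses diagnostic sites only, by majority vote over sites, with
ties left unassigned.

The single-origin test follows: if all individuals share one combination
of parent-specific diagnostic states over all loci and both sides, the
data are consistent with a single founding hybridization event; multiple
combinations indicate (at least) as many independent origins.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .core import AlleleRecord, Catalog, Cohort, SatcloneError


class Side(str, enum.Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNASSIGNED = "unassigned"


class Match(str, enum.Enum):
    PERFECT = "perfect"
    SNP_MISMATCH = "snp_mismatch"
    REPEAT_MISMATCH = "repeat_mismatch"
    BOTH_MISMATCH = "both_mismatch"


@dataclass(frozen=True)
class AlleleAssignment:
    """Side call and catalog-match quality for one allele occurrence."""

    allele: AlleleRecord
    side: Side
    match: Match
    matched_catalog_allele: Optional[str] = None


@dataclass(frozen=True)
class PhasedGenotype:
    """Per-individual, per-locus (maternal allele, paternal allele) pair."""

    individual_id: str
    locus: str
    maternal_allele: AlleleRecord
    paternal_allele: AlleleRecord

    def __post_init__(self) -> None:
        if self.maternal_allele.locus != self.locus or self.paternal_allele.locus != self.locus:
            raise ValueError("phased alleles must belong to the genotype's locus")


@dataclass
class PhaseFailure:
    """A genotype that could not be split into one maternal + one paternal allele."""

    individual_id: str
    locus: str
    sides: tuple[Side, Side]
    reason: str


@dataclass
class PhasedCohort:
    """Phasing result: phased genotypes, failures, and a per-allele report."""

    cohort: Cohort
    genotypes: dict[str, dict[str, PhasedGenotype]]  # individual -> locus -> phased
    failures: list[PhaseFailure]
    assignments: list[tuple[str, str, AlleleAssignment]]  # (individual, locus, assignment)
    diagnostic_sites: dict[str, dict[str, tuple[frozenset, frozenset]]]

    @property
    def n_phased(self) -> int:
        return sum(len(v) for v in self.genotypes.values())

    def phased_individuals(self) -> list[str]:
        """Individuals phased at every locus of the cohort panel (clone-callable)."""
        failed = {f.individual_id for f in self.failures}
        names = set(self.cohort.locus_names)
        return [
            ind.individual_id
            for ind in self.cohort.individuals
            if ind.individual_id not in failed
            and names <= set(self.genotypes.get(ind.individual_id, {}))
        ]

    def report_frame(self) -> pd.DataFrame:
        """One row per allele occurrence: individual, locus, side, match, catalog hit."""
        rows = [
            {
                "individual_id": ind,
                "locus": locus,
                "side": a.side.value,
                "match": a.match.value,
                "matched_catalog_allele": a.matched_catalog_allele or "",
                "novel": a.match is not Match.PERFECT,
            }
            for ind, locus, a in self.assignments
        ]
        return pd.DataFrame(
            rows,
            columns=["individual_id", "locus", "side", "match",
                     "matched_catalog_allele", "novel"],
        )

    def write_report(self, path) -> None:
        self.report_frame().to_csv(path, sep="\t", index=False)


def diagnostic_sites(
    locus: str, maternal_catalog: Catalog, paternal_catalog: Catalog
) -> dict[str, tuple[frozenset, frozenset]]:
    """Sites whose observed state sets are disjoint between parental catalogs.

    Returns ``{site: (maternal states, paternal states)}``.
    """
    if locus not in maternal_catalog or not maternal_catalog[locus]:
        raise SatcloneError(f"locus {locus} absent from maternal catalog")
    if locus not in paternal_catalog or not paternal_catalog[locus]:
        raise SatcloneError(f"locus {locus} absent from paternal catalog")
    mat, pat = maternal_catalog[locus], paternal_catalog[locus]
    sites = set(mat[0].snp_profile)
    out: dict[str, tuple[frozenset, frozenset]] = {}
    for site in sites:
        m_states = frozenset(a.snp_profile.get(site) for a in mat)
        p_states = frozenset(a.snp_profile.get(site) for a in pat)
        if None not in m_states and None not in p_states and not (m_states & p_states):
            out[site] = (m_states, p_states)
    return out


def _nearest(allele: AlleleRecord, candidates: Sequence[AlleleRecord]):
    """Nearest catalog allele by (SNP hamming, tract L1); returns (allele, snp_d, tract_d)."""
    best = None
    for cand in candidates:
        snp_d = sum(
            1
            for site in set(allele.snp_profile) | set(cand.snp_profile)
            if allele.snp_profile.get(site) != cand.snp_profile.get(site)
        )
        tract_d = sum(
            abs(allele.tract_lengths.get(t, 0) - cand.tract_lengths.get(t, 0))
            for t in set(allele.tract_lengths) | set(cand.tract_lengths)
        )
        score = (snp_d + tract_d, snp_d)
        if best is None or score < best[0]:
            best = (score, cand, snp_d, tract_d)
    assert best is not None
    return best[1], best[2], best[3]


def assign_allele(
    allele: AlleleRecord,
    maternal_catalog: Catalog,
    paternal_catalog: Catalog,
    diag: Optional[Mapping[str, tuple[frozenset, frozenset]]] = None,
) -> AlleleAssignment:
    """Phase one allele to a parental side and grade the catalog match.

    The side call uses diagnostic sites only (majority vote; ties or no
    informative site → unassigned).  Match quality is graded against the
    nearest same-side catalog allele: ``perfect`` requires structural
    equality with some catalog allele on the called side.
    """
    if diag is None:
        diag = diagnostic_sites(allele.locus, maternal_catalog, paternal_catalog)
    votes = {Side.MATERNAL: 0, Side.PATERNAL: 0}
    for site, (m_states, p_states) in diag.items():
        state = allele.snp_profile.get(site)
        if state in m_states:
            votes[Side.MATERNAL] += 1
        elif state in p_states:
            votes[Side.PATERNAL] += 1
    if votes[Side.MATERNAL] > votes[Side.PATERNAL]:
        side = Side.MATERNAL
    elif votes[Side.PATERNAL] > votes[Side.MATERNAL]:
        side = Side.PATERNAL
    else:
        side = Side.UNASSIGNED

    if side is Side.UNASSIGNED:
        pool = list(maternal_catalog[allele.locus]) + list(paternal_catalog[allele.locus])
        _, _, tract_d = _nearest(allele, pool)
        match = Match.SNP_MISMATCH if tract_d == 0 else Match.BOTH_MISMATCH
        return AlleleAssignment(allele, side, match, None)

    catalog = maternal_catalog if side is Side.MATERNAL else paternal_catalog
    candidates = catalog[allele.locus]
    for cand in candidates:
        if cand == allele:
            return AlleleAssignment(allele, side, Match.PERFECT, cand.allele_id)
    nearest, snp_d, tract_d = _nearest(allele, candidates)
    if snp_d and tract_d:
        match = Match.BOTH_MISMATCH
    elif snp_d:
        match = Match.SNP_MISMATCH
    else:
        match = Match.REPEAT_MISMATCH
    return AlleleAssignment(allele, side, match, nearest.allele_id)


def phase_cohort(
    cohort: Cohort, maternal_catalog: Catalog, paternal_catalog: Catalog
) -> PhasedCohort:
    """Phase every genotype of a cohort.

    Genotypes where both alleles call the same side, or where either allele
    is unassignable, are recorded as :class:`PhaseFailure` — data to
    report, not exceptions — and their individuals are excluded from clone
    calling (but not from allele counts).
    """
    diag = {
        locus: diagnostic_sites(locus, maternal_catalog, paternal_catalog)
        for locus in cohort.locus_names
    }
    phased: dict[str, dict[str, PhasedGenotype]] = {}
    failures: list[PhaseFailure] = []
    assignments: list[tuple[str, str, AlleleAssignment]] = []
    for ind in cohort.individuals:
        for locus, g in sorted(ind.genotypes.items()):
            # order-independence: assess the two alleles in canonical order
            a1, a2 = sorted(g.alleles, key=lambda a: a.key())
            asn1 = assign_allele(a1, maternal_catalog, paternal_catalog, diag[locus])
            asn2 = assign_allele(a2, maternal_catalog, paternal_catalog, diag[locus])
            assignments.append((ind.individual_id, locus, asn1))
            assignments.append((ind.individual_id, locus, asn2))
            sides = {asn1.side, asn2.side}
            if sides == {Side.MATERNAL, Side.PATERNAL}:
                mat = a1 if asn1.side is Side.MATERNAL else a2
                pat = a2 if asn1.side is Side.MATERNAL else a1
                phased.setdefault(ind.individual_id, {})[locus] = PhasedGenotype(
                    ind.individual_id, locus, mat, pat
                )
            else:
                reason = (
                    "allele(s) unassignable from diagnostic sites"
                    if Side.UNASSIGNED in sides
                    else f"both alleles phase {asn1.side.value}"
                )
                failures.append(
                    PhaseFailure(ind.individual_id, locus, (asn1.side, asn2.side), reason)
                )
    return PhasedCohort(cohort, phased, failures, assignments, diag)


@dataclass
class OriginClassification:
    """Partition of individuals by their parent-specific SNP combination."""

    classes: dict[tuple, list[str]] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def single_origin_consistent(self) -> bool:
        return len(self.classes) == 1


def single_origin_test(phased: PhasedCohort) -> OriginClassification:
    """Group individuals by diagnostic-SNP combinations over loci and sides.

    One class is consistent with a single founding hybridization; ``k``
    classes require at least ``k`` independent origins (mutations are
    assumed not to touch the diagnostic flanking sites).
    """
    loci = phased.cohort.locus_names
    classes: dict[tuple, list[str]] = {}
    for ind_id in phased.phased_individuals():
        key_parts = []
        for locus in loci:
            pg = phased.genotypes[ind_id][locus]
            sites = sorted(phased.diagnostic_sites[locus])
            key_parts.append(
                (
                    locus,
                    tuple(pg.maternal_allele.snp_profile.get(s) for s in sites),
                    tuple(pg.paternal_allele.snp_profile.get(s) for s in sites),
                )
            )
        classes.setdefault(tuple(key_parts), []).append(ind_id)
    return OriginClassification(classes)


def collapse_mt_haplotypes(
    sequences: Union[Mapping[str, str], Sequence]
) -> dict[str, list[str]]:
    """Group aligned mitochondrial fragments by exact sequence identity.

    Accepts ``{id: sequence}`` or Biopython ``SeqRecord`` iterables.
    Comparison is case-insensitive; IUPAC ambiguity codes are compared
    literally.  Haplotypes are named H1, H2, … in order of first
    appearance.  Raises ``ValueError`` on unequal lengths.
    """
    if not isinstance(sequences, Mapping):
        sequences = {rec.id: str(rec.seq) for rec in sequences}
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences not aligned: lengths {sorted(lengths)}")
    groups: dict[str, list[str]] = {}
    for name, seq in sequences.items():
        groups.setdefault(seq.upper(), []).append(name)
    return {f"H{i}": members for i, members in enumerate(groups.values(), start=1)}
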