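"""Allele counts, rarefied allelic richness, heterozygosity, group comparison.

Allelic richness is standardized by hypergeometric rarefaction: for a
sample of ``2N`` gene copies with allele counts ``N_i``, the expected
number of distinct alleles in a random subsample of ``g`` copies is

    R_S(g) = Σ_i [ 1 − C(2N − N_i, g) / C(2N, g) ]

with ``C(a, b) = 0`` when ``a < b``.  Computed in exact rational
arithmetic.  Gene diversity uses Nei's unbiased estimator
``He = (2n / (2n − 1)) · (1 − Σ p_i²)`` over ``n`` diploid individuals.
Group differences in richness are assessed with a seeded label-permutation
test (the data are too few and too structured for parametric assumptions).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import AlleleRecord, Cohort, SatcloneError
from .phasing import PhasedCohort


@dataclass
class AlleleCounts:
    """Occurrences of each distinct allele at one locus (one or all populations)."""

    locus: str
    population: Optional[str]  # None = pooled over populations
    counts: dict[tuple, int]  # allele key -> occurrences
    alleles: dict[tuple, AlleleRecord]  # representative record per key

    @property
    def n_alleles(self) -> int:
        return len(self.counts)

    @property
    def n_gene_copies(self) -> int:
        return sum(self.counts.values())

    def count_vector(self) -> list[int]:
        return sorted(self.counts.values(), reverse=True)


@dataclass
class RichnessResult:
    locus: str
    population: Optional[str]
    n_alleles: int
    g: int
    exact: Fraction

    @property
    def R_S(self) -> float:
        return float(self.exact)


@dataclass
class DiversityIndices:
    locus: str
    population: Optional[str]
    n_individuals: int
    Ho: float
    He: float  # Nei unbiased
    gene_diversity: float  # plain 1 - sum p^2
    allele_frequencies: dict[tuple, Fraction]


def _as_cohort(data: Union[Cohort, PhasedCohort]) -> Cohort:
    # phase failures stay in allele counts: count from the raw cohort
    return data.cohort if isinstance(data, PhasedCohort) else data


def allele_counts(
    data: Union[Cohort, PhasedCohort], locus: str, population: Optional[str] = None
) -> AlleleCounts:
    """Count allele occurrences (both genotype slots) structurally."""
    cohort = _as_cohort(data)
    cohort.locus(locus)  # raises KeyError for unknown locus
    individuals = cohort.by_population(population) if population else cohort.individuals
    counts: dict[tuple, int] = {}
    reps: dict[tuple, AlleleRecord] = {}
    for ind in individuals:
        g = ind.genotypes.get(locus)
        if g is None:
            continue
        for a in g.alleles:
            k = a.key()
            counts[k] = counts.get(k, 0) + 1
            reps.setdefault(k, a)
    return AlleleCounts(locus, population, counts, reps)


def rarefied_richness(
    counts: Union[AlleleCounts, Sequence[int]], g: int
) -> RichnessResult:
    """Expected number of distinct alleles in a ``g``-gene-copy subsample.

    Accepts an :class:`AlleleCounts` or a bare count vector.  Exact
    rational arithmetic; ``R_S(2N) = N`` and ``R_S(1) = 1`` hold
    identically.
    """
    if isinstance(counts, AlleleCounts):
        vec = list(counts.counts.values())
        locus, pop = counts.locus, counts.population
    else:
        vec = list(counts)
        locus, pop = "", None
    total = sum(vec)
    if not 1 <= g <= total:
        raise SatcloneError(f"rarefaction size g={g} outside [1, {total}]")
    denom = math.comb(total, g)
    r = sum(Fraction(denom - math.comb(total - n_i, g), denom) for n_i in vec)
    return RichnessResult(locus, pop, len(vec), g, r)


def heterozygosity(
    data: Union[Cohort, PhasedCohort], locus: str, population: Optional[str] = None
) -> DiversityIndices:
    """Observed heterozygosity and Nei's unbiased expected heterozygosity."""
    cohort = _as_cohort(data)
    individuals = [
        ind
        for ind in (cohort.by_population(population) if population else cohort.individuals)
        if locus in ind.genotypes
    ]
    n = len(individuals)
    if n < 2:
        raise SatcloneError(f"need ≥2 individuals for He at {locus}, got {n}")
    het = sum(
        1 for ind in individuals
        if ind.genotypes[locus].alleles[0] != ind.genotypes[locus].alleles[1]
    )
    ho = Fraction(het, n)
    ac = allele_counts(cohort, locus, population)
    total = ac.n_gene_copies
    freqs = {k: Fraction(v, total) for k, v in ac.counts.items()}
    plain = 1 - sum(p * p for p in freqs.values())
    he = Fraction(2 * n, 2 * n - 1) * plain
    return DiversityIndices(locus, population, n, float(ho), float(he), float(plain), freqs)


def summarize_across_populations(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and standard error (sample SD / √k) over populations."""
    if len(values) < 2:
        raise SatcloneError("need values from at least two populations")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(len(arr)))


@dataclass
class PermutationResult:
    observed_difference: float  # mean(A) - mean(B)
    p_value: float
    n_permutations: int


def compare_richness(
    group_a: Sequence[float],
    group_b: Sequence[float],
    n_permutations: int = 9999,
    seed: int = 0,
) -> PermutationResult:
    """Two-sided label-permutation test for a difference in mean richness.

    ``p = (1 + #{permuted |Δ| ≥ observed |Δ|}) / (B + 1)``.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise SatcloneError("both groups must be non-empty")
    if n_permutations < 999:
        raise SatcloneError("use at least 999 permutations")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    observed = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    hits = 0
    total = pooled.sum()
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        diff = perm[:na].mean() - (total - perm[:na].sum()) / len(b)
        if abs(diff) >= abs(observed) - 1e-12:
            hits += 1
    return PermutationResult(float(observed), (1 + hits) / (n_permutations + 1), n_permutations)


def exhaustive_mean_difference_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Exact two-sided permutation p-value by enumerating all label splits."""
    a = [float(x) for x in group_a]
    b = [float(x) for x in group_b]
    pooled = a + b
    na, nb = len(a), len(b)
    observed = abs(sum(a) / na - sum(b) / nb)
    hits = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        sel = set(idx)
        sa = sum(pooled[i] for i in sel)
        sb = sum(pooled[i] for i in range(len(pooled)) if i not in sel)
        if abs(sa / na - sb / nb) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def stats_table(
    data: Union[Cohort, PhasedCohort],
    g: Optional[int] = None,
    include_heterozygosity: bool = True,
) -> pd.DataFrame:
    """Per-locus × per-population diversity table with mean ± SE rows.

    Columns: locus, population, N (distinct alleles), R_S (rarefied at
    ``g``; default = the smallest 2N among the locus's population samples),
    and optionally Ho / He.  A ``total`` row pools populations; a
    ``mean±SE`` row summarizes across populations.
    """
    cohort = _as_cohort(data)
    rows = []
    for locus in cohort.locus_names:
        per_pop = {pop: allele_counts(cohort, locus, pop) for pop in cohort.populations}
        g_locus = g if g is not None else min(ac.n_gene_copies for ac in per_pop.values())
        ns, rs = [], []
        for pop, ac in per_pop.items():
            r = rarefied_richness(ac, min(g_locus, ac.n_gene_copies))
            row = {"locus": locus, "population": pop, "N": ac.n_alleles,
                   "R_S": round(r.R_S, 2)}
            if include_heterozygosity and len(cohort.by_population(pop)) >= 2:
                d = heterozygosity(cohort, locus, pop)
                row["Ho"] = round(d.Ho, 2)
                row["He"] = round(d.He, 2)
            ns.append(ac.n_alleles)
            rs.append(r.R_S)
            rows.append(row)
        pooled = allele_counts(cohort, locus)
        pooled_r = rarefied_richness(pooled, min(g_locus, pooled.n_gene_copies))
        rows.append({"locus": locus, "population": "total",
                     "N": pooled.n_alleles, "R_S": round(pooled_r.R_S, 2)})
        if len(ns) >= 2:
            n_mean, n_se = summarize_across_populations(ns)
            r_mean, r_se = summarize_across_populations(rs)
            rows.append({
                "locus": locus, "population": "mean±SE",
                "N": f"{round(n_mean, 2)} ± {round(n_se, 2)}",
                "R_S": f"{round(r_mean, 2)} ± {round(r_se, 2)}",
            })
    return pd.DataFrame(rows)
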