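"""Forward simulator for clonal cohorts of hybrid-origin parthenogens.

The generative model mirrors the biology the analysis assumes:

1. **Parental pools.**  Two bisexual species each carry a per-locus allele
   catalog.  Repeat-tract lengths are i.i.d. uniform integers on a
   configurable range; diagnostic flanking sites take states from disjoint
   per-species alphabets (maternal ``{A, C}``, paternal ``{G, T}``), so
   every allele is assignable to a parental side by construction.
   Panels are diploid Hardy–Weinberg draws from the catalogs, seeded with
   one copy of each catalog allele so the panels always span them.
2. **Hybrid founders.**  Each of ``n_origins`` founding hybridization
   events pairs one maternal-catalog and one paternal-catalog allele per
   locus.
3. **Clonal propagation.**  Apomictic Wright–Fisher reproduction within
   demes: each daughter is her mother's clone.  A locus mutates with
   probability ``mu`` per generation under a symmetric single-step model
   (one uniformly chosen variable tract on one side changes by ±1 repeat,
   reflecting at length 1).  Mutations never touch flanking SNP sites —
   diagnostic combinations are stable origin markers.  Migration follows
   an island model: marked individuals are shuffled uniformly across
   demes, conserving deme sizes.

Ground truth (founder genotypes, per-individual origin and mutation
history, true clone count) is returned for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .core import AlleleRecord, Cohort, Individual, LocusDef, SatcloneError, Species, UnphasedGenotype

MATERNAL_STATES = ("A", "C")
PATERNAL_STATES = ("G", "T")

# one phased multilocus genotype = tuple over loci of (maternal, paternal) AlleleRecord
PhasedGenome = tuple[tuple[AlleleRecord, AlleleRecord], ...]


def _per_locus(value: Union[int, Sequence[int]], n: int, name: str) -> list[int]:
    if isinstance(value, int):
        return [value] * n
    vals = list(value)
    if len(vals) != n:
        raise SatcloneError(f"{name}: expected {n} values, got {len(vals)}")
    return vals


@dataclass
class SimConfig:
    """Study-design parameters of the forward simulation.

    Defaults emulate the reference study's structure: four tetranucleotide
    loci with one variable tract and one diagnostic flanking SNP each, a
    single founding hybridization, and a handful of small, weakly connected
    demes sampled at realistic field sizes.
    """

    n_loci: int = 4
    tracts_per_locus: int = 1
    n_diagnostic_snps_per_locus: int = 1
    maternal_allele_counts: Union[int, Sequence[int]] = 3
    paternal_allele_counts: Union[int, Sequence[int]] = 3
    n_origins: int = 1
    n_demes: int = 7
    deme_sizes: Union[int, Sequence[int]] = 100
    generations: int = 50
    mu: float = 0.001  # per-locus per-generation stepwise mutation probability
    migration_rate: float = 0.01
    sample_sizes: Union[int, Sequence[int]] = 15
    seed: int = 0
    origin_distinguishing: bool = False
    panel_size: int = 20
    tract_length_range: tuple[int, int] = (5, 15)

    def __post_init__(self) -> None:
        for name in ("n_loci", "tracts_per_locus", "n_diagnostic_snps_per_locus",
                     "n_origins", "n_demes", "generations", "panel_size"):
            if getattr(self, name) < (0 if name == "generations" else 1):
                raise SatcloneError(f"{name} must be ≥ 1")
        if not 0 <= self.mu <= 1:
            raise SatcloneError("mu must lie in [0, 1]")
        if not 0 <= self.migration_rate <= 1:
            raise SatcloneError("migration_rate must lie in [0, 1]")
        if self.tract_length_range[0] < 1 or self.tract_length_range[0] > self.tract_length_range[1]:
            raise SatcloneError("tract_length_range must be 1 ≤ lo ≤ hi")
        for d, s in zip(self.deme_size_list(), self.sample_size_list()):
            if s > d:
                raise SatcloneError(f"sample size {s} exceeds deme size {d}")

    def deme_size_list(self) -> list[int]:
        return _per_locus(self.deme_sizes, self.n_demes, "deme_sizes")

    def sample_size_list(self) -> list[int]:
        return _per_locus(self.sample_sizes, self.n_demes, "sample_sizes")

    def loci(self) -> list[LocusDef]:
        tracts = tuple(f"t{i + 1}" for i in range(self.tracts_per_locus))
        snps = tuple(f"d{i + 1}" for i in range(self.n_diagnostic_snps_per_locus))
        return [LocusDef(f"L{i + 1}", "GATA", tracts, snps) for i in range(self.n_loci)]

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for f_ in self.__dataclass_fields__:
                v = getattr(self, f_)
                if isinstance(v, (list, tuple)):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f_}={v}\n")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        kwargs = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, _, v = line.partition("=")
                kwargs[k.strip()] = v.strip()
        return cls(**_coerce_config(kwargs))


def _coerce_config(kwargs: dict) -> dict:
    out = {}
    for k, v in kwargs.items():
        if k not in SimConfig.__dataclass_fields__:
            raise SatcloneError(f"unknown simulation parameter {k!r}")
        if k in ("mu", "migration_rate"):
            out[k] = float(v)
        elif k == "origin_distinguishing":
            out[k] = v.lower() in ("1", "true", "yes")
        elif k == "tract_length_range":
            lo, hi = v.split(",")
            out[k] = (int(lo), int(hi))
        elif "," in str(v):
            out[k] = [int(x) for x in str(v).split(",")]
        else:
            out[k] = int(v)
    return out


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    founder_genotypes: list[PhasedGenome]
    lineage: dict[str, tuple[int, tuple]]  # individual -> (origin, mutation events)
    true_clone_count: int

    def write(self, directory, prefix: str = "truth") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / f"{prefix}_lineage.tsv", "w", encoding="utf-8") as fh:
            fh.write("individual_id\torigin\tn_mutations\tevents\n")
            for ind, (origin, events) in self.lineage.items():
                ev = ";".join(
                    f"g{gen}:{locus}:{side}:{tract}:{delta:+d}"
                    for gen, locus, side, tract, delta in events
                )
                fh.write(f"{ind}\t{origin}\t{len(events)}\t{ev}\n")
        with open(directory / f"{prefix}_summary.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_origins": len(self.founder_genotypes),
                    "true_clone_count": self.true_clone_count,
                    "n_sampled": len(self.lineage),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


def _diag_profile(states: tuple[str, str], index: int, n_sites: int) -> list[str]:
    # allele `index` gets the binary expansion of its index over the site
    # alphabet, so low-index alleles have pairwise distinct combinations
    return [states[(index >> k) & 1] for k in range(n_sites)]


def _make_catalog(
    config: SimConfig, species: Species, counts: list[int], rng: np.random.Generator
) -> dict[str, list[AlleleRecord]]:
    states = MATERNAL_STATES if species is Species.MATERNAL else PATERNAL_STATES
    prefix = "M" if species is Species.MATERNAL else "P"
    lo, hi = config.tract_length_range
    catalog: dict[str, list[AlleleRecord]] = {}
    for locus, k in zip(config.loci(), counts):
        alleles = []
        for j in range(k):
            tracts = {
                t: int(rng.integers(lo, hi + 1)) for t in locus.variable_tracts
            }
            profile = dict(zip(locus.snp_positions,
                               _diag_profile(states, j, len(locus.snp_positions))))
            alleles.append(
                AlleleRecord(locus.name, tracts, profile,
                             allele_id=f"{prefix}{j + 1}", source_species=species)
            )
        catalog[locus.name] = alleles
    return catalog


def _panel_cohort(
    config: SimConfig, species: Species, catalog: dict[str, list[AlleleRecord]],
    rng: np.random.Generator,
) -> Cohort:
    pop = "maternal_panel" if species is Species.MATERNAL else "paternal_panel"
    individuals = []
    for i in range(config.panel_size):
        ind_id = f"{pop}-{i + 1:03d}"
        genotypes = {}
        for locus in config.loci():
            alleles = catalog[locus.name]
            k = len(alleles)
            # coverage block: the first ceil(k/2) individuals carry each
            # catalog allele once; the rest are Hardy–Weinberg draws
            if 2 * i + 1 < k:
                pair = (alleles[2 * i], alleles[2 * i + 1])
            elif 2 * i < k:
                pair = (alleles[2 * i], alleles[int(rng.integers(k))])
            else:
                pair = (alleles[int(rng.integers(k))], alleles[int(rng.integers(k))])
            genotypes[locus.name] = UnphasedGenotype(ind_id, locus.name, pair)
        individuals.append(Individual(ind_id, pop, species, genotypes))
    return Cohort(species, individuals, config.loci())


def simulate_parental_pools(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[Cohort, Cohort]:
    """Generate the two parental panels (maternal, paternal).

    Catalog tract lengths are uniform on ``tract_length_range``; diagnostic
    site states come from disjoint per-species alphabets, so every maternal
    allele differs from every paternal allele at each diagnostic site.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mat_counts = _per_locus(config.maternal_allele_counts, config.n_loci,
                            "maternal_allele_counts")
    pat_counts = _per_locus(config.paternal_allele_counts, config.n_loci,
                            "paternal_allele_counts")
    largest = max(mat_counts + pat_counts)
    if 2 * config.panel_size < largest:
        raise SatcloneError(
            f"panel_size {config.panel_size} too small to span a catalog of "
            f"{largest} alleles (needs ≥ {(largest + 1) // 2})"
        )
    mat_catalog = _make_catalog(config, Species.MATERNAL, mat_counts, rng)
    pat_catalog = _make_catalog(config, Species.PATERNAL, pat_counts, rng)
    return (
        _panel_cohort(config, Species.MATERNAL, mat_catalog, rng),
        _panel_cohort(config, Species.PATERNAL, pat_catalog, rng),
    )


def simulate_hybrid_origins(
    maternal_panel: Cohort,
    paternal_panel: Cohort,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[PhasedGenome]:
    """Draw ``n_origins`` founding hybrid genotypes from the parental panels.

    Each founder pairs, per locus, one allele observed in the maternal
    panel with one observed in the paternal panel.  With
    ``origin_distinguishing`` founder *i* takes maternal allele *i* at
    every locus, guaranteeing pairwise distinct diagnostic combinations.
    """
    from .core import catalog_from_cohort

    if rng is None:
        rng = np.random.default_rng(config.seed)
    mat_catalog = catalog_from_cohort(maternal_panel)
    pat_catalog = catalog_from_cohort(paternal_panel)
    loci = config.loci()
    founders: list[PhasedGenome] = []
    for origin in range(config.n_origins):
        genome = []
        for locus in loci:
            mats = mat_catalog[locus.name]
            pats = pat_catalog[locus.name]
            if not mats or not pats:
                raise SatcloneError(f"empty parental catalog at {locus.name}")
            if config.origin_distinguishing:
                if len(mats) < config.n_origins:
                    raise SatcloneError(
                        f"{locus.name}: origin-distinguishing founders need "
                        f"≥{config.n_origins} maternal alleles, have {len(mats)}"
                    )
                mat = mats[origin]
            else:
                mat = mats[int(rng.integers(len(mats)))]
            pat = pats[int(rng.integers(len(pats)))]
            genome.append((mat, pat))
        founders.append(tuple(genome))
    return founders


def _mutate(
    genome: PhasedGenome, locus_idx: int, loci: list[LocusDef], rng: np.random.Generator
) -> tuple[PhasedGenome, tuple]:
    """Apply one stepwise mutation at one locus; returns new genome + event."""
    locus = loci[locus_idx]
    side = int(rng.integers(2))
    tract = locus.variable_tracts[int(rng.integers(len(locus.variable_tracts)))]
    delta = 1 if rng.integers(2) else -1
    allele = genome[locus_idx][side]
    length = allele.tract_lengths[tract]
    if length + delta < 1:  # reflect at one repeat unit
        delta = 1
    new_tracts = dict(allele.tract_lengths)
    new_tracts[tract] = length + delta
    mutant = AlleleRecord(
        allele.locus, new_tracts, allele.snp_profile,
        allele_id=None, source_species=allele.source_species,
    )
    pair = (mutant, genome[locus_idx][1]) if side == 0 else (genome[locus_idx][0], mutant)
    new_genome = genome[:locus_idx] + (pair,) + genome[locus_idx + 1:]
    event = (locus_idx, "maternal" if side == 0 else "paternal", tract, delta)
    return new_genome, event


def simulate_clonal_evolution(
    founders: list[PhasedGenome],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[Cohort, SimTruth]:
    """Apomictic Wright–Fisher propagation with stepwise mutation and migration.

    Founders seed demes round-robin (origin *o* seeds deme ``o mod
    n_demes``; a deme with no origin reuses origin ``d mod n_origins``), so
    with ``n_demes == n_origins`` each deme starts as a pure founder
    lineage.  Returns the sampled cohort and its ground truth.
    """
    if not founders:
        raise SatcloneError("no founders")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loci = config.loci()
    locus_names = [l.name for l in loci]
    deme_sizes = config.deme_size_list()
    sample_sizes = config.sample_size_list()
    n_origins = len(founders)

    # state: per deme, list of (genome, origin, events tuple)
    demes: list[list[tuple[PhasedGenome, int, tuple]]] = []
    for d in range(config.n_demes):
        origins_here = [o for o in range(n_origins) if o % config.n_demes == d]
        if not origins_here:
            origins_here = [d % n_origins]
        demes.append(
            [
                (founders[origins_here[j % len(origins_here)]],
                 origins_here[j % len(origins_here)], ())
                for j in range(deme_sizes[d])
            ]
        )

    for gen in range(1, config.generations + 1):
        next_demes = []
        for d, pool in enumerate(demes):
            mothers = rng.integers(len(pool), size=deme_sizes[d])
            mutate_mask = rng.random((deme_sizes[d], config.n_loci)) < config.mu
            offspring = []
            for j, m in enumerate(mothers):
                genome, origin, events = pool[m]
                for locus_idx in np.nonzero(mutate_mask[j])[0]:
                    genome, ev = _mutate(genome, int(locus_idx), loci, rng)
                    events = events + ((gen, locus_names[ev[0]], ev[1], ev[2], ev[3]),)
                offspring.append((genome, origin, events))
            next_demes.append(offspring)
        demes = next_demes

        if config.migration_rate > 0 and config.n_demes > 1:
            slots = [(d, j) for d in range(config.n_demes) for j in range(deme_sizes[d])]
            marked = [s for s in slots if rng.random() < config.migration_rate]
            if len(marked) > 1:
                movers = [demes[d][j] for d, j in marked]
                order = rng.permutation(len(marked))
                for (d, j), k in zip(marked, order):
                    demes[d][j] = movers[int(k)]

    individuals: list[Individual] = []
    lineage: dict[str, tuple[int, tuple]] = {}
    genomes_sampled: set = set()
    for d, pool in enumerate(demes):
        chosen = rng.choice(len(pool), size=sample_sizes[d], replace=False)
        for rank, idx in enumerate(sorted(int(i) for i in chosen), start=1):
            genome, origin, events = pool[idx]
            ind_id = f"deme{d + 1}-{rank:03d}"
            genotypes = {
                name: UnphasedGenotype(ind_id, name, pair)
                for name, pair in zip(locus_names, genome)
            }
            individuals.append(
                Individual(ind_id, f"deme{d + 1}", Species.PARTHENOGEN, genotypes)
            )
            lineage[ind_id] = (origin, events)
            genomes_sampled.add(
                tuple((a.key(), b.key()) for a, b in genome)
            )

    cohort = Cohort(Species.PARTHENOGEN, individuals, loci)
    truth = SimTruth(list(founders), lineage, len(genomes_sampled))
    return cohort, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[Cohort, Cohort, Cohort, SimTruth]:
    """End-to-end simulation: (maternal panel, paternal panel, cohort, truth).

    All randomness flows from ``config.seed`` through independent
    sub-streams, so identical configs give bit-identical outputs.
    """
    seq = np.random.SeedSequence(config.seed)
    rng_pools, rng_origins, rng_evo = (np.random.default_rng(s) for s in seq.spawn(3))
    maternal, paternal = simulate_parental_pools(config, rng_pools)
    founders = simulate_hybrid_origins(maternal, paternal, config, rng_origins)
    cohort, truth = simulate_clonal_evolution(founders, config, rng_evo)
    return maternal, paternal, cohort, truth
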