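"""Shared fixtures: the bundled reference dataset, its catalogs, and oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import satclone as sc


@pytest.fixture(scope="session")
def dataset():
    return sc.load_unisexualis_dataset()


@pytest.fixture(scope="session")
def catalogs(dataset):
    return (
        sc.catalog_from_cohort(dataset.maternal_panel),
        sc.catalog_from_cohort(dataset.paternal_panel),
    )


@pytest.fixture(scope="session")
def phased(dataset, catalogs):
    return sc.phase_cohort(dataset.parthenogen, *catalogs)


@pytest.fixture(scope="session")
def clone_table(phased, dataset):
    return sc.map_to_reference_names(sc.call_clones(phased), dataset.clone_names)


@pytest.fixture(scope="session")
def character_matrix(clone_table):
    return sc.encode_matrix(clone_table)


# ---------------------------------------------------------------- oracles


def brute_force_partition(phased: sc.PhasedCohort) -> list[frozenset]:
    """O(n²) all-pairs clone partition, independent of call_clones."""
    loci = phased.cohort.locus_names
    ids = phased.phased_individuals()

    def same_clone(a: str, b: str) -> bool:
        for locus in loci:
            ga, gb = phased.genotypes[a][locus], phased.genotypes[b][locus]
            if ga.maternal_allele != gb.maternal_allele:
                return False
            if ga.paternal_allele != gb.paternal_allele:
                return False
        return True

    groups: list[list[str]] = []
    for ind in ids:
        for g in groups:
            if same_clone(ind, g[0]):
                g.append(ind)
                break
        else:
            groups.append([ind])
    return [frozenset(g) for g in groups]


def exhaustive_msn_edges(names, dist) -> set[tuple[str, str]]:
    """Union of all minimum spanning trees, by enumerating spanning trees.

    ``dist`` maps unordered name pairs to non-negative integers.  Usable up
    to ~7 nodes.
    """
    n = len(names)
    all_edges = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]

    def spans(edge_set) -> bool:
        parent = {x: x for x in names}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        merged = 0
        for a, b in edge_set:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                merged += 1
        return merged == n - 1

    best_weight = None
    best_trees: list[tuple] = []
    for tree in itertools.combinations(all_edges, n - 1):
        if not spans(tree):
            continue
        w = sum(dist[frozenset(e)] for e in tree)
        if best_weight is None or w < best_weight:
            best_weight, best_trees = w, [tree]
        elif w == best_weight:
            best_trees.append(tree)
    return {tuple(sorted(e)) for tree in best_trees for e in tree}


def monte_carlo_rarefaction(counts, g, reps, rng) -> tuple[float, float]:
    """(mean, SE) of distinct alleles over random g-copy subsamples."""
    pool = np.repeat(np.arange(len(counts)), counts)
    total = len(pool)
    if g >= total:
        return float(len(counts)), 0.0
    keys = rng.random((reps, total)).argpartition(g, axis=1)[:, :g]
    distinct = np.array([len(np.unique(pool[row])) for row in keys])
    return float(distinct.mean()), float(distinct.std(ddof=1) / np.sqrt(reps))
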