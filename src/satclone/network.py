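"""Mutational-step network over clones (statistical-parsimony style).

Clones are coded into a character matrix: one length column per
(locus, side, variable tract) and one state column per flanking site, with
the gap treated as an ordinary fifth state.  Distances between clones
count microsatellite repeat differences — ``unit`` mode sums absolute
repeat-count differences, ``event`` mode counts the number of tracts that
changed (one contiguous length change = one mutational event).  Flanking
indel/SNP site differences are excluded from the distance by default (the
repeat tracts carry the mutational signal; the flanking sites are linked
to them) but can be included.

The network is a tie-retaining minimum spanning network: processing clone
pairs in non-decreasing distance, every edge joining two different
components at the current distance level is added before components merge,
so alternative equally short connections are kept.  An optional connection
limit truncates edges beyond a step threshold, leaving separate
subnetworks.  The network is undirected and unrooted: it has no
evolutionary direction, so the "ancestral" clone can only be ranked by
spread and abundance, never proven.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from .clones import CloneTable
from .core import SatcloneError

DISTANCE_MODES = ("unit", "event")


@dataclass
class CharacterMatrix:
    """Clones × characters: repeat-tract lengths and flanking-site states."""

    clone_names: list[str]
    tract_columns: list[tuple[str, str, str]]  # (locus, side, tract)
    tract_values: list[list[int]]  # per clone, aligned with tract_columns
    site_columns: list[tuple[str, str, str]]  # (locus, side, site)
    site_values: list[list[str]]  # per clone, aligned with site_columns

    def row(self, name: str) -> tuple[list[int], list[str]]:
        i = self.clone_names.index(name)
        return self.tract_values[i], self.site_values[i]

    def to_frame(self):
        import pandas as pd

        cols = {}
        for j, col in enumerate(self.tract_columns):
            cols["/".join(col)] = [r[j] for r in self.tract_values]
        for j, col in enumerate(self.site_columns):
            cols["/".join(col)] = [r[j] for r in self.site_values]
        return pd.DataFrame(cols, index=self.clone_names)


def encode_matrix(clone_table: CloneTable, drop_constant: bool = True) -> CharacterMatrix:
    """Code a clone table into a character matrix.

    With ``drop_constant`` (default) columns invariant across clones are
    removed; distances are unaffected either way.
    """
    names = [c.name for c in clone_table.clones]
    loci = clone_table.locus_order
    for c in clone_table.clones:
        if set(c.genotypes) != set(loci):
            raise SatcloneError(f"clone {c.name} lacks loci {set(loci) - set(c.genotypes)}")

    tract_columns: list[tuple[str, str, str]] = []
    site_columns: list[tuple[str, str, str]] = []
    first = clone_table.clones[0].genotypes
    for locus in loci:
        for side, allele in zip(("maternal", "paternal"), first[locus]):
            for tract in sorted(allele.tract_lengths):
                tract_columns.append((locus, side, tract))
            for site in sorted(allele.snp_profile):
                site_columns.append((locus, side, site))

    tract_values, site_values = [], []
    for c in clone_table.clones:
        trow, srow = [], []
        for locus, side, tract in tract_columns:
            allele = c.genotypes[locus][0 if side == "maternal" else 1]
            trow.append(allele.tract_lengths[tract])
        for locus, side, site in site_columns:
            allele = c.genotypes[locus][0 if side == "maternal" else 1]
            srow.append(allele.snp_profile[site])
        tract_values.append(trow)
        site_values.append(srow)

    if drop_constant and len(names) > 1:
        keep_t = [j for j in range(len(tract_columns))
                  if len({r[j] for r in tract_values}) > 1]
        keep_s = [j for j in range(len(site_columns))
                  if len({r[j] for r in site_values}) > 1]
        tract_columns = [tract_columns[j] for j in keep_t]
        site_columns = [site_columns[j] for j in keep_s]
        tract_values = [[r[j] for j in keep_t] for r in tract_values]
        site_values = [[r[j] for j in keep_s] for r in site_values]

    return CharacterMatrix(names, tract_columns, tract_values, site_columns, site_values)


def step_distance(
    matrix: CharacterMatrix,
    clone_a: str,
    clone_b: str,
    mode: str = "event",
    include_sites: bool = False,
) -> int:
    """Mutational steps between two clones.

    ``unit``: Σ |repeat-count differences|; ``event``: number of tracts
    with any length difference.  With ``include_sites``, each differing
    flanking-site state (gap included as a fifth state) adds one step.
    """
    if mode not in DISTANCE_MODES:
        raise SatcloneError(f"unknown distance mode {mode!r}; use one of {DISTANCE_MODES}")
    ta, sa = matrix.row(clone_a)
    tb, sb = matrix.row(clone_b)
    if mode == "unit":
        d = sum(abs(x - y) for x, y in zip(ta, tb))
    else:
        d = sum(1 for x, y in zip(ta, tb) if x != y)
    if include_sites:
        d += sum(1 for x, y in zip(sa, sb) if x != y)
    return d


@dataclass
class CloneNetwork:
    """Clones as nodes, mutational-step edges, tie-retaining minimum spanning."""

    graph: nx.Graph
    distance_mode: str
    connection_limit: Optional[int]
    include_sites: bool = False

    @property
    def n_subnetworks(self) -> int:
        return nx.number_connected_components(self.graph)

    @property
    def is_connected(self) -> bool:
        return self.graph.number_of_nodes() > 0 and nx.is_connected(self.graph)

    def subnetworks(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), d["steps"]) for u, v, d in self.graph.edges(data=True)
        )

    def write_edgelist(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("clone_a\tclone_b\tsteps\n")
            for u, v, s in self.edges():
                fh.write(f"{u}\t{v}\t{s}\n")

    def write_dot(self, path) -> None:
        """GraphViz export; node labels carry totals, edges their step counts."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("graph clones {\n  node [shape=circle];\n")
            for n, d in self.graph.nodes(data=True):
                pops = ", ".join(f"{p}:{c}" for p, c in sorted(d["populations"].items()))
                fh.write(f'  "{n}" [label="{n}\\nn={d["total"]}", tooltip="{pops}"];\n')
            for u, v, d in self.graph.edges(data=True):
                fh.write(f'  "{u}" -- "{v}" [label="{d["steps"]}"];\n')
            fh.write("}\n")

    def write_graphml(self, path) -> None:
        import json

        g = nx.Graph()
        for n, d in self.graph.nodes(data=True):
            g.add_node(n, total=d["total"], populations=json.dumps(d["populations"], sort_keys=True))
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, steps=d["steps"])
        nx.write_graphml(g, path)


def pairwise_distances(
    matrix: CharacterMatrix, mode: str = "event", include_sites: bool = False
) -> dict[tuple[str, str], int]:
    names = matrix.clone_names
    return {
        (names[i], names[j]): step_distance(matrix, names[i], names[j], mode, include_sites)
        for i in range(len(names))
        for j in range(i + 1, len(names))
    }


def build_network(
    matrix: CharacterMatrix,
    clone_table: CloneTable,
    mode: str = "event",
    connection_limit: Optional[int] = None,
    include_sites: bool = False,
) -> CloneNetwork:
    """Tie-retaining minimum spanning network over the clones.

    Pairs are considered in non-decreasing step distance; at each distance
    level every edge joining two *different* components (as of the start of
    the level) is added, then components merge.  Edges beyond
    ``connection_limit`` steps are never added, which may leave separate
    subnetworks.
    """
    g = nx.Graph()
    by_name = {c.name: c for c in clone_table.clones}
    for name in matrix.clone_names:
        c = by_name[name]
        g.add_node(name, total=c.total, populations=dict(c.population_counts))

    dists = pairwise_distances(matrix, mode, include_sites)
    if connection_limit is not None:
        dists = {pair: d for pair, d in dists.items() if d <= connection_limit}

    parent = {n: n for n in matrix.clone_names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for d in sorted(set(dists.values())):
        level = [pair for pair, dist in dists.items() if dist == d]
        to_add = [(u, v) for u, v in level if find(u) != find(v)]
        for u, v in to_add:
            g.add_edge(u, v, steps=d)
        for u, v in to_add:
            parent[find(u)] = find(v)
    return CloneNetwork(g, mode, connection_limit, include_sites)


@dataclass
class AncestralReport:
    """Ranking of clones as candidates for the ancestral genotype.

    The network is unrooted, so this is a plausibility ranking by
    geographic spread, abundance and connectivity — not an inference of
    direction.
    """

    ranking: list[tuple[str, int, int, int]]  # (name, n_populations, total, degree)
    top_candidates: list[str] = field(default_factory=list)
    rootable: bool = False

    @property
    def top(self) -> Optional[str]:
        return self.top_candidates[0] if len(self.top_candidates) == 1 else None


def ancestral_candidate(network: CloneNetwork, clone_table: CloneTable) -> AncestralReport:
    """Rank clones by (populations occupied, total count, node degree).

    Ties at the top are reported as multiple candidates; no arbitrary
    winner is chosen.
    """
    if network.graph.number_of_nodes() == 0:
        raise SatcloneError("empty network")
    rows = []
    for c in clone_table.clones:
        if c.name not in network.graph:
            continue
        n_pops = sum(1 for v in c.population_counts.values() if v > 0)
        rows.append((c.name, n_pops, c.total, network.graph.degree(c.name)))
    rows.sort(key=lambda r: (-r[1], -r[2], -r[3], r[0]))
    best = rows[0][1:]
    top = [r[0] for r in rows if r[1:] == best]
    return AncestralReport(rows, top, rootable=False)
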