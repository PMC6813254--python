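"""Gene-content taxonomy via a bipartite genome-PC network.

Genomes and protein clusters (PCs) form a bipartite graph with an edge
whenever a genome encodes at least one member of a PC.  Two-level
community detection on this graph yields a proposed family (level-1
group) and subfamily (level-2 subgroup) for every networked genome.
Tandem (multi-pI) genomes are excluded — shared cargo between adjacent
integrations would bridge unrelated groups — as are PCs with fewer than
two protein members.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

SUMMARY_PREVALENCE_MIN = 0.50
SUMMARY_PREVALENCE_MIN_LARGEST = 0.25


@dataclass(frozen=True)
class TaxonAssignment:
    genome_id: str
    group: str  # level 1, proposed family
    subgroup: str  # level 2, proposed subfamily


def build_bipartite(
    genome_pc_membership: Mapping[str, Sequence[str]],
    pc_sizes: Mapping[str, int],
    pi_counts: Mapping[str, int],
) -> nx.Graph:
    """Bipartite genome-PC network.

    ``genome_pc_membership`` maps genome -> PCs it encodes (repeats are
    collapsed to a single unweighted edge); genomes with >= 2 pI genes and
    PCs with < 2 protein members are omitted.
    """
    g = nx.Graph()
    for genome, pcs in sorted(genome_pc_membership.items()):
        if pi_counts.get(genome, 1) >= 2:
            continue
        for pc in pcs:
            if pc_sizes.get(pc, 0) < 2:
                continue
            g.add_node(genome, bipartite="genome")
            g.add_node(pc, bipartite="pc")
            g.add_edge(genome, pc)
    return g


def network_density(g: nx.Graph) -> float:
    """Edges as a fraction of possible genome-PC pairs."""
    genomes = [n for n, d in g.nodes(data=True) if d.get("bipartite") == "genome"]
    pcs = [n for n, d in g.nodes(data=True) if d.get("bipartite") == "pc"]
    if not genomes or not pcs:
        return 0.0
    return g.number_of_edges() / (len(genomes) * len(pcs))


def _infomap_partition(g: nx.Graph, seed: int) -> dict[str, int]:
    """Single-level InfoMap partition of a networkx graph."""
    import igraph as ig

    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    graph = ig.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in g.edges])
    ig.set_random_number_generator(random.Random(seed))
    membership = graph.community_infomap().membership
    return {n: membership[index[n]] for n in nodes}


def cluster_two_level(g: nx.Graph, seed: int = 42) -> list[TaxonAssignment]:
    """Two-level clustering of the bipartite network.

    Level 1 (groups / proposed families) is an InfoMap partition of the
    whole network; level 2 (subgroups / proposed subfamilies) re-partitions
    each group's induced subgraph.  Genomes in different connected
    components can never share a group.  Deterministic for a given seed.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    level1 = _infomap_partition(g, seed)
    # remap group ids deterministically by sorted member lists
    group_members: dict[int, list[str]] = {}
    for n, grp in level1.items():
        group_members.setdefault(grp, []).append(n)
    ordered = sorted(group_members.values(), key=lambda ms: (-len(ms), min(ms)))
    assignments: list[TaxonAssignment] = []
    for gi, members in enumerate(ordered):
        sub = g.subgraph(members)
        level2 = _infomap_partition(sub, seed + 1 + gi)
        sub_members: dict[int, list[str]] = {}
        for n, sgrp in level2.items():
            sub_members.setdefault(sgrp, []).append(n)
        sub_ordered = sorted(sub_members.values(), key=lambda ms: (-len(ms), min(ms)))
        for si, sm in enumerate(sub_ordered):
            for n in sm:
                if g.nodes[n].get("bipartite") == "genome":
                    assignments.append(
                        TaxonAssignment(
                            genome_id=n,
                            group=f"group_{gi:03d}",
                            subgroup=f"group_{gi:03d}.sub_{si:03d}",
                        )
                    )
    assignments.sort(key=lambda a: a.genome_id)
    return assignments


def summarize_network(
    g: nx.Graph,
    assignments: Sequence[TaxonAssignment],
    largest_subgroup_id: str | None = None,
) -> nx.Graph:
    """Summary graph connecting subgroup nodes to their characteristic PCs.

    A subgroup links to a PC when more than 50% of its genomes encode the
    PC; for the largest subgroup (most genomes; computed unless supplied)
    the cutoff relaxes to 25% so its conserved core remains visible despite
    its internal diversity.  Subgroup node size attribute is
    log10(member count).
    """
    by_sub: dict[str, list[str]] = {}
    for a in assignments:
        by_sub.setdefault(a.subgroup, []).append(a.genome_id)
    if largest_subgroup_id is None and by_sub:
        largest_subgroup_id = min(
            by_sub, key=lambda s: (-len(by_sub[s]), s)
        )
    pcs = [n for n, d in g.nodes(data=True) if d.get("bipartite") == "pc"]
    summary = nx.Graph()
    for sub, genomes in sorted(by_sub.items()):
        summary.add_node(sub, kind="subgroup", size=math.log10(len(genomes)) if genomes else 0.0,
                         n_genomes=len(genomes))
        cutoff = (
            SUMMARY_PREVALENCE_MIN_LARGEST
            if sub == largest_subgroup_id
            else SUMMARY_PREVALENCE_MIN
        )
        for pc in pcs:
            prevalence = sum(1 for gen in genomes if g.has_edge(gen, pc)) / len(genomes)
            if prevalence > cutoff:
                summary.add_node(pc, kind="pc")
                summary.add_edge(sub, pc, prevalence=prevalence)
    return summary


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(g.edges):
            fh.write(f"{u}\t{v}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def write_assignments(assignments: Sequence[TaxonAssignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgroup\tsubgroup\n")
        for a in assignments:
            fh.write(f"{a.genome_id}\t{a.group}\t{a.subgroup}\n")
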