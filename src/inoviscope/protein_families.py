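"""Protein clusters (PCs) and inovirus protein families (iPFs).

PCs are communities in the all-versus-all protein similarity graph
(blastp-style thresholds: E <= 0.001 and bit >= 50, relaxed to bit >= 30
when both proteins are <= 70 aa, which rescues the very short structural
genes).  iPFs merge PCs connected by profile-profile hits (>= 90%
probability and >= 50% coverage, or >= 99% probability, >= 20% coverage
and hit length >= 100); profile-profile comparison itself is consumed as
tabular input, not reimplemented.

The built-in pairwise aligner (Smith-Waterman, BLOSUM62, Karlin-Altschul
bit conversion) keeps the graph construction self-contained at test
scale; production runs parse external all-vs-all tabular output.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

EDGE_EVALUE_MAX = 0.001
EDGE_BIT_MIN = 50.0
EDGE_BIT_MIN_SHORT = 30.0
SHORT_PROTEIN_MAX = 70  # aa; both partners must be <= this for the relaxed rule

# Karlin-Altschul parameters for BLOSUM62 with gap open 11 / extend 1.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class SimilarityEdge:
    protein_a: str
    protein_b: str
    bit_score: float
    e_value: float
    both_short: bool = False

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValueError("self-edges are not allowed")


@dataclass
class ProteinCluster:
    pc_id: str
    members: list[str]


@dataclass
class IPF:
    ipf_id: str
    pc_ids: list[str]
    label: str | None = None
    ambiguous_label: bool = False


# ---------------------------------------------------------------------------
# Built-in aligner


def smith_waterman_bits(a: str, b: str) -> tuple[float, float]:
    """Local alignment bit score and E-value for one protein pair.

    Smith-Waterman with BLOSUM62 and affine gaps (11/1) via Biopython's
    PairwiseAligner; the raw score is converted to bits with standard
    Karlin-Altschul parameters and E = K*m*n*exp(-lambda*S).
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    raw = aligner.score(a, b)
    bits = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)
    evalue = _KA_K * len(a) * len(b) * math.exp(-_KA_LAMBDA * raw)
    return bits, evalue


def builtin_all_vs_all(proteins: Mapping[str, str]) -> list[tuple[str, str, float, float]]:
    """All unordered pairs scored with the built-in aligner."""
    out = []
    for a, b in itertools.combinations(sorted(proteins), 2):
        bits, ev = smith_waterman_bits(proteins[a], proteins[b])
        out.append((a, b, bits, ev))
    return out


def parse_blast_tab(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Parse 12-column outfmt-6-style all-vs-all output to raw hits."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            p = line.rstrip("\n").split("\t")
            hits.append((p[0], p[1], float(p[11]), float(p[10])))
    return hits


# ---------------------------------------------------------------------------
# Graph and PC construction


def build_similarity_graph(
    proteins: Mapping[str, str],
    hits: Iterable[tuple[str, str, float, float]] | None = None,
) -> list[SimilarityEdge]:
    """Thresholded, deduplicated similarity edges.

    ``hits`` are ``(a, b, bit_score, e_value)`` tuples (from any aligner);
    when omitted the built-in aligner scores all pairs.  An edge is kept
    iff E <= 0.001 and (bit >= 50, or bit >= 30 with both proteins
    <= 70 aa).  Self-hits are dropped; the best hit per unordered pair is
    retained.
    """
    if hits is None:
        hits = builtin_all_vs_all(proteins)
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, bits, ev in hits:
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        if key not in best or bits > best[key][0]:
            best[key] = (bits, ev)
    edges = []
    for (a, b), (bits, ev) in sorted(best.items()):
        if ev > EDGE_EVALUE_MAX:
            continue
        short = len(proteins[a]) <= SHORT_PROTEIN_MAX and len(proteins[b]) <= SHORT_PROTEIN_MAX
        if bits >= EDGE_BIT_MIN or (short and bits >= EDGE_BIT_MIN_SHORT):
            edges.append(SimilarityEdge(a, b, bits, ev, both_short=short))
    return edges


def cluster_pcs(
    edges: Sequence[SimilarityEdge],
    proteins: Iterable[str],
    seed: int = 42,
) -> tuple[list[ProteinCluster], list[str]]:
    """Community detection on the similarity graph (InfoMap).

    Communities of size >= 2 become PCs; isolated or size-1 communities are
    returned as singletons.  Deterministic for a given seed.
    """
    import igraph as ig
    import random

    all_proteins = sorted(set(proteins))
    index = {p: i for i, p in enumerate(all_proteins)}
    g = ig.Graph(
        n=len(all_proteins),
        edges=[(index[e.protein_a], index[e.protein_b]) for e in edges],
    )
    ig.set_random_number_generator(random.Random(seed))
    membership = g.community_infomap().membership
    groups: dict[int, list[str]] = {}
    for p, m in zip(all_proteins, membership):
        groups.setdefault(m, []).append(p)
    pcs, singletons = [], []
    for m in sorted(groups, key=lambda m: (-len(groups[m]), min(groups[m]))):
        members = sorted(groups[m])
        if len(members) >= 2:
            pcs.append(ProteinCluster(pc_id=f"PC_{len(pcs):05d}", members=members))
        else:
            singletons.extend(members)
    return pcs, sorted(singletons)


# ---------------------------------------------------------------------------
# iPF merge


PROFILE_PROB_MIN = 90.0
PROFILE_COV_MIN = 0.50
PROFILE_PROB_MIN_ALT = 99.0
PROFILE_COV_MIN_ALT = 0.20
PROFILE_LEN_MIN_ALT = 100


def profile_hit_qualifies(probability: float, coverage: float, hit_length: float) -> bool:
    """Profile-profile merge rule: >=90% prob & >=50% cov, or >=99% prob,
    >=20% cov & hit length >=100."""
    return (probability >= PROFILE_PROB_MIN and coverage >= PROFILE_COV_MIN) or (
        probability >= PROFILE_PROB_MIN_ALT
        and coverage >= PROFILE_COV_MIN_ALT
        and hit_length >= PROFILE_LEN_MIN_ALT
    )


def merge_ipfs(
    pcs: Sequence[ProteinCluster],
    profile_hits: Iterable[tuple[str, str, float, float, float]],
) -> list[IPF]:
    """Merge PCs into iPFs along qualifying profile-profile hits.

    ``profile_hits`` are ``(pc_a, pc_b, probability, coverage, hit_length)``
    tuples; qualifying hits define edges and iPFs are the connected
    components (transitive closure), so the result is independent of hit
    order.
    """
    known = {pc.pc_id for pc in pcs}
    parent = {pc.pc_id: pc.pc_id for pc in pcs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, prob, cov, hlen in profile_hits:
        if a not in known or b not in known:
            raise ValueError(f"profile hit references unknown PC: {a!r}/{b!r}")
        if profile_hit_qualifies(prob, cov, hlen):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    comps: dict[str, list[str]] = {}
    for pc in pcs:
        comps.setdefault(find(pc.pc_id), []).append(pc.pc_id)
    return [
        IPF(ipf_id=f"iPF_{i:05d}", pc_ids=sorted(members))
        for i, (_, members) in enumerate(sorted(comps.items()))
    ]


# ---------------------------------------------------------------------------
# Family-level utilities


def filter_partial_sequences(lengths: Mapping[str, int]) -> list[str]:
    """Drop likely partial sequences from a family.

    The mean length is computed excluding the top and bottom 10% of values
    (floor(0.1 n) trimmed from each side); sequences shorter than half that
    trimmed mean are excluded.  The pass is repeated until no further
    sequence drops out, which makes the filter idempotent (removing the
    shortest members can raise the trimmed mean enough to expose further
    partials).
    """
    if not lengths:
        raise ValueError("no sequences")
    kept = dict(lengths)
    while kept:
        items = sorted(kept.items(), key=lambda kv: (kv[1], kv[0]))
        n = len(items)
        t = n // 10
        core = items[t : n - t] if n - 2 * t > 0 else items
        mean = sum(v for _, v in core) / len(core)
        survivors = {k: v for k, v in kept.items() if v >= 0.5 * mean}
        if len(survivors) == len(kept):
            break
        kept = survivors
    return sorted(kept)


def annotate_ipfs(
    ipfs: Sequence[IPF],
    pc_members: Mapping[str, Sequence[str]],
    protein_labels: Mapping[str, str],
) -> list[IPF]:
    """Label each iPF with the most frequent non-empty member label.

    Ties break lexicographically and set ``ambiguous_label``; iPFs whose
    members are all unlabeled stay unlabeled.
    """
    out = []
    for ipf in ipfs:
        counts: dict[str, int] = {}
        for pc_id in ipf.pc_ids:
            for prot in pc_members.get(pc_id, ()):
                lbl = protein_labels.get(prot, "")
                if lbl:
                    counts[lbl] = counts.get(lbl, 0) + 1
        if not counts:
            out.append(IPF(ipf.ipf_id, list(ipf.pc_ids), label=None))
            continue
        top = max(counts.values())
        winners = sorted(l for l, c in counts.items() if c == top)
        out.append(
            IPF(ipf.ipf_id, list(ipf.pc_ids), label=winners[0],
                ambiguous_label=len(winners) > 1)
        )
    return out


def find_ta_pairs(
    genome_genes: Mapping[str, Sequence[str]],
    gene_ipf: Mapping[str, str],
    ipf_annotation: Mapping[str, str],
    max_gap: int = 1,
) -> tuple[list[tuple[str, str, str]], list[str]]:
    """Toxin-antitoxin candidate screen by gene-order co-occurrence.

    ``genome_genes`` maps genome -> ordered gene ids; ``gene_ipf`` maps
    gene -> iPF; ``ipf_annotation`` maps iPF -> functional label.  For each
    toxin-annotated gene, genes at most ``max_gap`` positions away on
    either side are reported as ``(genome, toxin_gene, partner_gene)``
    pairs.  Unannotated iPFs adjacent to a toxin iPF in >= 2 distinct
    genomes are additionally returned as putative antitoxins.
    """
    pairs: list[tuple[str, str, str]] = []
    candidate_genomes: dict[str, set[str]] = {}
    for genome, genes in genome_genes.items():
        for idx, gid in enumerate(genes):
            ipf = gene_ipf.get(gid)
            if ipf is None or "toxin" not in ipf_annotation.get(ipf, "").lower():
                continue
            if "antitoxin" in ipf_annotation.get(ipf, "").lower():
                continue
            lo, hi = max(0, idx - max_gap), min(len(genes), idx + max_gap + 1)
            for nidx in range(lo, hi):
                if nidx == idx:
                    continue
                partner = genes[nidx]
                pairs.append((genome, gid, partner))
                p_ipf = gene_ipf.get(partner)
                if p_ipf is not None and not ipf_annotation.get(p_ipf, ""):
                    candidate_genomes.setdefault(p_ipf, set()).add(genome)
    putative_antitoxins = sorted(
        ipf for ipf, gs in candidate_genomes.items() if len(gs) >= 2
    )
    return pairs, putative_antitoxins


def write_membership_tsv(pcs: Sequence[ProteinCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pc_id\tprotein_id\n")
        for pc in pcs:
            for m in pc.members:
                fh.write(f"{pc.pc_id}\t{m}\n")
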