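"""ANI-based species dereplication of inovirus predictions.

Species demarcation follows the ICTV criterion for filamentous phages:
95% nucleotide identity over the full length of the shorter sequence
(alignment fraction 1.0, with a 0.999 numerical tolerance).  Clustering
is greedy and seeded in tiers so that the most trustworthy predictions —
circular contigs and genome-derived proviruses with canonical att sites —
anchor the species, and metagenome fragments only join or found clusters
afterwards.  Tandem predictions (multiple pI genes, i.e. probable
adjacent multi-integrations) are pooled and clustered separately so they
cannot bridge distinct species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np

logger = logging.getLogger(__name__)

SPECIES_ANI_MIN = 95.0
SPECIES_AF_MIN = 0.999  # "100% alignment fraction" with edge tolerance
HOST_ANI_MIN = 95.0
HOST_AF_MIN = 0.95

ANCHOR_K = 15  # k-mer anchor size for ANI block chaining

#: Seeding order: lower tier = higher clustering priority.
TIER_NAMES = {
    1: "circular/canonical genome-derived",
    2: "noncanonical genome-derived",
    3: "other genome-derived",
    4: "metagenome-derived",
}


@dataclass(frozen=True)
class ANIResult:
    ani: float  # percent identity over aligned blocks, 0-100
    af: float  # aligned fraction of the shorter sequence, 0-1

    def __post_init__(self) -> None:
        if not (0.0 <= self.ani <= 100.0 and 0.0 <= self.af <= 1.0):
            raise ValueError(f"invalid ANI result ({self.ani}, {self.af})")


@dataclass
class SpeciesCluster:
    species_id: str
    representative_id: str
    member_ids: list[str]
    seed_tier: int | str = 3


def _kmer_anchors(a: str, b: str, k: int = ANCHOR_K) -> list[tuple[int, int]]:
    """Shared-k-mer (position_a, position_b) anchors, unique k-mers only."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    anchors = []
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            anchors.append((i, j))
    return anchors


def _chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest co-linear chain (strictly increasing in both coordinates).

    Patience-style longest-increasing-subsequence on the second coordinate
    after sorting by the first; O(n log n)."""
    import bisect

    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda ab: (ab[0], ab[1]))
    tails: list[int] = []  # tails[d] = min end b-coordinate of chain of length d+1
    back: list[int] = [-1] * len(anchors)
    tail_idx: list[int] = []
    for idx, (_, b) in enumerate(anchors):
        d = bisect.bisect_left(tails, b)
        if d == len(tails):
            tails.append(b)
            tail_idx.append(idx)
        else:
            tails[d] = b
            tail_idx[d] = idx
        back[idx] = tail_idx[d - 1] if d > 0 else -1
    chain = []
    cur = tail_idx[len(tails) - 1]
    while cur != -1:
        chain.append(anchors[cur])
        cur = back[cur]
    return chain[::-1]


def _xdrop_extend(seq_a: str, seq_b: str, a: int, b: int, step: int, xdrop: float = 20.0) -> int:
    """Ungapped X-drop extension length from (a, b) in direction ``step``.

    Scores +1/match, -2/mismatch; stops at a sequence end or when the
    running score falls ``xdrop`` below its maximum.  Returns the number of
    bases up to and including the best-scoring position.
    """
    best, cur, best_len, l = 0.0, 0.0, 0, 0
    while True:
        pa = a + l if step > 0 else a - 1 - l
        pb = b + l if step > 0 else b - 1 - l
        if not (0 <= pa < len(seq_a) and 0 <= pb < len(seq_b)):
            break
        cur += 1.0 if seq_a[pa] == seq_b[pb] else -2.0
        l += 1
        if cur > best:
            best, best_len = cur, l
        if cur < best - xdrop:
            break
    return best_len


def compute_ani(seq_a: str, seq_b: str, k: int = ANCHOR_K) -> ANIResult:
    """Average nucleotide identity via k-mer anchor chaining.

    Shared ``k``-mers are chained co-linearly; the chained region is
    extended at both ends with an ungapped X-drop rule, then aligned
    globally (edit distance) and identity is computed over that aligned
    block.  ``af`` is the aligned length as a fraction of the shorter
    sequence.  Pairs sharing no ``k``-mer return (0, 0).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_a == seq_b:
        return ANIResult(100.0, 1.0)
    chain = _chain(_kmer_anchors(seq_a, seq_b, k))
    if not chain:
        return ANIResult(0.0, 0.0)
    a0, b0 = chain[0]
    a1, b1 = chain[-1][0] + k, chain[-1][1] + k
    head = _xdrop_extend(seq_a, seq_b, a0, b0, step=-1)
    tail = _xdrop_extend(seq_a, seq_b, a1, b1, step=+1)
    sub_a = seq_a[a0 - head : a1 + tail]
    sub_b = seq_b[b0 - head : b1 + tail]
    res = edlib.align(sub_a, sub_b, mode="NW", task="distance")
    aligned_len = max(len(sub_a), len(sub_b))
    matches = aligned_len - res["editDistance"]
    ani = 100.0 * matches / aligned_len
    af = min(len(sub_a), len(sub_b)) / min(len(seq_a), len(seq_b))
    return ANIResult(max(0.0, min(100.0, ani)), max(0.0, min(1.0, af)))


def _greedy_seeded(
    ids: Sequence[str],
    sequences: Mapping[str, str],
    ani_min: float,
    af_min: float,
    existing_seeds: Sequence[str] = (),
) -> tuple[dict[str, str], list[str]]:
    """Greedy clustering of ``ids`` against existing seeds, then new seeds.

    Sequences (longest first, ties by id) join the first seed they match at
    ani >= ani_min and af >= af_min; otherwise they found a new cluster.
    Returns (assignment id -> seed id, list of new seeds in creation order).
    """
    assignment: dict[str, str] = {}
    seeds = list(existing_seeds)
    new_seeds: list[str] = []
    for sid in sorted(ids, key=lambda s: (-len(sequences[s]), s)):
        for seed in seeds:
            r = compute_ani(sequences[sid], sequences[seed])
            if r.ani >= ani_min and r.af >= af_min:
                assignment[sid] = seed
                break
        else:
            seeds.append(sid)
            new_seeds.append(sid)
            assignment[sid] = sid
    return assignment, new_seeds


def cluster_species(
    sequences: Mapping[str, str],
    tiers: Mapping[str, int],
    tandem_ids: set[str] | frozenset[str] = frozenset(),
    ani_min: float = SPECIES_ANI_MIN,
    af_min: float = SPECIES_AF_MIN,
) -> list[SpeciesCluster]:
    """Tiered greedy species clustering at 95% ANI / full alignment fraction.

    Tiers are processed in priority order 1..4; within each tier,
    still-unassigned sequences are clustered greedily (longest first),
    joining any seed from the current or earlier tiers.  Tandem sequences
    are pooled and clustered separately with the same rule.  The cluster
    representative is always its seed, so a lower-priority sequence can
    never represent a cluster holding a higher-priority one.
    """
    tandem_ids = set(tandem_ids)
    regular = [s for s in sequences if s not in tandem_ids]
    assignment: dict[str, str] = {}
    seed_tier: dict[str, int | str] = {}
    seeds: list[str] = []
    for tier in sorted(set(tiers.get(s, 4) for s in regular)):
        tier_ids = [s for s in regular if tiers.get(s, 4) == tier and s not in assignment]
        sub, new_seeds = _greedy_seeded(tier_ids, sequences, ani_min, af_min, seeds)
        assignment.update(sub)
        for s in new_seeds:
            seed_tier[s] = tier
        seeds.extend(new_seeds)
    t_assignment, t_seeds = _greedy_seeded(
        sorted(tandem_ids), sequences, ani_min, af_min, ()
    )
    clusters: dict[str, SpeciesCluster] = {}
    for sid, seed in itertools.chain(assignment.items(), t_assignment.items()):
        tier = "tandem" if seed in t_seeds else seed_tier[seed]
        key = ("tandem_" if tier == "tandem" else "") + seed
        c = clusters.setdefault(
            key,
            SpeciesCluster(
                species_id=f"sp_{len(clusters):04d}",
                representative_id=seed,
                member_ids=[],
                seed_tier=tier,
            ),
        )
        c.member_ids.append(sid)
    out = list(clusters.values())
    for c in out:
        c.member_ids.sort()
    return out


def dereplicate_hosts(
    genomes: Mapping[str, str],
    ani_min: float = HOST_ANI_MIN,
    af_min: float = HOST_AF_MIN,
) -> list[SpeciesCluster]:
    """Host-genome dereplication at 95% identity / 95% alignment fraction."""
    assignment, seeds = _greedy_seeded(sorted(genomes), genomes, ani_min, af_min)
    clusters: dict[str, SpeciesCluster] = {}
    for gid, seed in assignment.items():
        c = clusters.setdefault(
            seed,
            SpeciesCluster(
                species_id=f"host_{len(clusters):04d}",
                representative_id=seed,
                member_ids=[],
                seed_tier=1,
            ),
        )
        c.member_ids.append(gid)
    for c in clusters.values():
        c.member_ids.sort()
    return list(clusters.values())


def accumulation_curve(
    species_of: Mapping[str, str],
    n_orderings: int = 100,
    seed: int = 42,
) -> np.ndarray:
    """Mean species-accumulation curve over random input orderings.

    For each of ``n_orderings`` random permutations of the sequences, the
    cumulative number of distinct species among the first i sequences is
    recorded; the per-position mean is returned.  The curve is monotone
    non-decreasing and ends at the total species count for every ordering.
    """
    ids = sorted(species_of)
    if not ids:
        raise ValueError("no sequences")
    rng = np.random.default_rng(seed)
    total = np.zeros(len(ids))
    for _ in range(n_orderings):
        perm = rng.permutation(len(ids))
        seen: set[str] = set()
        for pos, idx in enumerate(perm):
            seen.add(species_of[ids[idx]])
            total[pos] += len(seen)
    return total / n_orderings


def assign_tiers(predictions, source_class: Mapping[str, str]) -> dict[str, int]:
    """Map predictions to seeding tiers from completeness + provenance.

    Genome-derived circular or canonical-att predictions are tier 1,
    genome-derived noncanonical-att tier 2, other genome-derived tier 3,
    anything metagenome-derived tier 4.
    """
    tiers: dict[str, int] = {}
    for p in predictions:
        meta = source_class.get(p.prediction_id, "isolate_genome") == "metagenome"
        if meta:
            tiers[p.prediction_id] = 4
        elif p.completeness in ("circular", "canonical_att"):
            tiers[p.prediction_id] = 1
        elif p.completeness == "noncanonical_att":
            tiers[p.prediction_id] = 2
        else:
            tiers[p.prediction_id] = 3
    return tiers
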