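"""Morphogenesis (pI) ATPase marker detection and model refinement.

The pI gene — an FtsK/HerA-superfamily ATPase related to the Zot domain —
is the only gene conserved across all inoviruses and therefore the anchor
of the whole detection pipeline.  The default marker engine is an ungapped
position-specific scoring matrix (PSSM) scan; parsed ``hmmsearch --tblout``
output can be used instead via :func:`parse_hmmsearch_tblout`, with the
same downstream contract (bit score + E-value filtering).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .protein_features import TMDSpan, predict_tmds

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: hmmsearch-style profile hit thresholds: bit score >= 30 and E <= 0.001.
PROFILE_SCORE_MIN = 30.0
PROFILE_EVALUE_MAX = 0.001
#: blastp-style singleton-marker threshold: bit score >= 50.
SINGLETON_SCORE_MIN = 50.0


@dataclass
class MarkerModel:
    """Ungapped per-position log-odds model over the 20 amino acids."""

    model_id: str
    columns: np.ndarray  # shape (length, 20)
    origin: str = "seed"

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("model columns must be (length, 20)")
        if not np.isfinite(self.columns).all():
            raise ValueError("model scores must be finite")

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# model_id=%s origin=%s\n" % (self.model_id, self.origin))
            fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, col in enumerate(self.columns):
                fh.write(str(i) + "\t" + "\t".join(f"{v:.6g}" for v in col) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerModel":
        model_id, origin, rows = "model", "seed", []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split():
                        if tok.startswith("model_id="):
                            model_id = tok.split("=", 1)[1]
                        elif tok.startswith("origin="):
                            origin = tok.split("=", 1)[1]
                elif line.startswith("pos\t"):
                    continue
                elif line.strip():
                    rows.append([float(x) for x in line.split("\t")[1:]])
        return cls(model_id=model_id, columns=np.array(rows), origin=origin)


@dataclass(frozen=True)
class MarkerHit:
    gene_id: str
    model_id: str
    bit_score: float
    e_value: float
    ali_span: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))
    """((model_start, model_end), (target_start, target_end)), half-open."""


def default_evalue_calibration(bit_score: float, n_targets: int) -> float:
    """E = N_targets * 2**(-bit_score), the standard bit-score identity."""
    return n_targets * float(2.0 ** (-bit_score))


def encode_protein(protein: str) -> np.ndarray:
    """Map residues to PSSM column indices; unknown residues -> -1."""
    return np.array([_AA_INDEX.get(a, -1) for a in protein.upper()], dtype=int)


def score_profile(
    model: MarkerModel,
    protein: str,
    gene_id: str = "",
    n_targets: int = 1,
    evalue_calibration=default_evalue_calibration,
) -> MarkerHit | None:
    """Best ungapped placement of ``model`` along ``protein``.

    The bit score is the maximum over all placements of the summed
    per-column log-odds.  Unknown residues contribute 0 (with a warning).
    When the protein is shorter than the model, the protein slides inside
    the model instead (full-overlap placements in both cases).
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    idx = encode_protein(protein)
    if (idx < 0).any():
        warnings.warn(f"unknown residue(s) in {gene_id or 'protein'}; scored as 0")
    L, n = model.length, len(idx)
    cols = model.columns
    best_score = -np.inf
    best_span = ((0, L), (0, n))
    if n >= L:
        for off in range(n - L + 1):
            window = idx[off : off + L]
            valid = window >= 0
            s = cols[np.arange(L)[valid], window[valid]].sum()
            if s > best_score:
                best_score, best_span = s, ((0, L), (off, off + L))
    else:
        for off in range(L - n + 1):
            valid = idx >= 0
            s = cols[off + np.arange(n)[valid], idx[valid]].sum()
            if s > best_score:
                best_score, best_span = s, ((off, off + n), (0, n))
    return MarkerHit(
        gene_id=gene_id,
        model_id=model.model_id,
        bit_score=float(best_score),
        e_value=evalue_calibration(float(best_score), n_targets),
        ali_span=best_span,
    )


def scan_proteins(
    models: Sequence[MarkerModel],
    proteins: Mapping[str, str],
    evalue_calibration=default_evalue_calibration,
) -> list[MarkerHit]:
    """Score every protein against every model; best model per protein."""
    n_targets = len(proteins)
    hits = []
    for gene_id, prot in proteins.items():
        best: MarkerHit | None = None
        for model in models:
            h = score_profile(model, prot, gene_id=gene_id, n_targets=n_targets,
                              evalue_calibration=evalue_calibration)
            if h is not None and (best is None or h.bit_score > best.bit_score):
                best = h
        if best is not None:
            hits.append(best)
    return hits


def filter_marker_hits(hits: Iterable[MarkerHit], mode: str = "profile") -> list[MarkerHit]:
    """Apply the marker acceptance thresholds, preserving input order.

    ``profile`` keeps hits with bit score >= 30 and E <= 0.001 (the
    hmmsearch criterion); ``singleton`` keeps bit score >= 50 (the blastp
    criterion for markers with a single reference sequence).
    """
    if mode == "profile":
        return [h for h in hits
                if h.bit_score >= PROFILE_SCORE_MIN and h.e_value <= PROFILE_EVALUE_MAX]
    if mode == "singleton":
        return [h for h in hits if h.bit_score >= SINGLETON_SCORE_MIN]
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Model refinement


def pairwise_identity(a: str, b: str) -> float:
    """Global identity over the shorter sequence (cd-hit-like convention)."""
    import edlib

    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    res = edlib.align(short, long_, mode="HW", task="distance")
    return max(0.0, 1.0 - res["editDistance"] / len(short))


def greedy_identity_clusters(sequences: Sequence[str], threshold: float = 0.90) -> list[list[int]]:
    """Greedy longest-first clustering at a global-identity threshold.

    Mirrors cd-hit's behaviour: sequences sorted by length (desc, then by
    original index for determinism); each joins the first existing centroid
    it matches at >= ``threshold`` identity, else founds a new cluster.
    """
    order = sorted(range(len(sequences)), key=lambda i: (-len(sequences[i]), i))
    centroids: list[int] = []
    clusters: list[list[int]] = []
    for i in order:
        for c, cen in enumerate(centroids):
            if pairwise_identity(sequences[i], sequences[cen]) >= threshold:
                clusters[c].append(i)
                break
        else:
            centroids.append(i)
            clusters.append([i])
    return clusters


def build_model_from_sequences(
    sequences: Sequence[str],
    model_id: str,
    origin: str = "seed",
    pseudocount: float = 1.0,
) -> MarkerModel:
    """Build a PSSM from sequences via star alignment to the longest one.

    Each sequence is globally aligned to the centroid (longest sequence,
    ties by input order); residue counts are accumulated per centroid
    column, turned into log2 odds against a uniform background with
    pseudocounts.  Model length equals the centroid (ungapped consensus)
    length.  Deterministic.
    """
    import edlib

    if not sequences:
        raise ValueError("need at least one sequence")
    centroid = max(sequences, key=len)
    L = len(centroid)
    counts = np.zeros((L, 20))
    for seq in sequences:
        res = edlib.align(seq, centroid, mode="NW", task="path")
        # walk the alignment, mapping seq residues onto centroid columns
        nice = edlib.getNiceAlignment(res, seq, centroid)
        col = 0
        for qa, ta in zip(nice["query_aligned"], nice["target_aligned"]):
            if ta != "-":
                if qa != "-" and qa in _AA_INDEX:
                    counts[col, _AA_INDEX[qa]] += 1
                col += 1
    probs = (counts + pseudocount / 20.0) / (counts.sum(axis=1, keepdims=True) + pseudocount)
    columns = np.log2(probs / 0.05)
    return MarkerModel(model_id=model_id, columns=columns, origin=origin)


def refine_marker_models(
    validated_pi_proteins: Sequence[str],
    round_id: int,
    identity_threshold: float = 0.90,
    model_id: str | None = None,
) -> MarkerModel:
    """Rebuild the pI marker model from a new set of validated proteins.

    Proteins are clustered at 90% amino-acid identity (greedy longest-first);
    one representative per cluster (the centroid) enters a deterministic
    star alignment from which the refined PSSM is built.
    """
    if len(validated_pi_proteins) < 2:
        raise ValueError("refinement requires at least 2 sequences")
    clusters = greedy_identity_clusters(validated_pi_proteins, identity_threshold)
    reps = [validated_pi_proteins[c[0]] for c in clusters]
    return build_model_from_sequences(
        reps,
        model_id=model_id or f"pI_refined_r{round_id}",
        origin=f"refined-round-{round_id}",
    )


# ---------------------------------------------------------------------------
# pI characterization


def classify_pi_topology(protein: str, tmds: Sequence[TMDSpan] | None = None) -> str:
    """Locate the pI TMD: C-terminal third -> ``canonical_C_terminal``,
    N-terminal third -> ``atypical_N_terminal``, otherwise ``none``.

    Canonical pI proteins anchor in the membrane via a C-terminal TMD; a
    sizeable minority of inovirus-like sequences instead carry the TMD at
    the N terminus.
    """
    if tmds is None:
        tmds = predict_tmds(protein)
    if not tmds:
        return "none"
    n = len(protein)
    for tmd in tmds:
        if tmd.midpoint >= 2 * n / 3:
            return "canonical_C_terminal"
    for tmd in tmds:
        if tmd.midpoint <= n / 3:
            return "atypical_N_terminal"
    return "none"


def validate_pi_cluster(
    member_proteins: Mapping[str, str],
    member_contexts: Mapping[str, Sequence[str]],
) -> tuple[bool, list[str]]:
    """Decide whether a protein cluster is a genuine inovirus pI cluster.

    Criteria: (a) a majority of members carry 1-2 TMDs (N- or C-terminal
    location both accepted) and (b) at least half of the members co-occur
    with >=1 inovirus-expected gene class in their genome neighbourhood
    (``member_contexts`` values are label lists; replication-initiation or
    structural-candidate labels qualify).  Returns (verdict, failed reasons).
    """
    if not member_proteins:
        return False, ["empty cluster"]
    reasons = []
    n = len(member_proteins)
    with_tmd = sum(
        1 for p in member_proteins.values() if len(predict_tmds(p)) in (1, 2)
    )
    if with_tmd <= n / 2:
        reasons.append("no TMD" if with_tmd == 0 else "TMD minority")
    expected = {"replication", "structural"}
    with_context = sum(
        1
        for gid in member_proteins
        if any(lbl in expected for lbl in member_contexts.get(gid, ()))
    )
    if with_context < n / 2:
        reasons.append("context")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# hmmsearch interoperability


def parse_hmmsearch_tblout(path: str | Path) -> list[MarkerHit]:
    """Parse ``hmmsearch --tblout`` output into MarkerHits.

    Columns used: target name (1), query name (3), full-sequence E-value (5)
    and bit score (6).
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            hits.append(
                MarkerHit(
                    gene_id=parts[0],
                    model_id=parts[2],
                    e_value=float(parts[4]),
                    bit_score=float(parts[5]),
                )
            )
    return hits
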