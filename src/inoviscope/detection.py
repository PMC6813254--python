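"""Inovirus detection around pI marker genes.

The core of the pipeline: given a pI-like marker hit, score candidate
genome windows with a random-forest classifier trained on genome-context
features, keep the best-scoring window if its score exceeds 0.9, then
delineate the provirus by searching the flanks for direct-repeat att
sites (>=10 bp, duplicated on integration).  Predictions are typed by
completeness: ``circular`` (whole circular contig), ``canonical_att``
(repeat in a tRNA or outside an integrase), ``noncanonical_att`` (plain
direct repeat) or ``fuzzy`` (no boundary evidence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .genome_io import AnnotatedGenome, GeneRecord, REPLICATION_KEYWORDS, _flag
from .protein_features import is_candidate_structural

logger = logging.getLogger(__name__)

#: Window classifier acceptance cutoff for the best-scoring window.
WINDOW_SCORE_MIN = 0.9
#: Maximum number of genes in a candidate window around the pI gene.
MAX_WINDOW_GENES = 30
#: Minimum direct-repeat length for an att site (bp).
MIN_ATT_REPEAT = 10
#: Default distance searched on each side of a candidate region for att repeats.
DEFAULT_FLANK_BP = 20_000
#: Terminal exact repeat length used to infer circularity when topology
#: metadata is absent.
MIN_TERMINAL_REPEAT = 20

FEATURE_NAMES = (
    "gene_density_per_kb",
    "median_gene_length_nt",
    "frac_genes_lt300nt",
    "frac_unannotated",
    "n_structural_candidates",
    "frac_known_pc_hits",
    "mean_intergenic_gap_bp",
    "strand_coherence",
    "replication_gene_present",
    "window_size_over_30",
)


# ---------------------------------------------------------------------------
# Feature extraction


def _structural_flags(genes: Sequence[GeneRecord]) -> list[bool]:
    return [bool(g.translation) and is_candidate_structural(g.translation) for g in genes]


def extract_features(
    genome: AnnotatedGenome,
    contig_id: str,
    window: tuple[int, int],
    known_pc_hits: Mapping[str, bool] | None = None,
    structural_flags: Sequence[bool] | None = None,
) -> np.ndarray:
    """Genome-context feature vector for a gene-index window (inclusive).

    The ten features capture what distinguishes an integrated inovirus from
    host background: dense, short, poorly annotated genes, enrichment in
    short single-TMD structural candidates and known inovirus protein
    clusters, tight intergenic spacing, strong strand coherence and the
    presence of a replication-initiation (RCR) gene.  ``structural_flags``
    may carry precomputed per-gene candidacy to avoid recomputation during
    window scans.
    """
    genes = genome.contig_genes(contig_id)
    i, j = window
    if not (0 <= i <= j < len(genes)):
        raise ValueError(f"window {window} outside gene list (n={len(genes)})")
    sub = genes[i : j + 1]
    n = len(sub)
    span_bp = sub[-1].end - sub[0].start
    lengths = np.array([g.length for g in sub])
    if structural_flags is None:
        struct = _structural_flags(sub)
    else:
        struct = list(structural_flags[i : j + 1])
    pc_hits = known_pc_hits or {}
    gaps = [max(0, b.start - a.end) for a, b in zip(sub, sub[1:])]
    strands = [g.strand for g in sub]
    modal_frac = max(strands.count("+"), strands.count("-")) / n
    has_rep = any(_flag(g.annotation_labels, REPLICATION_KEYWORDS) for g in sub)
    return np.array(
        [
            n / (span_bp / 1000.0) if span_bp > 0 else 0.0,
            float(np.median(lengths)),
            float(np.mean(lengths < 300)),
            float(np.mean([g.is_hypothetical for g in sub])),
            float(sum(struct)),
            float(np.mean([bool(pc_hits.get(g.gene_id, False)) for g in sub])),
            float(np.mean(gaps)) if gaps else 0.0,
            modal_frac,
            1.0 if has_rep else 0.0,
            n / 30.0,
        ]
    )


# ---------------------------------------------------------------------------
# Classifier


@dataclass
class ClassifierModel:
    """A trained window classifier plus metadata.

    ``score`` is the fraction of forest trees voting "inovirus" (for the
    logistic baseline it is the predicted probability), so it always lies
    in [0, 1].
    """

    estimator: object
    feature_names: tuple[str, ...] = FEATURE_NAMES
    kind: str = "random_forest"
    version: str = "1"

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kind == "random_forest":
            votes = np.zeros(X.shape[0])
            for tree in self.estimator.estimators_:
                votes += tree.predict(X)
            return votes / len(self.estimator.estimators_)
        return self.estimator.predict_proba(X)[:, 1]

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump({"version": self.version, "kind": self.kind,
                     "feature_names": self.feature_names,
                     "estimator": self.estimator}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        import joblib

        d = joblib.load(path)
        return cls(estimator=d["estimator"], feature_names=tuple(d["feature_names"]),
                   kind=d["kind"], version=d["version"])


def train_classifier(
    labeled: Sequence[tuple[np.ndarray, int]],
    seed: int = 42,
    n_trees: int = 2000,
    kind: str = "random_forest",
) -> ClassifierModel:
    """Train the window classifier (random forest, 2,000 trees by default).

    Labels are 1 for inovirus windows, 0 for background.  A logistic
    regression baseline is available via ``kind="logistic"``; both expose
    the same scoring interface.  Raises on single-class input.
    """
    X = np.array([f for f, _ in labeled], dtype=float)
    y = np.array([int(l) for _, l in labeled])
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    if kind == "random_forest":
        est = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    elif kind == "logistic":
        est = LogisticRegression(max_iter=1000, random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    est.fit(X, y)
    return ClassifierModel(estimator=est, kind=kind)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment: stratified, with total fold sizes differing by <=1.

    Samples are shuffled within class, concatenated class-by-class, and
    dealt round-robin; the round-robin pass over the concatenated list
    balances totals exactly while keeping each class nearly even per fold.
    """
    rng = np.random.default_rng(seed)
    order = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        order.extend(idx.tolist())
    folds = np.empty(len(y), dtype=int)
    for pos, sample in enumerate(order):
        folds[sample] = pos % k
    return folds


def cross_validate(
    labeled: Sequence[tuple[np.ndarray, int]],
    k: int = 10,
    seed: int = 42,
    n_trees: int = 2000,
    kind: str = "random_forest",
    fpr_operating_max: float = 0.01,
):
    """k-fold cross-validation with a pooled-score ROC curve.

    Each sample is scored exactly once as a validation sample; the ROC is
    computed on the pooled out-of-fold scores.  The reported operating
    point is the highest true-positive rate achievable at a false-positive
    rate below ``fpr_operating_max`` (default <1%).

    Returns ``(roc_table, operating_point, pooled_scores)`` where
    ``roc_table`` is a pandas DataFrame with ``fpr``/``tpr`` columns and
    ``operating_point`` a dict with ``tpr``, ``fpr`` and ``auc``.
    """
    import pandas as pd
    from sklearn.metrics import roc_auc_score

    X = np.array([f for f, _ in labeled], dtype=float)
    y = np.array([int(l) for _, l in labeled])
    for cls in np.unique(y):
        if (y == cls).sum() < k:
            raise ValueError(f"k={k} exceeds size of class {cls}")
    folds = _stratified_folds(y, k, seed)
    scores = np.empty(len(y))
    for f in range(k):
        val = folds == f
        model = train_classifier(
            list(zip(X[~val], y[~val])), seed=seed + f, n_trees=n_trees, kind=kind
        )
        scores[val] = model.score(X[val])
    fpr, tpr, _ = roc_curve(y, scores)
    roc_table = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    ok = fpr < fpr_operating_max
    op = {
        "tpr": float(tpr[ok].max()) if ok.any() else 0.0,
        "fpr": float(fpr_operating_max),
        "auc": float(roc_auc_score(y, scores)),
    }
    return roc_table, op, scores


# ---------------------------------------------------------------------------
# Window scan


def enumerate_windows(
    n_genes: int, pi_index: int, max_genes: int = MAX_WINDOW_GENES
) -> list[tuple[int, int]]:
    """All gene-index intervals containing ``pi_index`` with size <= max.

    Intervals are truncated at contig ends; ordering is (size asc, start
    asc) so that the first argmax under a stable max realizes the
    smallest-then-leftmost tie-break.
    """
    if not (0 <= pi_index < n_genes):
        raise ValueError("pi_index outside gene list")
    out = []
    for size in range(1, min(max_genes, n_genes) + 1):
        for i in range(max(0, pi_index - size + 1), min(pi_index, n_genes - size) + 1):
            out.append((i, i + size - 1))
    return out


def scan_windows(
    genome: AnnotatedGenome,
    contig_id: str,
    pi_gene_index: int,
    model: ClassifierModel | Callable[[np.ndarray], np.ndarray],
    known_pc_hits: Mapping[str, bool] | None = None,
    max_genes: int = MAX_WINDOW_GENES,
    score_threshold: float = WINDOW_SCORE_MIN,
) -> tuple[tuple[int, int], float] | None:
    """Best-scoring gene window around the pI gene, if it clears 0.9.

    Enumerates every interval of at most ``max_genes`` genes containing the
    pI gene, scores each with the classifier, and returns the argmax
    interval with its score when the score exceeds ``score_threshold``
    (strict), else None.  Ties break to the smallest interval, then the
    leftmost.  ``model`` may be any callable mapping a feature matrix to
    scores (used by the brute-force equivalence tests).
    """
    genes = genome.contig_genes(contig_id)
    if not genes:
        return None
    windows = enumerate_windows(len(genes), pi_gene_index, max_genes)
    struct = _structural_flags(genes)
    X = np.array(
        [
            extract_features(genome, contig_id, w, known_pc_hits, structural_flags=struct)
            for w in windows
        ]
    )
    scorer = model.score if isinstance(model, ClassifierModel) else model
    scores = np.asarray(scorer(X), dtype=float)
    best = int(np.argmax(scores))  # first max = smallest, then leftmost
    if scores[best] > score_threshold:
        return windows[best], float(scores[best])
    return None


# ---------------------------------------------------------------------------
# att sites


@dataclass(frozen=True)
class AttSite:
    """A direct-repeat attachment site (coordinates 0-based half-open).

    ``context`` is ``tRNA`` (a copy overlaps a tRNA gene, the canonical
    integration target), ``non_integrase`` (the enclosed region carries an
    integrase gene that neither copy interrupts) or ``plain``.
    """

    repeat_seq: str
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    context: str = "plain"

    def __post_init__(self) -> None:
        if len(self.repeat_seq) < 1:
            raise ValueError("empty repeat")
        if self.left_span[1] > self.right_span[0]:
            raise ValueError("left copy must be entirely upstream of right copy")


def maximal_direct_repeats(
    left: str, right: str, min_repeat: int = MIN_ATT_REPEAT
) -> list[tuple[int, int, int]]:
    """All maximal exact repeats with one copy in each flank string.

    Returns ``(left_offset, right_offset, length)`` triples with
    ``length >= min_repeat``; a pair is maximal when it cannot be extended
    by one base on either side within the flank strings.  Seed-and-extend
    on ``min_repeat``-mers; equivalent to the quadratic all-pairs scan.
    """
    k = min_repeat
    if len(left) < k or len(right) < k:
        return []
    seeds: dict[str, list[int]] = {}
    for i in range(len(left) - k + 1):
        seeds.setdefault(left[i : i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()
    for j in range(len(right) - k + 1):
        for i in seeds.get(right[j : j + k], ()):
            a, b = i, j
            while a > 0 and b > 0 and left[a - 1] == right[b - 1]:
                a, b = a - 1, b - 1
            length = k + (i - a)
            while a + length < len(left) and b + length < len(right) and left[a + length] == right[b + length]:
                length += 1
            if length >= k:
                found.add((a, b, length))
    return sorted(found)


def _overlaps(span: tuple[int, int], gene: GeneRecord) -> bool:
    return span[0] < gene.end and gene.start < span[1]


def _within(span: tuple[int, int], gene: GeneRecord) -> bool:
    return gene.start <= span[0] and span[1] <= gene.end


def find_att_sites(
    genome: AnnotatedGenome,
    contig_id: str,
    span: tuple[int, int],
    flank_bp: int = DEFAULT_FLANK_BP,
    min_repeat: int = MIN_ATT_REPEAT,
) -> list[AttSite]:
    """Direct-repeat att candidates flanking a candidate provirus span.

    Searches up to ``flank_bp`` upstream and downstream of ``span`` for
    maximal exact direct repeats of at least ``min_repeat`` bp with one
    copy on each side.  Each repeat is annotated with its integration
    context and the list is sorted by (length desc, distance to span asc).
    """
    seq = genome.contigs[contig_id]
    s0, s1 = span
    if not (0 <= s0 < s1 <= len(seq)):
        raise ValueError(f"span {span} outside contig {contig_id!r}")
    lo = max(0, s0 - flank_bp)
    hi = min(len(seq), s1 + flank_bp)
    left, right = seq[lo:s0], seq[s1:hi]
    genes = genome.contig_genes(contig_id)
    out = []
    for a, b, length in maximal_direct_repeats(left, right, min_repeat):
        lspan = (lo + a, lo + a + length)
        rspan = (s1 + b, s1 + b + length)
        enclosed = (lspan[1], rspan[0])
        if any(g.is_trna and (_overlaps(lspan, g) or _overlaps(rspan, g)) for g in genes):
            context = "tRNA"
        else:
            integrases = [g for g in genes if g.is_integrase and _overlaps(enclosed, g)]
            copy_inside = any(
                _within(lspan, g) or _within(rspan, g)
                for g in genes
                if g.is_integrase
            )
            context = "non_integrase" if integrases and not copy_inside else "plain"
        out.append(
            AttSite(
                repeat_seq=seq[lspan[0] : lspan[1]],
                left_span=lspan,
                right_span=rspan,
                context=context,
            )
        )
    out.sort(
        key=lambda att: (
            -len(att.repeat_seq),
            (s0 - att.left_span[1]) + (att.right_span[0] - s1),
            att.left_span,
        )
    )
    return out


# ---------------------------------------------------------------------------
# Prediction assembly


@dataclass(frozen=True)
class InovirusPrediction:
    """A typed inovirus detection on one contig (0-based half-open span)."""

    prediction_id: str
    contig_id: str
    span: tuple[int, int]
    pi_gene_id: str
    window_score: float
    completeness: str
    att: AttSite | None = None
    tandem: bool = False
    gene_index_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.completeness in ("canonical_att", "noncanonical_att") and self.att is None:
            raise ValueError(f"{self.completeness} prediction requires an att site")


def is_circular(genome: AnnotatedGenome, contig_id: str) -> bool:
    """Circularity from topology metadata, else inferred from an exact
    terminal repeat of >=20 bp (assembler-style circularization signature,
    searched up to 1 kb)."""
    topo = genome.topology.get(contig_id)
    if topo is not None and topo != "unknown":
        return topo == "circular"
    seq = genome.contigs[contig_id]
    for k in range(min(len(seq) // 2, 1000), MIN_TERMINAL_REPEAT - 1, -1):
        if seq[:k] == seq[-k:]:
            return True
    return False


def classify_prediction(
    genome: AnnotatedGenome,
    contig_id: str,
    window: tuple[int, int],
    att_hits: Sequence[AttSite],
    pi_count: int,
    pi_gene_id: str,
    window_score: float,
    prediction_id: str = "",
) -> InovirusPrediction:
    """Assemble a typed prediction from a scored window and att search.

    Completeness: whole circular contig -> ``circular``; best att with
    tRNA/non-integrase context -> ``canonical_att``; plain direct repeat ->
    ``noncanonical_att``; no repeat -> ``fuzzy``.  With an att pair, the
    span is extended to cover both repeat copies.  ``tandem`` marks regions
    with >=2 pI genes (likely multiple adjacent integrations).
    """
    genes = genome.contig_genes(contig_id)
    i, j = window
    span = (genes[i].start, genes[j].end)
    tandem = pi_count >= 2
    pid = prediction_id or f"{contig_id}|{span[0]}-{span[1]}"
    if is_circular(genome, contig_id):
        return InovirusPrediction(
            prediction_id=pid, contig_id=contig_id,
            span=(0, len(genome.contigs[contig_id])),
            pi_gene_id=pi_gene_id, window_score=window_score,
            completeness="circular", att=None, tandem=tandem,
            gene_index_span=(0, len(genes) - 1 if genes else 0),
        )
    if att_hits:
        canonical = [a for a in att_hits if a.context in ("tRNA", "non_integrase")]
        best = canonical[0] if canonical else att_hits[0]
        completeness = "canonical_att" if canonical else "noncanonical_att"
        span = (best.left_span[0], best.right_span[1])
        return InovirusPrediction(
            prediction_id=pid, contig_id=contig_id, span=span,
            pi_gene_id=pi_gene_id, window_score=window_score,
            completeness=completeness, att=best, tandem=tandem,
            gene_index_span=window,
        )
    return InovirusPrediction(
        prediction_id=pid, contig_id=contig_id, span=span,
        pi_gene_id=pi_gene_id, window_score=window_score,
        completeness="fuzzy", att=None, tandem=tandem,
        gene_index_span=window,
    )
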