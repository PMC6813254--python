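"""Sequence-only protein feature prediction.

Transmembrane domains (TMDs) are called with a Kyte–Doolittle hydropathy
sliding window (window 19, cutoff 1.6), signal peptides with a simple
tripartite N/H/C-region rule.  Both are deliberately lightweight heuristics
standing behind a pluggable interface: parsers for TMHMM short-format and
SignalP summary output can substitute real predictions where available.
The downstream contract only consumes span counts and positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Kyte–Doolittle hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

TMD_WINDOW = 19
TMD_CUTOFF = 1.6

# the signal-peptide H-region uses strongly hydrophobic residues only;
# A/G/S are reserved for the C-region cleavage context
_HYDROPHOBIC = set("ILMFVWC")
_BASIC = set("KR")
_SMALL = set("AGS")


@dataclass(frozen=True)
class TMDSpan:
    """A predicted membrane-spanning segment (0-based half-open residues)."""

    start: int
    end: int
    mean_hydropathy: float

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


def _hydropathy(protein: str) -> np.ndarray:
    return np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein.upper()])


def predict_tmds(protein: str, window: int = TMD_WINDOW, cutoff: float = TMD_CUTOFF) -> list[TMDSpan]:
    """Predict TMDs as maximal unions of qualifying hydropathy windows.

    A window of ``window`` residues qualifies when its mean Kyte–Doolittle
    hydropathy is >= ``cutoff``; overlapping qualifying windows are merged
    into one span.  Proteins shorter than the window yield no TMDs.
    """
    n = len(protein)
    if n < window:
        return []
    h = _hydropathy(protein)
    csum = np.concatenate([[0.0], np.cumsum(h)])
    means = (csum[window:] - csum[:-window]) / window  # means[i] = window at i
    qualifying = means >= cutoff
    spans: list[TMDSpan] = []
    i = 0
    n_windows = len(means)
    while i < n_windows:
        if not qualifying[i]:
            i += 1
            continue
        j = i
        while j + 1 < n_windows and qualifying[j + 1]:
            j += 1
        start, end = i, j + window
        spans.append(TMDSpan(start, end, float(h[start:end].mean())))
        i = j + 1
    return spans


def strip_signal_peptide(protein: str) -> tuple[str, bool]:
    """Remove an N-terminal signal peptide if the tripartite rule fires.

    Rule: within the first 35 residues, a basic residue (N-region) followed
    by a hydrophobic stretch of >=7 residues ending before position 35;
    cleavage happens after the first small residue (A/G/S) that follows the
    stretch.  Returns ``(mature, stripped)``.
    """
    if len(protein) < 10:
        return protein, False
    head = protein[:35].upper()
    for i, aa in enumerate(head):
        if aa not in _BASIC:
            continue
        # hydrophobic stretch starting after the basic residue
        j = i + 1
        while j < len(head) and head[j] not in _HYDROPHOBIC:
            if head[j] in _BASIC:
                break
            j += 1
        k = j
        while k < len(head) and head[k] in _HYDROPHOBIC:
            k += 1
        if k - j >= 7 and k < 35:
            # cleave after the first small residue following the stretch
            for c in range(k, min(len(protein), 40)):
                if protein[c].upper() in _SMALL:
                    mature = protein[c + 1 :]
                    if mature:
                        return mature, True
                    return protein, False
            return protein, False
    return protein, False


def is_candidate_structural(
    protein: str,
    min_len: int = 30,
    max_len: int = 90,
    allowed_tmd_counts: tuple[int, ...] = (1, 2),
) -> bool:
    """Inovirus structural-protein candidacy.

    After in-silico signal-peptide removal, a candidate is 30-90 aa long
    (inclusive) and carries 1 or 2 predicted TMDs.  The stricter single-TMD
    variant is available via ``allowed_tmd_counts=(1,)``.
    """
    mature, _ = strip_signal_peptide(protein)
    if not (min_len <= len(mature) <= max_len):
        return False
    return len(predict_tmds(mature)) in allowed_tmd_counts


# ---------------------------------------------------------------------------
# Optional parsers for external predictor output


def parse_tmhmm_short(path: str | Path) -> dict[str, list[TMDSpan]]:
    """Parse TMHMM short-format output into per-protein TMD spans."""
    out: dict[str, list[TMDSpan]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 5 and parts[2] == "TMhelix":
                start, end = int(parts[3]) - 1, int(parts[4])
                out.setdefault(parts[0], []).append(TMDSpan(start, end, float("nan")))
    return out


def parse_signalp_summary(path: str | Path) -> dict[str, int]:
    """Parse a SignalP summary file to per-protein cleavage positions.

    Returns ``{protein_id: cleavage_index}`` (0-based index of the first
    mature residue) for proteins with a predicted signal peptide.
    """
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) >= 2 and parts[1].strip().startswith("SP"):
                # CS position column like "CS pos: 22-23"
                for p in parts:
                    if "CS pos:" in p:
                        pos = p.split("CS pos:")[1].strip().split("-")[0]
                        out[parts[0].strip()] = int(pos)
    return out
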