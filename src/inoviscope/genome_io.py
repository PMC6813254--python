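"""Annotated-genome data model and standard-format I/O.

Every other module operates on :class:`AnnotatedGenome`: a set of contig
nucleotide sequences plus ordered per-contig gene records carrying protein
translations and free-text functional labels.  Coordinates are 0-based
half-open internally; all external files (FASTA/GFF3/TSV) use the 1-based
inclusive GFF3 convention, so ``internal_start = gff_start - 1`` and
``internal_end = gff_end`` exactly.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Case-insensitive keywords marking a gene as an integrase/recombinase.
INTEGRASE_KEYWORDS = ("integrase", "recombinase", "phage_integrase")
#: Case-insensitive keywords marking a gene as a tRNA.
TRNA_KEYWORDS = ("trna",)
#: Keywords marking replication-initiation genes (rolling-circle endonucleases).
REPLICATION_KEYWORDS = ("rcr", "replication initiation", "rep_", "replication")


class GenomeIOError(ValueError):
    """Raised for malformed annotation input (e.g. gene outside its contig)."""


@dataclass(frozen=True)
class GeneRecord:
    """A single annotated gene.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on
    ``contig_id``; ``translation`` may be empty for untranslated features
    (tRNAs, genes whose annotation carried no protein sequence), in which
    case ``untranslated`` is set.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    translation: str = ""
    annotation_labels: frozenset[str] = frozenset()
    is_trna: bool = False
    is_integrase: bool = False
    untranslated: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeIOError(
                f"gene {self.gene_id!r}: invalid span ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeIOError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_hypothetical(self) -> bool:
        """A gene with no functional label is treated as hypothetical."""
        return len(self.annotation_labels) == 0


@dataclass
class AnnotatedGenome:
    """Contig sequences plus per-contig, start-sorted gene lists."""

    contigs: dict[str, str]
    genes: dict[str, list[GeneRecord]]
    topology: dict[str, str] = field(default_factory=dict)
    source_class: str = "isolate_genome"
    genome_id: str = "genome"

    def __post_init__(self) -> None:
        for cid in self.contigs:
            self.genes.setdefault(cid, [])
            self.topology.setdefault(cid, "linear")
        for cid, recs in self.genes.items():
            if cid not in self.contigs:
                raise GenomeIOError(f"genes reference unknown contig {cid!r}")
            clen = len(self.contigs[cid])
            for g in recs:
                if g.end > clen:
                    raise GenomeIOError(
                        f"gene {g.gene_id!r} extends past end of contig {cid!r} "
                        f"({g.end} > {clen})"
                    )
            recs.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def contig_genes(self, contig_id: str) -> list[GeneRecord]:
        return self.genes.get(contig_id, [])

    def all_genes(self) -> Iterable[GeneRecord]:
        for cid in sorted(self.genes):
            yield from self.genes[cid]

    def proteins(self) -> dict[str, str]:
        """gene_id -> translation for every translated gene."""
        return {
            g.gene_id: g.translation
            for g in self.all_genes()
            if g.translation and not g.untranslated
        }


def _labels_from_text(text: str) -> frozenset[str]:
    return frozenset(l.strip() for l in text.split(";") if l.strip())


def _flag(labels: Iterable[str], keywords: Sequence[str]) -> bool:
    lowered = [l.lower() for l in labels]
    return any(any(k in l for l in lowered) for k in keywords)


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        if "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _genes_from_gff3(path: Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeIOError(f"{path}: malformed GFF3 line: {line[:80]!r}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            a = _parse_gff3_attributes(attrs)
            # labels inside a product value are comma-joined (';' separates
            # GFF3 attributes and cannot appear in values)
            labels = {l.strip() for l in a.get("product", "").split(",") if l.strip()}
            if ftype.lower() == "trna":
                labels.add("tRNA")
            rows.append(
                dict(
                    gene_id=a.get("ID", f"{contig}:{start}-{end}"),
                    contig_id=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    translation=a.get("translation", ""),
                    labels=frozenset(labels),
                )
            )
    return rows


def _genes_from_table(path: Path) -> list[dict]:
    """Tab-separated gene table: gene_id, contig, start, end, strand,
    labels (';'-joined, may be empty), translation.  Coordinates 1-based
    inclusive, matching the GFF3 dialect."""
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "contig", "start", "end", "strand"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise GenomeIOError(f"{path}: missing required columns {sorted(required)}")
        for rec in reader:
            rows.append(
                dict(
                    gene_id=rec["gene_id"],
                    contig_id=rec["contig"],
                    start=int(rec["start"]) - 1,
                    end=int(rec["end"]),
                    strand=rec["strand"],
                    translation=rec.get("translation", "") or "",
                    labels=_labels_from_text(rec.get("labels", "") or ""),
                )
            )
    return rows


def load_annotated_genome(
    sequence_file: str | Path,
    annotation_file: str | Path,
    source_class: str = "isolate_genome",
    topology: Mapping[str, str] | None = None,
    integrase_keywords: Sequence[str] = INTEGRASE_KEYWORDS,
    trna_keywords: Sequence[str] = TRNA_KEYWORDS,
) -> AnnotatedGenome:
    """Load a nucleotide FASTA plus a GFF3 or tabular gene file.

    tRNA/integrase flags are derived from case-insensitive keyword matches
    against the annotation labels (the keyword lists are configurable).
    Genes without a translation are kept and flagged ``untranslated``; a gene
    whose span exceeds its contig is a hard error naming the gene.
    """
    sequence_file, annotation_file = Path(sequence_file), Path(annotation_file)
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(sequence_file, "fasta")}
    if not contigs:
        raise GenomeIOError(f"no sequences parsed from {sequence_file}")

    if annotation_file.suffix.lower() in (".gff", ".gff3"):
        raw = _genes_from_gff3(annotation_file)
    else:
        raw = _genes_from_table(annotation_file)

    genes: dict[str, list[GeneRecord]] = {cid: [] for cid in contigs}
    for row in raw:
        cid = row["contig_id"]
        if cid not in contigs:
            raise GenomeIOError(f"gene {row['gene_id']!r} references unknown contig {cid!r}")
        labels = row["labels"]
        rec = GeneRecord(
            gene_id=row["gene_id"],
            contig_id=cid,
            start=row["start"],
            end=row["end"],
            strand=row["strand"],
            translation=row["translation"],
            annotation_labels=labels,
            is_trna=_flag(labels, trna_keywords),
            is_integrase=_flag(labels, integrase_keywords),
            untranslated=not row["translation"],
        )
        genes[cid].append(rec)

    return AnnotatedGenome(
        contigs=contigs,
        genes=genes,
        topology=dict(topology or {}),
        source_class=source_class,
        genome_id=sequence_file.stem,
    )


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write a genome back out as FASTA + GFF3 (1-based inclusive)."""
    with open(fasta_path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in genome.contigs:
            for g in genome.contig_genes(cid):
                ftype = "tRNA" if g.is_trna else "CDS"
                attrs = [f"ID={g.gene_id}"]
                if g.annotation_labels:
                    attrs.append("product=" + ",".join(sorted(g.annotation_labels)))
                if g.translation:
                    attrs.append(f"translation={g.translation}")
                fh.write(
                    f"{cid}\tinoviscope\t{ftype}\t{g.start + 1}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t" + ";".join(attrs) + "\n"
                )


# ---------------------------------------------------------------------------
# Prediction report I/O

_PRED_COLUMNS = [
    "prediction_id",
    "contig_id",
    "start",
    "end",
    "pi_gene_id",
    "window_score",
    "completeness",
    "att_repeat_seq",
    "att_left_start",
    "att_left_end",
    "att_right_start",
    "att_right_end",
    "att_context",
    "tandem",
]


def write_predictions(predictions: Sequence, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write predictions as ``<prefix>.gff`` + ``<prefix>.tsv``.

    The GFF3 uses 1-based inclusive coordinates; the TSV keeps the full
    record (completeness class, window score, att coordinates) and
    round-trips losslessly through :func:`read_predictions`.
    """
    out_prefix = Path(out_prefix)
    gff_path = out_prefix.with_suffix(".gff")
    tsv_path = out_prefix.with_suffix(".tsv")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in predictions:
            fh.write(
                f"{p.contig_id}\tinoviscope\tprovirus\t{p.span[0] + 1}\t{p.span[1]}\t"
                f"{p.window_score:.4f}\t+\t.\tID={p.prediction_id};completeness={p.completeness}\n"
            )
    with open(tsv_path, "w") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_PRED_COLUMNS)
        for p in predictions:
            att = p.att
            writer.writerow(
                [
                    p.prediction_id,
                    p.contig_id,
                    p.span[0] + 1,
                    p.span[1],
                    p.pi_gene_id,
                    repr(p.window_score),
                    p.completeness,
                    att.repeat_seq if att else "",
                    att.left_span[0] + 1 if att else "",
                    att.left_span[1] if att else "",
                    att.right_span[0] + 1 if att else "",
                    att.right_span[1] if att else "",
                    att.context if att else "",
                    int(p.tandem),
                ]
            )
    return gff_path, tsv_path


def read_predictions(tsv_path: str | Path) -> list:
    """Read a prediction TSV written by :func:`write_predictions`."""
    from .detection import AttSite, InovirusPrediction

    out = []
    with open(tsv_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for rec in reader:
            att = None
            if rec["att_repeat_seq"]:
                att = AttSite(
                    repeat_seq=rec["att_repeat_seq"],
                    left_span=(int(rec["att_left_start"]) - 1, int(rec["att_left_end"])),
                    right_span=(int(rec["att_right_start"]) - 1, int(rec["att_right_end"])),
                    context=rec["att_context"],
                )
            out.append(
                InovirusPrediction(
                    prediction_id=rec["prediction_id"],
                    contig_id=rec["contig_id"],
                    span=(int(rec["start"]) - 1, int(rec["end"])),
                    pi_gene_id=rec["pi_gene_id"],
                    window_score=float(rec["window_score"]),
                    completeness=rec["completeness"],
                    att=att,
                    tandem=bool(int(rec["tandem"])),
                )
            )
    return out
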