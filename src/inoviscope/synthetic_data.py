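"""Synthetic annotated genomes with planted inovirus proviruses.

The generator emulates the genomic signature that the detector exploits:
an integrated inovirus cassette of 6-12 short genes (median ~300 nt,
versus ~900 nt for the host background), mostly unannotated, on one
strand, tightly packed, carrying >= 2 short structural candidates
(30-90 aa with a planted transmembrane run), exactly one pI-like gene
embedding the seed marker motif, usually a rolling-circle replication
gene, and flanked by exact direct repeats (the att site) optionally
inside a tRNA or together with an integrase.  Hard-negative confounder
cassettes (plasmid-like and terminase-bearing Caudovirales-like) share
the short-gene/unannotated signature but lack the pI motif and the
structural-candidate enrichment.

Everything is reproducible from the config seed, and every planted
element is returned as ground truth so detector output can be scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import AnnotatedGenome, GeneRecord
from .marker_search import AMINO_ACIDS, MarkerModel
from .protein_features import is_candidate_structural

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Seed marker models

#: Walker-A-flavoured consensus used as the synthetic pI (morphogenesis
#: ATPase) marker motif.
PI_CONSENSUS = "GLDLVSGPTGSGKSTLLRELAKRLAEEQGY"

#: Four terminase-like consensus motifs (synthetic stand-ins for the
#: terminase_1/3/6/GpA marker profiles used for Caudovirales co-infection).
TERMINASE_CONSENSUSES = {
    "terminase_1": "MRLEPKQREFLIGLAKGLSGGGKSELAARM",
    "terminase_3": "MRLEPKQREFLWGLAKGMSGGGKSELAARM",
    "terminase_6": "MRFEPKQRELLIGVAKGLSGGGKTELAARM",
    "terminase_GpA": "MRLDPKQREFLIGLAKGLTGGGKSEIAARM",
}


def consensus_pssm(
    consensus: str,
    model_id: str,
    match: float = 3.0,
    mismatch: float = -1.0,
    origin: str = "seed",
) -> MarkerModel:
    """Log-odds matrix scoring ``match`` for the consensus residue and
    ``mismatch`` elsewhere; a perfect consensus hit scores 3 x length."""
    cols = np.full((len(consensus), 20), mismatch, dtype=float)
    for i, aa in enumerate(consensus):
        cols[i, AMINO_ACIDS.index(aa)] = match
    return MarkerModel(model_id=model_id, columns=cols, origin=origin)


def seed_pi_model() -> MarkerModel:
    return consensus_pssm(PI_CONSENSUS, "pI_seed")


def terminase_models() -> list[MarkerModel]:
    return [consensus_pssm(c, name) for name, c in TERMINASE_CONSENSUSES.items()]


# ---------------------------------------------------------------------------
# Config / ground truth types


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark."""

    seed: int = 42
    n_genomes: int = 50
    n_inovirus: int = 25
    n_plasmid_confounders: int = 13
    n_caudovirales_confounders: int = 12
    # host background
    host_genes_per_genome: tuple[int, int] = (7, 11)
    host_gene_median_nt: int = 900
    host_gene_sigma: float = 0.35
    host_gap_range: tuple[int, int] = (40, 200)
    host_frac_annotated: float = 0.75
    # inovirus cassette
    cassette_genes: tuple[int, int] = (6, 12)
    cassette_gene_median_nt: int = 300
    min_structural: int = 2
    rcr_gene_prob: float = 0.8
    pi_motif_mutations: int = 2
    cassette_gap_range: tuple[int, int] = (5, 40)
    att_repeat_len: int = 14
    frac_circular: float = 0.0
    frac_trna_context: float = 0.4
    frac_integrase_context: float = 0.3
    # species structure for planted inoviruses
    n_inovirus_species: int | None = None
    substitution_rate: float = 0.02
    # spacers
    spacers_per_inovirus: int = 2
    spacer_length: int = 32
    spacer_mutation_proportions: tuple[float, float, float] = (0.5, 0.3, 0.2)

    def __post_init__(self) -> None:
        if not (
            self.n_inovirus + self.n_plasmid_confounders + self.n_caudovirales_confounders
            <= self.n_genomes
        ):
            raise ValueError("more planted elements than genomes")
        if not 0 <= self.frac_circular <= 1:
            raise ValueError("frac_circular must be in [0,1]")
        if abs(sum(self.spacer_mutation_proportions) - 1.0) > 1e-9:
            raise ValueError("spacer mutation proportions must sum to 1")


@dataclass(frozen=True)
class PlantedElement:
    genome_id: str
    contig_id: str
    label: str  # inovirus | plasmid_confounder | caudovirales_confounder
    span: tuple[int, int]  # att-to-att (or cassette) nucleotide span
    gene_index_span: tuple[int, int]  # cassette gene indices in the contig
    att_left: tuple[int, int] | None = None
    att_right: tuple[int, int] | None = None
    att_context: str | None = None
    species_id: str | None = None
    pi_gene_id: str | None = None


@dataclass
class GroundTruth:
    elements: list[PlantedElement]
    spacers: dict[str, str] = field(default_factory=dict)  # spacer_id -> sequence
    spacer_source: dict[str, str] = field(default_factory=dict)  # spacer_id -> genome_id
    spacer_mismatches: dict[str, int] = field(default_factory=dict)

    def by_label(self, label: str) -> list[PlantedElement]:
        return [e for e in self.elements if e.label == label]


# ---------------------------------------------------------------------------
# Sequence-level helpers

_BASES = "ACGT"

_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_STOPS = ("TAA", "TAG", "TGA")

_GENETIC_CODE = {c: aa for aa, cs in _CODONS.items() for c in cs}
for _s in _STOPS:
    _GENETIC_CODE[_s] = "*"

#: Host-like amino-acid sampling pool, hydrophobics mildly depleted so that
#: spurious transmembrane calls in background proteins stay rare.
_HOST_AA_POOL = "ACDEFGHIKLMNPQRSTVWY" + "DENQSTKRG" * 2

_HYDROPHOBIC_POOL = "LAIVF"
_HYDROPHILIC_POOL = "DENQST"  # no K/R: keeps the signal-peptide rule silent


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(_BASES), size=n))


def random_protein(rng: np.random.Generator, n_aa: int, pool: str = _HOST_AA_POOL) -> str:
    return "M" + "".join(rng.choice(list(pool), size=n_aa - 1))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Random synonymous codons plus a stop codon."""
    codons = [_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein]
    codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def translate_cds(cds: str) -> str:
    aas = []
    for i in range(0, len(cds) - 2, 3):
        aa = _GENETIC_CODE.get(cds[i : i + 3], "X")
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute exactly round(divergence * len) distinct positions, always
    to a different base, so the realized divergence equals the request."""
    n_sub = int(round(divergence * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in _BASES if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return "".join(out)


def structural_candidate_protein(rng: np.random.Generator) -> str:
    """A 40-80 aa protein with one planted transmembrane run.

    Layout: Met + hydrophilic head + 21 hydrophobic residues + hydrophilic
    tail; passes :func:`is_candidate_structural` by construction (asserted).
    """
    total = int(rng.integers(40, 81))
    head = int(rng.integers(5, 12))
    tmd = 21
    tail = total - 1 - head - tmd
    prot = (
        "M"
        + "".join(rng.choice(list(_HYDROPHILIC_POOL), size=head))
        + "".join(rng.choice(list(_HYDROPHOBIC_POOL), size=tmd))
        + "".join(rng.choice(list(_HYDROPHILIC_POOL), size=max(3, tail)))
    )
    assert is_candidate_structural(prot), "generator produced a non-candidate"
    return prot


def pi_protein(rng: np.random.Generator, n_mutations: int = 2) -> str:
    """A pI-like protein: embedded (mutated) marker motif + C-terminal TMD."""
    motif = list(PI_CONSENSUS)
    if n_mutations:
        pos = rng.choice(len(motif), size=n_mutations, replace=False)
        for p in pos:
            choices = [a for a in AMINO_ACIDS if a != motif[p]]
            motif[p] = choices[rng.integers(19)]
    head = "".join(rng.choice(list(_HYDROPHILIC_POOL), size=int(rng.integers(25, 40))))
    linker = "".join(rng.choice(list(_HYDROPHILIC_POOL), size=int(rng.integers(15, 25))))
    tmd = "".join(rng.choice(list(_HYDROPHOBIC_POOL), size=21))
    return "M" + head + "".join(motif) + linker + tmd + "DEN"


# ---------------------------------------------------------------------------
# Gene-plan assembly

_HOST_LABELS = (
    "ABC transporter", "DNA polymerase III subunit", "ribosomal protein",
    "two-component sensor kinase", "aminotransferase", "cell division protein",
    "elongation factor", "oxidoreductase", "peptidase", "glycosyltransferase",
)
_CAUDO_LABELS = ("phage capsid protein", "portal protein", "tail fiber protein")


@dataclass
class _GenePlan:
    protein: str
    label: str | None = None
    role: str = "host"  # host|pi|structural|rcr|integrase|filler|terminase
    trna: bool = False
    trna_len: int = 0
    cds: str | None = None  # fixed codon choice (species templates only)
    gap_before: str | None = None  # fixed intergenic gap (templates only)


def _host_gene(rng: np.random.Generator, cfg: SimulationConfig) -> _GenePlan:
    n_nt = int(rng.lognormal(np.log(cfg.host_gene_median_nt), cfg.host_gene_sigma))
    n_aa = max(60, n_nt // 3)
    label = (
        str(rng.choice(_HOST_LABELS)) if rng.random() < cfg.host_frac_annotated else None
    )
    return _GenePlan(protein=random_protein(rng, n_aa), label=label)


def _cassette_plan(rng: np.random.Generator, cfg: SimulationConfig, kind: str) -> list[_GenePlan]:
    """Gene plan for one planted cassette (inovirus or confounder)."""
    n_genes = int(rng.integers(cfg.cassette_genes[0], cfg.cassette_genes[1] + 1))
    plans: list[_GenePlan] = []
    if kind == "inovirus":
        plans.append(_GenePlan(protein=pi_protein(rng, cfg.pi_motif_mutations), role="pi"))
        for _ in range(cfg.min_structural):
            plans.append(_GenePlan(protein=structural_candidate_protein(rng), role="structural"))
        if rng.random() < cfg.rcr_gene_prob:
            plans.append(
                _GenePlan(
                    protein=random_protein(rng, int(rng.integers(90, 130))),
                    label="RCR replication initiation protein",
                    role="rcr",
                )
            )
    elif kind == "caudovirales_confounder":
        consensus = list(TERMINASE_CONSENSUSES.values())[int(rng.integers(4))]
        plans.append(
            _GenePlan(
                protein="M" + "".join(rng.choice(list(_HYDROPHILIC_POOL), size=20))
                + consensus
                + "".join(rng.choice(list(_HYDROPHILIC_POOL), size=30)),
                label="terminase large subunit",
                role="terminase",
            )
        )
        for lbl in rng.choice(_CAUDO_LABELS, size=2, replace=False):
            plans.append(
                _GenePlan(
                    protein=random_protein(rng, int(rng.integers(100, 220))),
                    label=str(lbl),
                    role="filler",
                )
            )
    elif kind == "plasmid_confounder":
        plans.append(
            _GenePlan(
                protein=random_protein(rng, int(rng.integers(90, 130))),
                label="RepA replication protein",
                role="filler",
            )
        )
    else:
        raise ValueError(f"unknown cassette kind {kind!r}")
    while len(plans) < n_genes:
        n_nt = int(rng.lognormal(np.log(cfg.cassette_gene_median_nt), 0.3))
        n_aa = max(35, n_nt // 3)
        plans.append(_GenePlan(protein=random_protein(rng, n_aa), role="filler"))
    order = rng.permutation(len(plans))
    return [plans[i] for i in order]


def _assemble_contig(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    contig_id: str,
    cassette: list[_GenePlan] | None,
    kind: str | None,
    circular: bool,
) -> tuple[str, list[GeneRecord], dict]:
    """Lay host genes and an optional cassette onto one contig.

    Returns (sequence, gene records, info) where info carries the cassette
    nucleotide span, gene-index span, att spans and context.
    """
    parts: list[str] = []
    genes: list[tuple[int, int, str, _GenePlan]] = []  # start,end,strand,plan
    pos = 0
    info: dict = {}

    def emit_gene(plan: _GenePlan, strand: str) -> None:
        nonlocal pos
        if plan.trna:
            seq = random_dna(rng, plan.trna_len)
        else:
            cds = plan.cds or back_translate(plan.protein, rng)
            seq = cds if strand == "+" else reverse_complement(cds)
        parts.append(seq)
        genes.append((pos, pos + len(seq), strand, plan))
        pos += len(seq)

    def emit_gap(lo: int, hi: int) -> None:
        nonlocal pos
        gap = random_dna(rng, int(rng.integers(lo, hi)))
        parts.append(gap)
        pos += len(gap)

    n_host = int(rng.integers(cfg.host_genes_per_genome[0], cfg.host_genes_per_genome[1] + 1))
    if circular and cassette is not None:
        # a free circular inovirus contig: the cassette is the whole contig
        strand = "+"
        emit_gap(*cfg.cassette_gap_range)
        first = len(genes)
        for plan in cassette:
            emit_gene(plan, strand)
            emit_gap(*cfg.cassette_gap_range)
        info.update(
            span=(0, None),  # patched to contig length below
            gene_index_span=(first, len(genes) - 1),
            att_left=None, att_right=None, att_context=None,
        )
        seq = "".join(parts)
        info["span"] = (0, len(seq))
        recs = _to_records(contig_id, genes)
        info["pi_gene_index"] = next(
            (i for i, (_, _, _, p) in enumerate(genes) if p.role == "pi"), None
        )
        return seq, recs, info

    insert_after = int(rng.integers(1, n_host)) if cassette is not None else -1
    strand = "+"
    for h in range(n_host):
        if rng.random() < 0.35:
            strand = "+" if strand == "-" else "-"
        emit_gap(*cfg.host_gap_range)
        emit_gene(_host_gene(rng, cfg), strand)
        if h == insert_after and cassette is not None:
            emit_gap(*cfg.host_gap_range)
            _insert_cassette(rng, cfg, parts, genes, cassette, kind, info)
            pos = sum(len(p) for p in parts)
    emit_gap(*cfg.host_gap_range)
    seq = "".join(parts)
    recs = _to_records(contig_id, genes)
    info["pi_gene_index"] = next(
        (i for i, (_, _, _, p) in enumerate(genes) if p.role == "pi"), None
    )
    return seq, recs, info


def _insert_cassette(rng, cfg, parts, genes, cassette, kind, info) -> None:
    """Append [tRNA?] att_left, cassette genes, att_right to the layout."""
    pos = sum(len(p) for p in parts)
    has_att = kind == "inovirus"
    context = None
    repeat = random_dna(rng, cfg.att_repeat_len) if has_att else ""
    if has_att:
        u = rng.random()
        if u < cfg.frac_trna_context:
            context = "tRNA"
        elif u < cfg.frac_trna_context + cfg.frac_integrase_context:
            context = "integrase"
        else:
            context = "plain"
    att_left = att_right = None
    if has_att:
        if context == "tRNA":
            # tRNA gene whose 3' end is the att repeat
            body = random_dna(rng, 62)
            parts.append(body + repeat)
            trna_plan = _GenePlan(protein="", label="tRNA-Leu", trna=True, trna_len=76)
            genes.append((pos, pos + 76, "+", trna_plan))
            att_left = (pos + 62, pos + 76)
            pos += 76
        else:
            parts.append(repeat)
            att_left = (pos, pos + cfg.att_repeat_len)
            pos += cfg.att_repeat_len
    first_gene_idx = len(genes)
    plans = list(cassette)
    if context == "integrase":
        plans.insert(
            0,
            _GenePlan(
                protein=random_protein(rng, int(rng.integers(100, 140))),
                label="tyrosine integrase",
                role="integrase",
            ),
        )
    for plan in plans:
        gap = plan.gap_before or random_dna(rng, int(rng.integers(*cfg.cassette_gap_range)))
        parts.append(gap)
        pos += len(gap)
        cds = plan.cds or back_translate(plan.protein, rng)
        parts.append(cds)
        genes.append((pos, pos + len(cds), "+", plan))
        pos += len(cds)
    if has_att:
        gap = random_dna(rng, int(rng.integers(*cfg.cassette_gap_range)))
        parts.append(gap)
        pos += len(gap)
        parts.append(repeat)
        att_right = (pos, pos + cfg.att_repeat_len)
        pos += cfg.att_repeat_len
    info.update(
        gene_index_span=(first_gene_idx, len(genes) - 1),
        att_left=att_left,
        att_right=att_right,
        att_context=context,
        repeat=repeat,
    )


def _to_records(contig_id: str, genes) -> list[GeneRecord]:
    recs = []
    for idx, (start, end, strand, plan) in enumerate(genes):
        labels = frozenset([plan.label]) if plan.label else frozenset()
        recs.append(
            GeneRecord(
                gene_id=f"{contig_id}_{idx:03d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=strand,
                translation=plan.protein,
                annotation_labels=labels,
                is_trna=plan.trna,
                is_integrase=plan.role == "integrase",
                untranslated=not plan.protein,
            )
        )
    return recs


# ---------------------------------------------------------------------------
# Fixture generation


def generate_fixture(
    config: SimulationConfig,
) -> tuple[dict[str, AnnotatedGenome], GroundTruth]:
    """Generate the synthetic benchmark: genomes, ground truth, spacers.

    Byte-reproducible for a given config; planted att repeats are asserted
    unique within their contig (regenerated otherwise), planted structural
    genes pass candidacy by construction, and spacers are sampled from the
    planted proviruses with 0-2 substitutions at the configured
    proportions.
    """
    cfg = config
    master = np.random.default_rng(cfg.seed)
    kinds: list[str | None] = (
        ["inovirus"] * cfg.n_inovirus
        + ["plasmid_confounder"] * cfg.n_plasmid_confounders
        + ["caudovirales_confounder"] * cfg.n_caudovirales_confounders
    )
    kinds += [None] * (cfg.n_genomes - len(kinds))
    master.shuffle(kinds)  # type: ignore[arg-type]

    # species templates for planted inoviruses: codon choices fixed per
    # template so that instances diverge only by the applied substitutions
    templates: list[list[_GenePlan]] | None = None
    if cfg.n_inovirus_species is not None:
        t_rng = np.random.default_rng([cfg.seed, 10_007])
        templates = []
        for _ in range(cfg.n_inovirus_species):
            plans = _cassette_plan(t_rng, cfg, "inovirus")
            templates.append(
                [
                    replace(
                        p,
                        cds=back_translate(p.protein, t_rng),
                        gap_before=random_dna(
                            t_rng, int(t_rng.integers(*cfg.cassette_gap_range))
                        ),
                    )
                    for p in plans
                ]
            )

    genomes: dict[str, AnnotatedGenome] = {}
    elements: list[PlantedElement] = []
    truth = GroundTruth(elements=elements)
    ino_counter = 0
    for gi, kind in enumerate(kinds):
        genome_id = f"g{gi:03d}"
        contig_id = f"{genome_id}_c0"
        rng = np.random.default_rng([cfg.seed, gi])
        cassette = None
        species_id = None
        circular = False
        if kind == "inovirus":
            if templates is not None:
                t = ino_counter % len(templates)
                first_instance = ino_counter < len(templates)
                cassette = (
                    templates[t]
                    if first_instance
                    else [_diverge_plan(p, cfg.substitution_rate, rng) for p in templates[t]]
                )
                species_id = f"isp_{t:03d}"
            else:
                cassette = _cassette_plan(rng, cfg, kind)
                species_id = f"isp_{ino_counter:03d}"
            circular = rng.random() < cfg.frac_circular
            ino_counter += 1
        elif kind is not None:
            cassette = _cassette_plan(rng, cfg, kind)

        for _attempt in range(50):
            seq, recs, info = _assemble_contig(rng, cfg, contig_id, cassette, kind, circular)
            if kind != "inovirus" or circular:
                break
            if seq.count(info["repeat"]) == 2 and _att_copies_maximal(seq, info):
                break
        else:
            raise RuntimeError("could not place a unique att repeat")

        genome = AnnotatedGenome(
            contigs={contig_id: seq},
            genes={contig_id: recs},
            topology={contig_id: "circular" if circular else "linear"},
            source_class="isolate_genome",
            genome_id=genome_id,
        )
        genomes[genome_id] = genome

        if kind is not None:
            if kind == "inovirus" and not circular:
                span = (info["att_left"][0], info["att_right"][1])
            else:
                gi0, gi1 = info["gene_index_span"]
                span = (recs[gi0].start, recs[gi1].end) if recs else (0, len(seq))
                if circular:
                    span = (0, len(seq))
            pi_idx = info.get("pi_gene_index")
            pi_gene = recs[pi_idx].gene_id if pi_idx is not None else None
            elements.append(
                PlantedElement(
                    genome_id=genome_id,
                    contig_id=contig_id,
                    label=kind,
                    span=span,
                    gene_index_span=info["gene_index_span"],
                    att_left=info.get("att_left"),
                    att_right=info.get("att_right"),
                    att_context=info.get("att_context"),
                    species_id=species_id,
                    pi_gene_id=pi_gene,
                )
            )

    _sample_spacers(cfg, genomes, truth)
    return genomes, truth


def _att_copies_maximal(seq: str, info: dict) -> bool:
    """True when the planted repeat pair cannot be extended by chance, so
    the truth att coordinates are exactly a maximal direct repeat."""
    (l0, l1), (r0, r1) = info["att_left"], info["att_right"]
    if l0 > 0 and r0 > 0 and seq[l0 - 1] == seq[r0 - 1]:
        return False
    if l1 < len(seq) and r1 < len(seq) and seq[l1] == seq[r1]:
        return False
    return True


def _diverge_plan(plan: _GenePlan, rate: float, rng: np.random.Generator) -> _GenePlan:
    """Mutate a template gene's CDS at ``rate``, preserving the open frame.

    Substitutions that would create a premature stop codon are reverted to
    the template codon; the translation is re-derived from the mutated CDS.
    """
    if plan.cds is None or rate <= 0:
        return plan
    body, stop = plan.cds[:-3], plan.cds[-3:]
    mutated = list(mutate_sequence(body, rate, rng))
    for c in range(0, len(mutated) - 2, 3):
        if "".join(mutated[c : c + 3]) in _STOPS:
            mutated[c : c + 3] = body[c : c + 3]
    cds = "".join(mutated) + stop
    gap = mutate_sequence(plan.gap_before, rate, rng) if plan.gap_before else None
    return replace(plan, cds=cds, protein=translate_cds(cds), gap_before=gap)


def _sample_spacers(cfg: SimulationConfig, genomes, truth: GroundTruth) -> None:
    rng = np.random.default_rng([cfg.seed, 20_011])
    props = cfg.spacer_mutation_proportions
    for el in truth.by_label("inovirus"):
        seq = genomes[el.genome_id].contigs[el.contig_id]
        lo, hi = el.span
        if hi - lo < cfg.spacer_length + 2:
            continue
        for si in range(cfg.spacers_per_inovirus):
            start = int(rng.integers(lo, hi - cfg.spacer_length))
            spacer = seq[start : start + cfg.spacer_length]
            u = rng.random()
            n_mut = 0 if u < props[0] else (1 if u < props[0] + props[1] else 2)
            if n_mut:
                spacer = mutate_sequence(spacer, n_mut / len(spacer), rng)
            if rng.random() < 0.5:
                spacer = reverse_complement(spacer)
            sid = f"sp_{el.genome_id}_{si}"
            truth.spacers[sid] = spacer
            truth.spacer_source[sid] = el.genome_id
            truth.spacer_mismatches[sid] = n_mut


# ---------------------------------------------------------------------------
# Scoring against truth


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def score_against_truth(
    predictions: Sequence,
    truth: GroundTruth,
    prediction_genome: Mapping[str, str],
    overlap: float = 0.5,
) -> dict:
    """Prediction-level recall/precision against planted inovirus spans.

    A prediction is a true positive when it shares >= ``overlap``
    reciprocal overlap with an inovirus truth span on the same contig; each
    truth span can be matched once.  Boundary error statistics are the att
    coordinate offsets over matched pairs.  With zero predictions,
    precision is reported as 1.0 with ``zero_call`` set.
    """
    ino = truth.by_label("inovirus")
    unmatched = {(e.genome_id, e.contig_id, e.span): e for e in ino}
    tp = 0
    boundary_errors: list[int] = []
    for p in predictions:
        gid = prediction_genome.get(p.prediction_id)
        match_key = None
        for key, e in unmatched.items():
            if e.contig_id == p.contig_id and (gid is None or gid == e.genome_id):
                if reciprocal_overlap(p.span, e.span) >= overlap:
                    match_key = key
                    break
        if match_key is not None:
            e = unmatched.pop(match_key)
            tp += 1
            if p.att is not None and e.att_left is not None:
                boundary_errors.append(abs(p.att.left_span[0] - e.att_left[0]))
                boundary_errors.append(abs(p.att.right_span[1] - e.att_right[1]))
    n_pred = len(predictions)
    recall = tp / len(ino) if ino else 1.0
    precision = tp / n_pred if n_pred else 1.0
    return dict(
        recall=recall,
        precision=precision,
        n_true=len(ino),
        n_predicted=n_pred,
        n_matched=tp,
        zero_call=n_pred == 0,
        boundary_error_mean=float(np.mean(boundary_errors)) if boundary_errors else 0.0,
        boundary_error_max=int(max(boundary_errors)) if boundary_errors else 0,
    )


# ---------------------------------------------------------------------------
# File output


def write_fixture(
    genomes: Mapping[str, AnnotatedGenome],
    truth: GroundTruth,
    outdir: str | Path,
) -> Path:
    """Write the fixture in the dialects the loaders read: per-genome FASTA
    and GFF3, a spacer FASTA and the ground truth as BED + TSV."""
    from .genome_io import write_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gid, genome in genomes.items():
        write_genome(genome, outdir / f"{gid}.fna", outdir / f"{gid}.gff")
    with open(outdir / "spacers.fasta", "w") as fh:
        for sid, seq in truth.spacers.items():
            fh.write(f">{sid}\n{seq}\n")
    with open(outdir / "truth.bed", "w") as fh:
        for e in truth.elements:
            fh.write(f"{e.contig_id}\t{e.span[0]}\t{e.span[1]}\t{e.label}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "genome_id\tcontig_id\tlabel\tstart\tend\tatt_context\tspecies_id\tpi_gene_id\n"
        )
        for e in truth.elements:
            fh.write(
                f"{e.genome_id}\t{e.contig_id}\t{e.label}\t{e.span[0] + 1}\t{e.span[1]}\t"
                f"{e.att_context or ''}\t{e.species_id or ''}\t{e.pi_gene_id or ''}\n"
            )
    return outdir
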