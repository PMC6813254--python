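# Methods

## Detection model

`inoviscope` treats inovirus discovery as marker-anchored genome-context
classification. The anchor is the morphogenesis ATPase (pI), the only
gene conserved across all known inoviruses; everything else about these
genomes — short genes, sparse annotation, compact spacing, a couple of
tiny single-TMD structural proteins, often a rolling-circle replication
initiator — is statistical signal, which a classifier can exploit but no
single gene search can.

### Marker engine

The default engine scores proteins against a position-specific scoring
matrix (PSSM) by taking the maximum over all ungapped placements of the
summed per-column log-odds. When a protein is shorter than the model the
protein slides within the model instead, so refined models built from
long representatives can still score shorter family members. This engine
is deliberately not a profile HMM: it has no insert/delete states and
its bit scores are not comparable to hmmer's. It exists so the pipeline
is fully exercisable without profile databases; `hmmsearch --tblout`
output can be parsed into the same `MarkerHit` records and flows through
the identical filter (bit ≥ 30 and E ≤ 0.001 for profiles, bit ≥ 50 for
single-sequence markers). E-values for the built-in engine use the
calibration E = N·2^(−bits), which is the plain bit-score identity; it
is overridable because any serious use should calibrate against a decoy
set.

Marker model refinement clusters validated pI proteins at 90% identity
(greedy, longest first, identity measured globally over the shorter
sequence — cd-hit's convention), then builds a new PSSM from a star
alignment of the cluster representatives to the longest one, with
pseudocount 1.0 against a uniform background. The refinement loop
mirrors iterative profile improvement: search, validate, rebuild,
repeat.

### Protein features

TMDs are maximal unions of 19-residue windows with mean Kyte–Doolittle
hydropathy ≥ 1.6. Signal peptides use a tripartite rule: a basic
N-region residue, a ≥ 7-residue strongly hydrophobic stretch (L/I/V/F/M/
W/C) ending before position 35, cleavage after the first following
small residue (A/G/S). Both are heuristics standing in for dedicated
predictors (which are license-restricted); the pipeline only consumes
span counts and positions, and parsers for TMHMM/SignalP output are
provided. TMDs are counted after in-silico signal-peptide removal. A
structural candidate is a mature protein of 30–90 aa with 1 or 2 TMDs;
the stricter single-TMD variant is a parameter
(`allowed_tmd_counts=(1,)`).

### Window classifier

Each candidate window (every gene interval of ≤ 30 genes containing the
pI gene, truncated at contig ends) is summarized by ten features:

| feature | meaning |
|---|---|
| gene density | genes per kb of window span |
| median gene length | nt |
| fraction short genes | length < 300 nt |
| fraction unannotated | empty label set |
| structural candidates | count of 30–90 aa, 1–2 TMD proteins |
| known-PC fraction | genes hitting known inovirus protein clusters |
| mean intergenic gap | bp, floored at 0 |
| strand coherence | modal-strand fraction |
| replication gene | RCR/replication-initiation label present (0/1) |
| window size | genes / 30 |

The classifier is a random forest of 2,000 trees (scikit-learn, other
parameters default); the score of a window is the fraction of trees
voting "inovirus", so it lies in [0, 1] and the acceptance cutoff is a
strict 0.9. A logistic-regression baseline sits behind the same
interface. Feature extraction is table-driven so the feature set can be
swapped without touching the classifier.

Training windows come from a fixture with ground truth: positives are
the exact planted cassettes; negatives are confounder cassettes, random
host-background windows, and cassettes over-extended into the host by
2–3 genes (these teach tight boundaries). Partial sub-windows of
cassettes are deliberately *not* negatives: they share the positives'
density and length profile, and labeling them negative teaches the
forest to reject legitimately extreme cassettes. Because each cassette
yields one positive but several negatives, positives are replicated to
balance the classes; without this the vote fraction is dragged toward
the majority class and the 0.9 cutoff becomes unreachable for windows
the forest actually recognizes. The shipped training conditions are 160
genomes with 100 planted inoviruses and 60 confounders.

Window enumeration treats "up to 30 genes around pI" as intervals of
total size ≤ 30 containing the pI gene; ties in score break to the
smallest interval, then the leftmost — every tie-break is explicit so
runs are reproducible.

### att sites and completeness

Boundaries are sought as maximal exact direct repeats ≥ 10 bp with one
copy in each flank (default search distance 20 kb each side, truncated
at contig ends), found by seed-and-extend and verified in tests against
a quadratic oracle. Context classification: a copy overlapping a tRNA
gene → `tRNA`; an integrase gene inside the enclosed region with neither
copy inside it → `non_integrase`; otherwise `plain`. Repeats are ranked
by length (desc), then total distance to the candidate span. Since the
classifier window can overshoot the provirus by an edge gene — hiding
the att copy inside the span — the pipeline retries the repeat search on
one-gene-shrunk spans when no canonical-context repeat is found.
Completeness: whole circular contigs (topology metadata, or an exact
terminal repeat ≥ 20 bp when metadata is absent) are `circular`;
tRNA/integrase-context repeats give `canonical_att`; plain repeats
`noncanonical_att`; nothing → `fuzzy`. Regions with ≥ 2 pI genes are
flagged tandem and kept out of gene-content taxonomy and regular species
pools.

## Species clustering

ANI is computed by chaining shared 15-mers co-linearly (longest
increasing subsequence), extending the chained region at both ends with
an ungapped X-drop rule (+1 match, −2 mismatch, drop 20), and taking
identity from a global edit-distance alignment of the block; AF is the
aligned fraction of the shorter sequence. The X-drop extension matters:
extending unconditionally to the sequence ends would let a single
spurious shared 15-mer between unrelated sequences claim a near-full
alignment fraction. Species demarcation is 95% ANI at AF = 1.0, with AF
≥ 0.999 accepted to absorb edge-trimming artifacts. Clustering is
greedy and seeded in tiers (1: circular/canonical-att genome-derived,
2: noncanonical-att genome-derived, 3: other genome-derived,
4: metagenome-derived), longest sequence first within a tier, so the
most reliable predictions are always the representatives. Host
dereplication uses the same machinery at 95% identity / 95% AF.
Accumulation curves average the cumulative count of first-seen species
over 100 random orderings.

## Protein families and taxonomy

Similarity edges require E ≤ 0.001 and bit ≥ 50, or bit ≥ 30 when both
proteins are ≤ 70 aa (short structural genes cannot reach 50 bits). The
built-in pairwise aligner is Smith–Waterman with BLOSUM62 and gaps 11/1,
converted to bits with standard Karlin–Altschul parameters (λ = 0.267,
K = 0.041); production runs parse 12-column tabular output instead. PCs
are InfoMap communities of size ≥ 2 (python-igraph, seeded RNG). iPFs
merge PCs along profile–profile hits at ≥ 90% probability and ≥ 50%
coverage, or ≥ 99%, ≥ 20% and hit length ≥ 100; profile–profile
comparison itself is consumed as tabular input, never reimplemented.
The partial-sequence filter (drop sequences shorter than half the
10%-trimmed mean) is iterated to a fixpoint so it is idempotent — a
single pass is not, because removing the shortest members can raise the
trimmed mean enough to expose further partials.

The gene-content taxonomy links genomes to PCs they encode (tandem
genomes and < 2-member PCs excluded), partitions the bipartite graph
with InfoMap and re-partitions each group for subgroups. The
planted-block recovery contract, not algorithm identity, is what the
tests pin down, so the backend is pluggable. The summary graph connects
a subgroup to a PC when > 50% of its genomes encode it (> 25% for the
largest subgroup, which is computed, not hard-coded).

## Host interaction screens

Spacer matching is an exhaustive ≤ 1-mismatch Hamming scan of both
strands — for 20–60 nt queries this is strictly more sensitive than the
short-read blastn heuristic it replaces and implements the same
post-filter semantics; gaps are deliberately not allowed. A blastn
tabular parser is retained as an alternative backend. Spacer loci must
have a cas-labeled gene (configurable keyword list, default prefixes
cas/csn/csy/cmr/cst) within ±10 kb; metagenome-derived spacers without
coordinates pass with an explicit flag. Self-targeting means spacer and
targeted provirus share a host genome. Caudovirales co-infection is
flagged by terminase-model hits ≥ 30 bits, with distinct prophages
counted as hits ≥ 5 kb apart. Prevalence is computed per host genus
after dereplication, so database redundancy cannot inflate it.

## Synthetic data generator

The generator emulates the features the detector relies on, under
controlled difficulty:

- **Host background**: 7–11 genes per genome, lognormal lengths (median
  900 nt, σ = 0.35), 75% annotated, gaps 40–200 bp, strand persistence.
  The amino-acid pool is mildly depleted in hydrophobics so spurious TMD
  calls in host proteins stay rare.
- **Inovirus cassette**: 6–12 genes, median 300 nt, one pI gene carrying
  the seed PSSM consensus with 2 substitutions plus a C-terminal TMD,
  ≥ 2 structural candidates (30–90 aa with a planted 21-residue
  hydrophobic run; candidacy asserted at generation), an RCR-labeled
  gene with probability 0.8, tight gaps (5–40 bp), one strand.
- **att sites**: 14-bp exact repeats flanking the cassette; contexts
  tRNA (0.4), integrase (0.3) or plain. The generator rejects layouts
  where the repeat occurs elsewhere or could be extended by chance, so
  truth coordinates are exactly maximal repeats.
- **Confounders**: plasmid-like cassettes (short unannotated genes plus
  a RepA-labeled replication gene — deliberately sharing the
  short-gene/unannotated/replication signature) and Caudovirales-like
  cassettes (terminase-motif gene plus capsid/portal/tail labels). They
  lack pI motifs and structural-candidate enrichment.
- **Species structure**: optional templates with fixed codon and gap
  choices; instances diverge by exact-count nucleotide substitutions
  (premature stops reverted), so realized ANI equals the requested
  divergence.
- **Spacers**: 32-mers sampled from planted proviruses with 0/1/2
  substitutions at proportions 0.5/0.3/0.2, half reverse-complemented.

The benchmark conditions are 50 genomes, 25 planted proviruses and 25
confounders (13 plasmid-like, 12 Caudovirales-like). What passing tests
on this fixture show is that the pipeline's machinery is correct and
that the classifier recovers the planted signature; they do not show
field performance on real genomes, whose annotation pipelines, gene
callers, composition biases and mobile-element diversity the generator
does not attempt to model. In particular, real inovirus detection
depends on marker profiles built from curated reference proteins, which
are user-supplied here.

## Problem sizes and numerical choices

Test and acceptance runs use: classifier training on a 160-genome
fixture with 2,000 trees; oracle comparisons on 100 window landscapes,
200 2-kb flank pairs, 100 ANI pairs at 0–10% divergence, 1,000 spacer
cases; community recovery over 20 (PC) and 10 (taxonomy) seeds; the
cross-validation checks use 200 trees, since they exercise the fold
machinery and pooled-ROC bookkeeping, which are independent of ensemble
size. All randomness flows from explicit seeds; ties everywhere have
documented, deterministic resolutions. Floating-point thresholds are
applied exactly as stated (≥/≤ inclusive, window score strictly > 0.9);
the only tolerance is AF ≥ 0.999 for "100% alignment fraction".

## Known limitations

- The built-in marker engine's bit scores are not hmmer-comparable; the
  E-value calibration is nominal. Production searches should use parsed
  hmmsearch output.
- TMD/signal-peptide heuristics approximate dedicated predictors; they
  are tuned for planted signal, not benchmarked against real membrane
  proteins.
- ANI block chaining assumes mostly co-linear sequences; rearranged
  genomes would under-report AF.
- The ten context features are a reconstruction of the published
  feature idea (density, gene length, annotation sparsity, structural
  candidates, strand layout, replication genes); the exact published
  set is not public, and the extractor is table-driven so it can be
  replaced.
- Spacer matching forbids indels (Hamming, not edit distance) — a
  deliberate narrowing consistent with mismatch-count filtering.
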