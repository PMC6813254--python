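"""CRISPR spacer matching, cas context, self-targeting, co-infection."""

import numpy as np
import pytest

from inoviscope.genome_io import AnnotatedGenome, GeneRecord
from inoviscope.host_interactions import (
    compute_prevalence,
    detect_caudovirales_coinfection,
    detect_self_targeting,
    hamming_placements,
    match_spacers,
    require_cas_context,
    reverse_complement,
)
from inoviscope.marker_search import MarkerHit
from inoviscope.synthetic_data import (
    TERMINASE_CONSENSUSES,
    mutate_sequence,
    random_dna,
    terminase_models,
)


class TestMatchSpacers:
    def test_exact_forward_match(self, rng):
        target = random_dna(rng, 1000)
        spacer = target[200:232]
        (m,) = [x for x in match_spacers({"s": spacer}, {"p": target})
                if x.target_span == (200, 232)]
        assert (m.strand, m.mismatches) == ("+", 0)

    def test_single_substitution_reverse_strand(self, rng):
        target = random_dna(rng, 1000)
        proto = target[500:532]
        mutated = mutate_sequence(proto, 1 / 32, rng)
        spacer = reverse_complement(mutated)
        hits = [x for x in match_spacers({"s": spacer}, {"p": target})
                if x.target_span == (500, 532)]
        assert hits and hits[0].strand == "-" and hits[0].mismatches == 1

    def test_two_mismatches_rejected(self, rng):
        target = random_dna(rng, 1000)
        spacer = mutate_sequence(target[300:332], 2 / 32, rng)
        hits = match_spacers({"s": spacer}, {"p": target})
        assert all(m.target_span != (300, 332) for m in hits)

    def test_agrees_with_bruteforce_hamming_scan(self, rng):
        for _ in range(50):
            target = random_dna(rng, 400)
            spacer = random_dna(rng, 24)
            pos = int(rng.integers(0, 376))
            planted = mutate_sequence(target[pos : pos + 24],
                                      int(rng.integers(0, 3)) / 24, rng)
            target = target[:pos] + planted + target[pos + 24:]
            got = {(m.strand, m.target_span[0], m.mismatches)
                   for m in match_spacers({"s": spacer}, {"p": target})}
            brute = set()
            for strand, q in (("+", spacer), ("-", reverse_complement(spacer))):
                for off in range(len(target) - 24 + 1):
                    mm = sum(a != b for a, b in zip(q, target[off : off + 24]))
                    if mm <= 1:
                        brute.add((strand, off, mm))
            assert got == brute

    def test_strand_symmetry(self, rng):
        """Matching s on t yields the same placements (strand, offset
        mirrored, mismatches) as matching revcomp(s) on revcomp(t)."""
        t = random_dna(rng, 300)
        s = mutate_sequence(t[100:130], 1 / 30, rng)
        direct = {(m.mismatches, m.strand, m.target_span)
                  for m in match_spacers({"s": s}, {"p": t})}
        mirrored = {
            (m.mismatches, m.strand,
             (len(t) - m.target_span[1], len(t) - m.target_span[0]))
            for m in match_spacers({"s": reverse_complement(s)},
                                   {"p": reverse_complement(t)})
        }
        assert direct and direct == mirrored

    def test_best_flag_marks_fewest_mismatches(self, rng):
        target = random_dna(rng, 500)
        spacer = target[50:82]
        t2 = target[:400] + mutate_sequence(spacer, 1 / 32, rng) + target[432:]
        matches = match_spacers({"s": spacer}, {"p": t2})
        best = [m for m in matches if m.is_best]
        assert len(best) == 1 and best[0].mismatches == min(m.mismatches for m in matches)


def _host_genome(cas_pos=None, length=30_000):
    genes = []
    if cas_pos is not None:
        genes.append(GeneRecord("cas", "hc", cas_pos, cas_pos + 900, "+",
                                "M" + "A" * 299, frozenset({"cas3 helicase"})))
    return AnnotatedGenome(contigs={"hc": "A" * length}, genes={"hc": genes})


class TestCasContext:
    def _match(self):
        from inoviscope.host_interactions import SpacerMatch

        return SpacerMatch("sp1", "pred1", "+", 0, (0, 32))

    def test_cas_gene_8kb_away_kept(self):
        host = {"h": _host_genome(cas_pos=9000)}
        out = require_cas_context([self._match()], {"sp1": ("h", "hc", 1000)}, host)
        assert len(out) == 1 and out[0].cas_context

    def test_cas_gene_12kb_away_removed(self):
        host = {"h": _host_genome(cas_pos=13_100)}
        out = require_cas_context([self._match()], {"sp1": ("h", "hc", 1000)}, host)
        assert out == []

    def test_no_annotation_removed(self):
        host = {"h": _host_genome(cas_pos=None)}
        assert require_cas_context([self._match()], {"sp1": ("h", "hc", 1000)}, host) == []

    def test_metagenome_spacer_passes_without_flag(self):
        out = require_cas_context([self._match()], {}, {})
        assert len(out) == 1 and not out[0].cas_context


class TestSelfTargeting:
    def _matches(self):
        from inoviscope.host_interactions import SpacerMatch

        return [SpacerMatch("sp1", "pred1", "+", 0, (0, 32))]

    def test_same_genome_flags_self_targeting(self):
        out = detect_self_targeting(self._matches(), {"pred1": "h1"}, {"sp1": "h1"})
        assert out[0].self_targeting

    def test_different_genomes_not_flagged(self):
        out = detect_self_targeting(self._matches(), {"pred1": "h2"}, {"sp1": "h1"})
        assert not out[0].self_targeting

    def test_unresolved_host_flagged(self):
        out = detect_self_targeting(self._matches(), {"pred1": "h1"}, {})
        assert not out[0].self_targeting and out[0].unresolved_host


class TestCoinfection:
    @staticmethod
    def _genome_with(protein, start=1000, extra=None):
        genes = [GeneRecord("t1", "c", start, start + 3 * len(protein) + 3, "+",
                            protein, frozenset())]
        if extra is not None:
            prot2, start2 = extra
            genes.append(GeneRecord("t2", "c", start2, start2 + 3 * len(prot2) + 3,
                                    "+", prot2, frozenset()))
        return AnnotatedGenome(contigs={"c": "A" * 40_000}, genes={"c": genes})

    def test_planted_terminase_flags_genome(self):
        prot = "M" + "D" * 10 + TERMINASE_CONSENSUSES["terminase_1"] + "D" * 10
        flagged, n = detect_caudovirales_coinfection(self._genome_with(prot),
                                                    terminase_models())
        assert flagged and n == 1

    def test_score_just_below_threshold_not_flagged(self):
        genome = self._genome_with("M" + "D" * 100)
        flagged, n = detect_caudovirales_coinfection(genome, terminase_models())
        assert not flagged and n == 0

    def test_two_close_hits_count_one_prophage(self):
        prot = "M" + TERMINASE_CONSENSUSES["terminase_3"] + "D" * 5
        genome = self._genome_with(prot, start=1000, extra=(prot, 3000))
        flagged, n = detect_caudovirales_coinfection(genome, terminase_models())
        assert flagged and n == 1

    def test_two_distant_hits_count_two(self):
        prot = "M" + TERMINASE_CONSENSUSES["terminase_3"] + "D" * 5
        genome = self._genome_with(prot, start=1000, extra=(prot, 20_000))
        flagged, n = detect_caudovirales_coinfection(genome, terminase_models())
        assert flagged and n == 2


class TestPrevalence:
    def test_duplicate_genomes_counted_once(self, rng):
        g = random_dna(rng, 3000)
        hosts = {"a": g, "b": g}
        table, _ = compute_prevalence(hosts, {"a": "Vibrio", "b": "Vibrio"},
                                      {"a": ["p1"]})
        row = table[table.genus == "Vibrio"].iloc[0]
        assert row.n_genomes == 1 and row.prevalence == 1.0

    def test_genus_without_detections_has_zero_prevalence(self, rng):
        hosts = {"a": random_dna(rng, 3000)}
        table, _ = compute_prevalence(hosts, {"a": "Bacillus"}, {})
        assert table.iloc[0].prevalence == 0.0

    def test_cooccurrence_counts_distinct_species(self, rng):
        hosts = {"a": random_dna(rng, 3000)}
        _, co = compute_prevalence(
            hosts, {"a": "Vibrio"}, {"a": ["p1", "p2", "p3"]},
            prediction_species={"p1": "sp1", "p2": "sp2", "p3": "sp1"},
        )
        assert co["a"] == 2


def test_hamming_placements_handles_short_target():
    assert hamming_placements("ACGT", "AC", 1) == []
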