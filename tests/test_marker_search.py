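"""PSSM marker engine, hit filtering and pI model refinement."""

import numpy as np
import pytest

from inoviscope.marker_search import (
    AMINO_ACIDS,
    MarkerHit,
    MarkerModel,
    classify_pi_topology,
    filter_marker_hits,
    greedy_identity_clusters,
    parse_hmmsearch_tblout,
    refine_marker_models,
    scan_proteins,
    score_profile,
    validate_pi_cluster,
)
from inoviscope.protein_features import TMDSpan


class TestScoreProfile:
    def test_all_zero_model_scores_zero(self):
        model = MarkerModel("z", np.zeros((3, 20)))
        assert score_profile(model, "ACDEFG").bit_score == 0.0

    def test_single_column_model_forced_score(self):
        cols = np.zeros((1, 20))
        cols[0, AMINO_ACIDS.index("L")] = 2.0
        assert score_profile(MarkerModel("m", cols), "L").bit_score == 2.0

    def test_matches_exhaustive_placement_oracle(self, rng):
        for _ in range(20):
            length = int(rng.integers(1, 11))
            cols = rng.normal(size=(length, 20))
            model = MarkerModel("m", cols)
            protein = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(length, 51))))
            hit = score_profile(model, protein)
            brute = max(
                sum(cols[k, AMINO_ACIDS.index(protein[off + k])] for k in range(length))
                for off in range(len(protein) - length + 1)
            )
            assert hit.bit_score == pytest.approx(brute, abs=1e-9)

    def test_unknown_residue_contributes_zero_with_warning(self):
        cols = np.full((1, 20), 5.0)
        with pytest.warns(UserWarning):
            hit = score_profile(MarkerModel("m", cols), "X")
        assert hit.bit_score == 0.0

    def test_empty_protein_rejected(self):
        with pytest.raises(ValueError):
            score_profile(MarkerModel("m", np.zeros((1, 20))), "")

    def test_model_tsv_round_trip(self, tmp_path, rng):
        model = MarkerModel("m1", rng.normal(size=(7, 20)), origin="refined-round-2")
        model.to_tsv(tmp_path / "m.tsv")
        back = MarkerModel.from_tsv(tmp_path / "m.tsv")
        assert back.model_id == "m1" and back.origin == "refined-round-2"
        np.testing.assert_allclose(back.columns, model.columns, atol=1e-5)


class TestFilterMarkerHits:
    @pytest.mark.parametrize(
        "score,evalue,mode,kept",
        [
            (30.0, 0.001, "profile", True),   # both thresholds inclusive
            (29.9, 1e-10, "profile", False),  # score boundary
            (35.0, 0.002, "profile", False),  # e-value boundary
            (50.0, 0.5, "singleton", True),   # singleton ignores e-value
            (49.9, 1e-10, "singleton", False),
        ],
    )
    def test_threshold_boundaries(self, score, evalue, mode, kept):
        hit = MarkerHit("g", "m", score, evalue)
        assert (filter_marker_hits([hit], mode) == [hit]) is kept

    def test_empty_input(self):
        assert filter_marker_hits([], "profile") == []

    def test_idempotent_and_order_preserving(self, rng):
        hits = [
            MarkerHit(f"g{i}", "m", float(rng.uniform(20, 60)), float(10.0 ** -rng.uniform(0, 8)))
            for i in range(30)
        ]
        once = filter_marker_hits(hits, "profile")
        assert filter_marker_hits(once, "profile") == once
        order = [h.gene_id for h in hits]
        assert [h.gene_id for h in once] == [g for g in order if g in {h.gene_id for h in once}]


class TestRefinement:
    def test_identical_pair_gives_single_cluster_profile(self):
        model = refine_marker_models(["MACDEFGHIKL", "MACDEFGHIKL"], round_id=2)
        assert model.length == 11
        assert model.origin == "refined-round-2"
        # the model's best hit on its own training sequence is the consensus
        assert score_profile(model, "MACDEFGHIKL").bit_score > 0

    def test_divergent_sequences_split_into_two_clusters(self, rng):
        base = "".join(rng.choice(list(AMINO_ACIDS), size=100))
        near = base[:95] + "AAAAA"       # ~95% identical
        far = "".join(rng.choice(list(AMINO_ACIDS), size=100))  # ~5% identical
        clusters = greedy_identity_clusters([base, near, far], 0.90)
        assert len(clusters) == 2

    def test_refined_model_rescoring_training_set_passes_filter(self, rng):
        ancestor = "".join(rng.choice(list(AMINO_ACIDS), size=110))

        def variant(d):
            s = list(ancestor)
            for p in rng.choice(110, size=int(110 * d), replace=False):
                s[p] = AMINO_ACIDS[int(rng.integers(20))]
            return "".join(s)

        family = [ancestor, variant(0.05), variant(0.05), variant(0.3), variant(0.3)]
        model = refine_marker_models(family, round_id=3)
        hits = scan_proteins([model], {f"p{i}": s for i, s in enumerate(family)})
        assert len(filter_marker_hits(hits, "profile")) == len(family)

    def test_duplicating_sequences_never_increases_cluster_count(self, rng):
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=80)) for _ in range(4)]
        base = len(greedy_identity_clusters(seqs, 0.9))
        doubled = len(greedy_identity_clusters(seqs + seqs, 0.9))
        assert doubled <= base

    def test_fewer_than_two_sequences_rejected(self):
        with pytest.raises(ValueError):
            refine_marker_models(["MACDEF"], round_id=2)


class TestPiCharacterization:
    def test_c_terminal_tmd_is_canonical(self):
        assert classify_pi_topology("A" * 300, [TMDSpan(270, 290, 3.0)]) == "canonical_C_terminal"

    def test_n_terminal_tmd_is_atypical(self):
        assert classify_pi_topology("A" * 300, [TMDSpan(5, 25, 3.0)]) == "atypical_N_terminal"

    def test_no_tmd_is_none(self):
        assert classify_pi_topology("A" * 300, []) == "none"

    def test_validate_cluster_passes_with_tmds_and_context(self):
        prot = "M" + "D" * 40 + "L" * 21 + "D" * 10
        members = {f"p{i}": prot for i in range(4)}
        contexts = {"p0": ["replication"], "p1": ["structural"], "p2": ["replication"], "p3": []}
        ok, reasons = validate_pi_cluster(members, contexts)
        assert ok and reasons == []

    def test_validate_cluster_fails_without_tmds(self):
        members = {f"p{i}": "M" + "D" * 60 for i in range(4)}
        contexts = {k: ["replication"] for k in members}
        ok, reasons = validate_pi_cluster(members, contexts)
        assert not ok and "no TMD" in reasons

    def test_validate_cluster_fails_without_context(self):
        prot = "M" + "D" * 40 + "L" * 21 + "D" * 10
        members = {f"p{i}": prot for i in range(3)}
        ok, reasons = validate_pi_cluster(members, {k: [] for k in members})
        assert not ok and "context" in reasons


def test_parse_hmmsearch_tblout(tmp_path):
    content = (
        "# comment line\n"
        "geneA  -  pI_model  -  1.2e-12  45.3  0.1  1.2e-12  44.0  0.1 "
        "1 1 0 0 1 1 1 1 description\n"
    )
    path = tmp_path / "hits.tbl"
    path.write_text(content)
    (hit,) = parse_hmmsearch_tblout(path)
    assert hit.gene_id == "geneA"
    assert hit.model_id == "pI_model"
    assert hit.e_value == pytest.approx(1.2e-12)
    assert hit.bit_score == pytest.approx(45.3)
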