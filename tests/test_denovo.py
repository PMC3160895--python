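import numpy as np
import pytest

from epireact.alignment import AlignmentParams, PairwiseScoreMatrix, \
    score_matrix
from epireact.core import Peptide, PeptideSet, RunConfig, ValidationError
from epireact.denovo import (Cluster, MultipleAlignment, NoveltyIndex,
                             align_cluster, blosum50_groups, cluster_peptides,
                             column_information, distance_matrix,
                             enumerate_candidates, extract_motif, generate,
                             novelty_filter, rank_and_select, select_clusters)
from epireact.denovo import LOG2_20, build_kmer_index
from epireact.model import train_model
from epireact.synthetic import make_fixture
from oracles import max_identity_any_window, substring_in_any, violates_novelty


class TestGroups:
    def test_partition_covers_alphabet_once(self):
        groups = blosum50_groups()
        joined = "".join(groups)
        assert sorted(joined) == sorted("ACDEFGHIKLMNPQRSTVWY")

    def test_chemically_coherent(self):
        groups = blosum50_groups()
        by_res = {aa: g for g in groups for aa in g}
        assert by_res["F"] == by_res["W"] == by_res["Y"]   # aromatics
        assert by_res["I"] == by_res["L"] == by_res["V"]   # aliphatics
        assert by_res["K"] == by_res["R"]                  # basics


class TestDistanceMatrix:
    def test_toy_closed_form(self):
        s = np.array([[10.0, 5.0, 0.0], [5.0, 10.0, 0.0], [0.0, 0.0, 8.0]])
        m = PairwiseScoreMatrix("local", s, ["a", "b", "c"])
        d = distance_matrix(m)
        assert d[0, 1] == pytest.approx(0.5)
        assert d[0, 2] == pytest.approx(1.0)
        assert np.all(np.diagonal(d) == 0.0)

    def test_identical_peptides_distance_zero(self):
        pset = PeptideSet([Peptide("a", "ACDEFGHIK"), Peptide("b", "ACDEFGHIK"),
                           Peptide("c", "WWWWWWWWW")], strict=False)
        d = distance_matrix(score_matrix(pset, AlignmentParams(mode="local")))
        assert d[0, 1] == pytest.approx(0.0)

    def test_global_matrix_rejected(self, tiny_matrices):
        mg, _ = tiny_matrices
        with pytest.raises(ValidationError):
            distance_matrix(mg)

    def test_values_in_unit_interval(self, tiny_matrices):
        d = distance_matrix(tiny_matrices[1])
        assert np.all((d >= 0.0) & (d <= 1.0))


class TestClustering:
    def test_all_far_gives_singletons(self):
        d = 1.0 - np.eye(5)
        clusters = cluster_peptides(d, 0.7)
        assert len(clusters) == 5
        assert all(c.size == 1 for c in clusters)

    def test_all_close_gives_one_cluster(self):
        d = np.zeros((6, 6))
        clusters = cluster_peptides(d, 0.7)
        assert len(clusters) == 1 and clusters[0].size == 6

    def test_planted_two_family_structure_recovered(self):
        # within-family distance < 0.4, between > 0.9
        n = 10
        d = np.full((n, n), 0.95)
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    d[i, j] = 0.3
        np.fill_diagonal(d, 0.0)
        clusters = cluster_peptides(d, 0.7)
        families = sorted(tuple(sorted(c.members)) for c in clusters
                          if c.size > 1)
        assert families == [tuple(range(5)), tuple(range(5, 10))]

    def test_complete_linkage_diameter_bound(self, tiny_matrices):
        d = distance_matrix(tiny_matrices[1])
        for c in cluster_peptides(d, 0.7):
            sub = d[np.ix_(c.members, c.members)]
            assert sub.max() <= 0.7 + 1e-12


class TestSelectClusters:
    def _label_run(self, composition):
        labels = []
        clusters = []
        for n_pos, n_neg in composition:
            start = len(labels)
            labels += ["positive"] * n_pos + ["negative"] * n_neg
            clusters.append(Cluster(members=list(range(start, len(labels)))))
        return clusters, labels

    @pytest.mark.parametrize("n_pos,n_neg,expected", [
        (5, 0, "H"),             # all positive, at the H size threshold
        (4, 0, "unselected"),    # below H threshold
        (0, 8, "L"),             # all negative, at the L size threshold
        (0, 7, "unselected"),    # below L threshold
        (2, 6, "M"),             # fraction 0.25 == training fraction
        (4, 4, "unselected"),    # fraction 0.5 far from 0.25
    ])
    def test_typing_rules(self, n_pos, n_neg, expected):
        clusters, labels = self._label_run([(n_pos, n_neg)])
        select_clusters(clusters, labels, train_pos_fraction=0.25)
        assert clusters[0].type == expected


class TestAlignCluster:
    def _pset(self, seqs):
        return PeptideSet([Peptide(f"p{i}", s) for i, s in enumerate(seqs)],
                          strict=False)

    def test_identical_sequences_align_without_gaps(self):
        pset = self._pset(["ACDEFGHIK"] * 4)
        msa = align_cluster(Cluster(members=[0, 1, 2, 3]), pset)
        assert all(r == "ACDEFGHIK" for r in msa.rows)
        assert np.allclose(msa.information, LOG2_20)

    def test_rows_ungap_to_originals(self, tiny_set, tiny_matrices):
        d = distance_matrix(tiny_matrices[1])
        clusters = [c for c in cluster_peptides(d, 0.7) if c.size >= 2]
        assert clusters, "fixture should contain at least one real cluster"
        for c in clusters:
            msa = align_cluster(c, tiny_set, m_local=tiny_matrices[1])
            for k, idx in enumerate(c.members):
                assert msa.ungapped(k) == tiny_set[idx].sequence

    def test_single_substitution_pair(self):
        pset = self._pset(["ACDEFGHIK", "ACDEFGHIR"])
        msa = align_cluster(Cluster(members=[0, 1]), pset)
        assert msa.width == 9
        n_mismatch_cols = sum(1 for col in zip(*msa.rows) if len(set(col)) == 2)
        assert n_mismatch_cols == 1

    def test_cluster_of_one_rejected(self):
        with pytest.raises(ValidationError):
            align_cluster(Cluster(members=[0]), self._pset(["ACDEF"]))


class TestColumnInformation:
    def test_conserved_column_is_full_information(self):
        assert column_information("AAAA") == pytest.approx(LOG2_20)

    def test_uniform_20_residues_is_zero(self):
        assert column_information("ACDEFGHIKLMNPQRSTVWY") == pytest.approx(0.0)

    def test_two_residue_even_split(self):
        assert column_information("AACC") == pytest.approx(LOG2_20 - 1.0)

    def test_gaps_excluded_and_all_gap_is_zero(self):
        assert column_information("A-A-") == pytest.approx(LOG2_20)
        assert column_information("----") == 0.0


class TestExtractMotif:
    def _msa(self, seqs):
        return MultipleAlignment(member_ids=[f"p{i}" for i in range(len(seqs))],
                                 rows=seqs)

    def test_empty_index_fixes_everything(self):
        msa = self._msa(["ACDEFGHIKLMNPQR"] * 3)
        motif = extract_motif(0, msa, frozenset())
        assert motif.fixed == list("ACDEFGHIKLMNPQR")
        assert all(len(s) == 1 for s in motif.allowed)

    def test_self_indexed_sequence_limits_fixed_runs(self):
        seq = "ACDEFGHIKLMNPQR"
        msa = self._msa([seq] * 3)
        index = build_kmer_index(PeptideSet([Peptide("t", seq)]))
        motif = extract_motif(0, msa, index)
        fixed = [f is not None for f in motif.fixed]
        runs, run = [], 0
        for f in fixed:
            run = run + 1 if f else 0
            runs.append(run)
        # no fixed 4-run may spell an indexed 4-mer; here every 4-mer of the
        # sequence is indexed, so runs must stay at 3 or below
        for w in range(12):
            window = "".join(seq[w:w + 4])
            if all(fixed[w:w + 4]):
                assert not substring_in_any(window, [seq])
        assert max(runs) <= 3

    def test_disjoint_index_leaves_sequence_fixed(self):
        seq = "ACDEFGHIKLMNPQR"
        msa = self._msa([seq] * 2)
        index = build_kmer_index(PeptideSet([Peptide("t", "WWWWWWWWWWWWWWW")]))
        motif = extract_motif(0, msa, index)
        assert motif.fixed == list(seq)

    def test_no_fixed_4mer_ever_in_index_brute_force(self, tiny_set,
                                                     tiny_matrices):
        d = distance_matrix(tiny_matrices[1])
        index = build_kmer_index(tiny_set)
        seqs = tiny_set.sequences
        checked = 0
        for c in cluster_peptides(d, 0.7):
            if c.size < 2:
                continue
            msa = align_cluster(c, tiny_set, m_local=tiny_matrices[1])
            for row in range(c.size):
                seq = msa.ungapped(row)
                if len(seq) != 15:
                    continue
                motif = extract_motif(row, msa, index)
                fixed = [f is not None for f in motif.fixed]
                for w in range(12):
                    if all(fixed[w:w + 4]):
                        assert not substring_in_any(seq[w:w + 4], seqs)
                checked += 1
        assert checked > 0

    def test_identity_budget_limits_fixed_positions(self):
        seq = "ACDEFGHIKLMNPQR"
        msa = self._msa([seq] * 3)
        motif = extract_motif(0, msa, frozenset(), max_identities=5,
                              identity_window=11)
        fixed = [f is not None for f in motif.fixed]
        for start in range(5):
            assert sum(fixed[start:start + 11]) <= 5

    def test_allowed_sets_never_empty(self, tiny_set, tiny_matrices):
        d = distance_matrix(tiny_matrices[1])
        index = build_kmer_index(tiny_set)
        for c in cluster_peptides(d, 0.7):
            if c.size < 2:
                continue
            msa = align_cluster(c, tiny_set, m_local=tiny_matrices[1])
            for row in range(c.size):
                if len(msa.ungapped(row)) != 15:
                    continue
                motif = extract_motif(row, msa, index, max_identities=5)
                assert all(len(s) >= 1 for s in motif.allowed)


class TestEnumerate:
    def _motif(self, allowed):
        from epireact.denovo import Motif
        return Motif(source_id="s", cluster_type="H",
                     fixed=[next(iter(s)) if len(s) == 1 else None
                            for s in allowed],
                     allowed=[frozenset(s) for s in allowed])

    def test_all_fixed_yields_single_sequence(self):
        motif = self._motif(list("ACDEFGHIKLMNPQR"))
        assert enumerate_candidates(motif) == ["ACDEFGHIKLMNPQR"]

    def test_product_count(self):
        allowed = list("ACDEFGHIKLMNP") + ["QR", "WYV"]
        out = enumerate_candidates(self._motif(allowed))
        assert len(out) == 6
        assert len(set(out)) == 6

    def test_capped_sampling_is_seeded(self):
        allowed = ["ACDEFWY"] * 5 + list("ACDEFGHIKL")
        motif = self._motif(allowed)
        a = enumerate_candidates(motif, cap=10, rng=np.random.default_rng(7))
        b = enumerate_candidates(motif, cap=10, rng=np.random.default_rng(7))
        assert a == b and len(a) == 10 and len(set(a)) == 10


class TestNoveltyFilter:
    def _index(self, train_seqs, test_seqs=()):
        train = PeptideSet([Peptide(f"t{i}", s)
                            for i, s in enumerate(train_seqs)], strict=False)
        test = (PeptideSet([Peptide(f"u{i}", s)
                            for i, s in enumerate(test_seqs)], strict=False)
                if test_seqs else None)
        return NoveltyIndex.build(train, test)

    def test_training_peptide_fails_on_shared_kmer(self):
        seq = "ACDEFGHIKLMNPQR"
        ok, reason = novelty_filter(seq, self._index([seq]))
        assert not ok and "4-mer" in reason

    def test_test_set_kmers_also_banned(self):
        seq = "ACDEFGHIKLMNPQR"
        index = self._index(["WWWWWWWWWWWWWWW"], test_seqs=[seq])
        ok, reason = novelty_filter(seq, index)
        assert not ok and "4-mer" in reason

    def test_disjoint_alphabet_passes(self):
        ok, reason = novelty_filter("W" * 15, self._index(["ACDEFGHIKLMNPQR"]))
        assert ok and reason is None

    def test_borderline_identity_five_passes_six_fails(self):
        train = "ADGKNQSVWYACDFH"
        # candidate matching train at exactly 5 scattered positions (offset 0)
        cand5 = list("WWWWWWWWWWWWWWW")
        cand6 = list("WWWWWWWWWWWWWWW")
        for p in (0, 2, 4, 6, 8):
            cand5[p] = train[p]
            cand6[p] = train[p]
        cand6[10] = train[10]
        cand5, cand6 = "".join(cand5), "".join(cand6)
        index = self._index([train])
        assert max_identity_any_window(cand5, train) == 5
        assert max_identity_any_window(cand6, train) == 6
        assert novelty_filter(cand5, index)[0]
        ok, reason = novelty_filter(cand6, index)
        assert not ok and "identity" in reason

    def test_vectorized_scan_matches_offset_oracle(self):
        rng = np.random.default_rng(30)
        aas = np.array(list("ACDEFG"))  # small alphabet to force matches
        trains = ["".join(rng.choice(aas, size=rng.integers(9, 22)))
                  for _ in range(8)]
        index = self._index(trains)
        for _ in range(30):
            cand = "".join(rng.choice(aas, size=15))
            expected = max(max_identity_any_window(cand, t) for t in trains)
            assert index.max_identity_in_window(cand) == expected


class TestRankAndSelect:
    def _pool(self, cls, probs):
        return [(f"{'ACDEFGHIKLMNPQR'[i % 15] * 15}"[:15], p)
                for i, p in enumerate(probs)]

    def test_exact_fit_selects_all(self):
        pools = {"H": [("A" * 15, 0.9), ("C" * 15, 0.8)],
                 "L": [("D" * 15, 0.1), ("E" * 15, 0.2)],
                 "M": [("F" * 15, 0.5), ("G" * 15, 0.6)]}
        out = rank_and_select(pools, counts=2)
        assert out.counts() == {"H": 2, "L": 2, "M": 2}

    def test_shortfall_names_class(self):
        pools = {"H": [("A" * 15, 0.9)], "L": [], "M": []}
        with pytest.raises(ValidationError, match="L"):
            rank_and_select(pools, counts={"H": 1, "L": 1, "M": 0})

    def test_h_takes_top_l_takes_bottom(self):
        pools = {"H": [("A" * 15, 0.2), ("C" * 15, 0.9), ("D" * 15, 0.7)],
                 "L": [("E" * 15, 0.8), ("F" * 15, 0.1), ("G" * 15, 0.4)]}
        out = rank_and_select(pools, counts={"H": 2, "L": 2, "M": 0})
        assert {c.sequence for c in out.of_class("H")} == {"C" * 15, "D" * 15}
        assert {c.sequence for c in out.of_class("L")} == {"F" * 15, "G" * 15}

    def test_m_selection_reproducible_under_seed(self):
        pool = [(chr(65 + i % 26) * 15, 0.5) for i in range(10)]
        pool = [(s, p) for s, p in dict(pool).items()]
        pools = {"M": pool}
        a = rank_and_select(pools, counts={"M": 4},
                            rng=np.random.default_rng(3))
        b = rank_and_select(pools, counts={"M": 4},
                            rng=np.random.default_rng(3))
        assert [c.sequence for c in a] == [c.sequence for c in b]


@pytest.fixture(scope="module")
def pipeline_run():
    pset = make_fixture("clustered", seed=41)
    cfg = RunConfig(seed=41)
    model, bundle = train_model(pset, cfg, subset="A")
    clist, report = generate(pset, model, bundle.table.norm_params,
                             bundle.m_local, config=cfg,
                             counts={"H": 25, "L": 25, "M": 25},
                             max_pool_per_class=200)
    return pset, cfg, clist, report, bundle


class TestGeneratePipeline:
    def test_every_candidate_passes_brute_force_novelty_recheck(self, pipeline_run):
        pset, cfg, clist, report, _ = pipeline_run
        train_seqs = pset.sequences
        for c in clist:
            assert not violates_novelty(c.sequence, train_seqs, [],
                                        cfg.max_common_stretch,
                                        cfg.max_identities,
                                        cfg.identity_window), c.sequence

    def test_cluster_diameters_bounded_by_cutoff(self, pipeline_run):
        pset, cfg, _, report, bundle = pipeline_run
        d = distance_matrix(bundle.m_local)
        for c in report.clusters:
            sub = d[np.ix_(c.members, c.members)]
            assert sub.max() <= cfg.cluster_cutoff + 1e-12

    def test_h_dominates_l_in_predicted_reactivity(self, pipeline_run):
        _, _, clist, _, _ = pipeline_run
        h = np.median([c.predicted_reactivity for c in clist.of_class("H")])
        l = np.median([c.predicted_reactivity for c in clist.of_class("L")])
        assert h > l

    def test_all_candidates_are_15mers(self, pipeline_run):
        _, _, clist, _, _ = pipeline_run
        assert all(len(c.sequence) == 15 for c in clist)
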