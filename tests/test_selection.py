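"""Mann-Whitney ranking, reduced tables, LOOCV AUC, and the selection loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmbc import (
    ClassPrior,
    SimulationSpec,
    build_reduced,
    load_model,
    loocv_auc,
    model_from_json,
    model_to_json,
    null_spec,
    planted_spec,
    predict,
    rank_taxa,
    save_model,
    select_features,
    simulate,
    train,
)


def _two_group_table(group_a, group_b, extra_taxon=50):
    """n_a + n_b samples, taxon 0 carrying the values, taxon 1 constant."""
    values = np.array(group_a + group_b)
    counts = np.column_stack([values, np.full(values.size, extra_taxon)])
    mask = np.array([False] * len(group_a) + [True] * len(group_b))
    return counts, mask


class TestRankTaxa:
    def test_exact_small_sample_pvalue(self):
        counts, mask = _two_group_table([1, 2, 3], [4, 5, 6])
        ranking = rank_taxa(counts, mask)
        # exact enumeration: 2 of the C(6,3)=20 assignments are as extreme
        assert ranking.pvalues[0] == pytest.approx(0.1, abs=1e-12)
        assert ranking.pvalues[1] == pytest.approx(1.0)  # constant taxon: no separation
        assert ranking.order[0] == 0

    def test_threshold_is_strict(self):
        counts, mask = _two_group_table([1, 2, 3], [4, 5, 6])
        assert rank_taxa(counts, mask, threshold=0.5).candidate_count == 1
        assert rank_taxa(counts, mask, threshold=0.1).candidate_count == 0  # P == threshold excluded

    def test_order_sorts_pvalues(self, rng):
        counts = rng.integers(0, 60, size=(24, 8)) + 1
        mask = np.arange(24) < 12
        ranking = rank_taxa(counts, mask)
        sorted_p = ranking.pvalues[ranking.order]
        assert np.all(np.diff(sorted_p) >= 0)
        assert sorted(ranking.order.tolist()) == list(range(8))
        assert np.all((ranking.pvalues >= 0) & (ranking.pvalues <= 1))

    def test_proportion_mode_differs_under_depth_confounding(self):
        # one class sequenced 10x deeper: raw counts separate, proportions do not
        rng = np.random.default_rng(4)
        shallow = rng.multinomial(100, [0.5, 0.5], size=8)
        deep = rng.multinomial(1000, [0.5, 0.5], size=8)
        counts = np.vstack([shallow, deep])
        mask = np.arange(16) >= 8
        raw = rank_taxa(counts, mask)
        prop = rank_taxa(counts, mask, on_proportions=True)
        assert raw.pvalues[0] < 0.01
        assert prop.pvalues[0] > 0.05

    def test_errors(self):
        counts = np.array([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="both classes"):
            rank_taxa(counts, np.array([True, True]))
        with pytest.raises(ValueError, match="threshold"):
            rank_taxa(counts, np.array([True, False]), threshold=1.5)


class TestBuildReduced:
    def test_documented_example(self):
        row = np.array([[3, 5, 2, 7]])
        assert build_reduced(row, [0, 2]).tolist() == [[3, 2, 12]]

    def test_all_but_one_passes_through(self):
        row = np.array([[3, 5, 2, 7]])
        assert build_reduced(row, [0, 1, 2]).tolist() == [[3, 5, 2, 7]]

    def test_keep_all_appends_zero_column(self):
        row = np.array([[3, 5, 2, 7]])
        out = build_reduced(row, [0, 1, 2, 3])
        assert out.shape == (1, 5)
        assert out[0, -1] == 0
        assert out.sum() == 17

    def test_errors(self):
        row = np.array([[3, 5, 2, 7]])
        with pytest.raises(ValueError, match="at least one"):
            build_reduced(row, [])
        with pytest.raises(ValueError, match="duplicate"):
            build_reduced(row, [0, 0])
        with pytest.raises(ValueError, match="range"):
            build_reduced(row, [4])

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.data())
    def test_row_totals_conserved(self, data):
        n = data.draw(st.integers(1, 8))
        t = data.draw(st.integers(2, 10))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 500, size=(n, t))
        k = data.draw(st.integers(1, t))
        keep = rng.choice(t, size=k, replace=False)
        reduced = build_reduced(counts, keep)
        assert np.array_equal(reduced.sum(axis=1), counts.sum(axis=1))
        assert reduced.shape == (n, k + 1)


class TestLoocvAuc:
    def test_strong_separation(self):
        spec = SimulationSpec(
            pi_healthy=np.array([0.8, 0.1, 0.1]),
            pi_diseased=np.array([0.1, 0.8, 0.1]),
            theta_healthy=0.01,
            theta_diseased=0.01,
            n_per_class=20,
            depth=1000,
            seed=2,
        )
        table, _ = simulate(spec)
        auc, scores = loocv_auc(table.counts, table.labels == "diseased", [0, 1])
        assert auc >= 0.95
        assert scores.shape == (40,)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_null_band_with_fixed_keep(self, seed):
        table, _ = simulate(null_spec(seed=seed))
        auc, _ = loocv_auc(table.counts, table.labels == "diseased", [0, 1])
        assert 0.3 <= auc <= 0.7

    def test_fixed_prior_shifts_scores_not_auc(self):
        table, _ = simulate(planted_spec(n_per_class=10, seed=3))
        mask = table.labels == "diseased"
        auc_emp, s_emp = loocv_auc(table.counts, mask, [0, 1])
        prior = ClassPrior(np.array([0.9, 0.1]), "user")
        auc_fix, s_fix = loocv_auc(table.counts, mask, [0, 1], prior=prior)
        assert not np.allclose(s_emp, s_fix)
        assert auc_fix == pytest.approx(auc_emp, abs=0.1)

    def test_small_class_error(self):
        counts = np.array([[5, 5]] * 6)
        mask = np.array([True, True, False, False, False, False])
        with pytest.raises(ValueError, match="larger"):
            loocv_auc(counts, mask, [0])


class TestSelectFeatures:
    def test_single_candidate_single_round(self):
        counts, mask = _two_group_table([10, 11, 12, 13, 14, 15], [20, 21, 22, 23, 24, 25])
        trace = select_features(counts, mask)
        assert len(trace.rounds) == 1
        assert trace.best_k == 1
        assert trace.best_round.taxa == (0,)

    def test_no_candidates_errors(self):
        counts = np.array([[5, 5]] * 8)
        mask = np.arange(8) < 4
        with pytest.raises(ValueError, match="threshold"):
            select_features(counts, mask)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_signal_dominates_selection(self, seed):
        table, truth = simulate(planted_spec(seed=seed))
        trace = select_features(table.counts, table.labels == "diseased")
        assert trace.best_auc >= 0.9
        # the selected set consists of planted signal taxa only
        assert set(trace.best_round.taxa) <= set(truth["signal_taxa"])

    def test_parsimony_tie_break(self):
        table, _ = simulate(planted_spec(seed=0))
        trace = select_features(table.counts, table.labels == "diseased")
        best = max(r.auc for r in trace.rounds)
        tied = [r.k for r in trace.rounds if r.auc == best]
        assert trace.best_k == min(tied)
        assert len(tied) > 1  # the tie is real on this dataset

    def test_rounds_strictly_increasing_and_nested(self):
        table, _ = simulate(planted_spec(seed=1))
        trace = select_features(table.counts, table.labels == "diseased")
        ks = [r.k for r in trace.rounds]
        assert ks == list(range(1, len(ks) + 1))
        for a, b in zip(trace.rounds, trace.rounds[1:]):
            assert set(a.taxa) < set(b.taxa)
        assert all(0.0 <= r.auc <= 1.0 for r in trace.rounds)

    def test_invariant_to_noncandidate_column_permutation(self):
        table, _ = simulate(planted_spec(n_taxa=8, seed=4))
        mask = table.labels == "diseased"
        trace = select_features(table.counts, mask)
        ranking = rank_taxa(table.counts, mask)
        cand = ranking.order[: ranking.candidate_count]
        non_cand = [t for t in range(8) if t not in set(cand.tolist())]
        if len(non_cand) >= 2:
            perm = np.arange(8)
            perm[non_cand[0]], perm[non_cand[1]] = non_cand[1], non_cand[0]
            trace_p = select_features(table.counts[:, perm], mask)
            assert [r.auc for r in trace_p.rounds] == pytest.approx(
                [r.auc for r in trace.rounds], abs=1e-9
            )

    def test_rerank_per_fold_runs(self):
        table, _ = simulate(planted_spec(n_taxa=6, n_per_class=8, seed=6))
        trace = select_features(table.counts, table.labels == "diseased", rerank_per_fold=True)
        assert trace.best_auc >= 0.9


class TestTrainPredict:
    def test_planted_model_contrast_is_on_signal_taxa(self):
        table, truth = simulate(planted_spec(seed=0))
        model = train(table, positive_label="diseased")
        neg, pos = model.class_params
        diffs = np.abs(neg.pi - pos.pi)
        # the largest compositional contrast sits on a fitted signature taxon
        sig_names = set(model.signature_taxa)
        assert sig_names <= {f"taxon_{i + 1:03d}" for i in truth["signal_taxa"]}
        assert int(np.argmax(diffs[:-1])) < len(model.signature_taxa)

    def test_in_sample_prediction_deterministic(self):
        table, _ = simulate(planted_spec(n_per_class=10, seed=7))
        model = train(table, positive_label="diseased")
        r1 = predict(model, table.counts, table.taxa, sample_ids=table.sample_ids)
        r2 = predict(model, table.counts, table.taxa, sample_ids=table.sample_ids)
        assert np.array_equal(r1.probs, r2.probs)
        accuracy = np.mean(np.asarray(r1.calls) == table.labels)
        assert accuracy >= 0.9

    def test_fresh_sample_generalization(self):
        spec = planted_spec(seed=8)
        table, _ = simulate(spec)
        model = train(table, positive_label="diseased")
        test_table, _ = simulate(planted_spec(seed=1008, n_per_class=25))
        res = predict(model, test_table.counts, test_table.taxa, sample_ids=test_table.sample_ids)
        assert np.mean(np.asarray(res.calls) == test_table.labels) >= 0.9

    def test_predict_maps_taxa_by_name(self):
        table, _ = simulate(planted_spec(n_per_class=10, seed=9))
        model = train(table, positive_label="diseased")
        # shuffle columns and add an unseen taxon: scores must be unchanged
        perm = np.random.default_rng(0).permutation(len(table.taxa))
        shuffled = table.counts[:, perm]
        taxa = [table.taxa[j] for j in perm]
        extra = np.column_stack([shuffled, np.full(shuffled.shape[0], 17)])
        base = predict(model, table.counts, table.taxa)
        moved = predict(model, shuffled, taxa)
        assert np.array_equal(base.probs, moved.probs)
        with_extra = predict(model, extra, taxa + ["novel_taxon"])
        assert with_extra.probs.shape == base.probs.shape

    def test_predict_all_reads_in_other(self):
        table, _ = simulate(planted_spec(n_per_class=10, seed=10))
        model = train(table, positive_label="diseased")
        other_names = [t for t in table.taxa if t not in set(model.signature_taxa)]
        counts = np.full((2, len(other_names)), 100)
        res = predict(model, counts, other_names)
        assert np.all(np.isfinite(res.probs))
        assert res.probs.sum(axis=1) == pytest.approx([1.0, 1.0])

    def test_predict_no_overlap_errors(self):
        table, _ = simulate(planted_spec(n_per_class=10, seed=11))
        model = train(table, positive_label="diseased")
        with pytest.raises(ValueError, match="overlap"):
            predict(model, np.array([[1, 2]]), ["genusA", "genusB"])

    def test_serialization_round_trip_bit_identical(self, tmp_path):
        table, _ = simulate(planted_spec(n_per_class=10, seed=12))
        model = train(table, positive_label="diseased", seed=12)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        assert model_to_json(loaded) == model_to_json(model)
        a = predict(model, table.counts, table.taxa)
        b = predict(loaded, table.counts, table.taxa)
        assert np.array_equal(a.probs, b.probs)
        assert model_from_json(model_to_json(model)).signature_taxa == model.signature_taxa

    def test_user_prior_is_recorded_and_used(self):
        table, _ = simulate(planted_spec(n_per_class=10, seed=13))
        model = train(table, prior=(0.2, 0.8), positive_label="diseased")
        assert model.prior.source == "user"
        assert model.prior.probs == pytest.approx([0.2, 0.8])
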