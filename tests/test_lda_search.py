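"""Fisher LDA, LOOCV (against a brute-force oracle), greedy search, Youden
recentring, and model-size selection."""

import numpy as np
import pytest

from mirpanel import (
    MarkerSpec,
    SimulationConfig,
    fit_fisher_lda,
    fit_normalization,
    generate_cohort,
    greedy_search,
    log_transform,
    loocv_metrics,
    normalize_to_controls,
    recenter_youden,
    select_model_size,
    youden_threshold,
)
from mirpanel.lda_search import GreedySearchTrace, TraceRow, _loocv_scores

from .conftest import feature_matrix


def brute_force_loocv_scores(X, y):
    """Independent oracle: explicit per-sample refit loop, no shortcuts."""
    X = np.asarray(X, float)
    y = np.asarray(y, bool)
    out = np.empty(len(y))
    for i in range(len(y)):
        keep = np.ones(len(y), bool)
        keep[i] = False
        model = fit_fisher_lda(X[keep], y[keep])
        out[i] = X[i] @ model.coefficients + model.intercept
    return out


class TestFitFisherLDA:
    def test_one_dimensional_closed_form(self):
        # cases {2,4}, controls {0,2}: pooled variance 2, w=1, intercept -2
        X = np.array([[2.0], [4.0], [0.0], [2.0]])
        y = np.array([True, True, False, False])
        model = fit_fisher_lda(X, y)
        np.testing.assert_allclose(model.coefficients, [1.0])
        assert model.intercept == pytest.approx(-2.0)
        scores = X.ravel() * model.coefficients[0] + model.intercept
        np.testing.assert_allclose(scores, [0.0, 2.0, -2.0, 0.0])

    def test_duplicated_feature_takes_ridge_path(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = np.array([True] * 20 + [False] * 20)
        x[y] += 1.5
        one = fit_fisher_lda(x[:, None], y)
        dup = fit_fisher_lda(np.column_stack([x, x]), y)
        s1 = x * one.coefficients[0] + one.intercept
        s2 = np.column_stack([x, x]) @ dup.coefficients + dup.intercept
        assert ((s1 >= 0) == (s2 >= 0)).all()
        np.testing.assert_allclose(s1, s2, rtol=1e-5)

    def test_label_swap_negates_model(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = np.array([True] * 15 + [False] * 15)
        a = fit_fisher_lda(X, y)
        b = fit_fisher_lda(X, ~y)
        np.testing.assert_allclose(a.coefficients, -b.coefficients, atol=1e-12)
        assert a.intercept == pytest.approx(-b.intercept)

    def test_cases_score_higher_on_average(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 4))
        y = np.array([True] * 30 + [False] * 30)
        X[y] += 0.8
        m = fit_fisher_lda(X, y)
        s = X @ m.coefficients + m.intercept
        assert s[y].mean() > s[~y].mean()

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_fisher_lda(np.zeros((3, 1)), [True, False, False])


class TestLOOCV:
    def test_perfect_separation_gives_accuracy_one(self):
        X = np.concatenate([np.full(10, 10.0), np.zeros(10)])[:, None]
        y = np.array([True] * 10 + [False] * 10)
        sens, spec, acc = loocv_metrics(X, y)
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_null_features_near_chance_accuracy(self):
        """On pure-noise features LOOCV accuracy hugs chance from below:
        holding a sample out shifts its own class mean away from it, so the
        estimate is pessimistic (occasionally far below 0.5), never
        optimistic."""
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 2))
            y = rng.permutation([True] * 20 + [False] * 20)
            accs.append(loocv_metrics(X, y)[2])
        accs = np.asarray(accs)
        assert accs.max() <= 0.7
        assert 0.3 <= np.median(accs) <= 0.7

    def test_matches_brute_force_oracle_on_random_instances(self):
        """50 random instances, n <= 60, p <= 3: exact agreement."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n1 = int(rng.integers(3, 30))
            n0 = int(rng.integers(3, 30))
            p = int(rng.integers(1, 4))
            X = rng.normal(size=(n1 + n0, p))
            y = np.array([True] * n1 + [False] * n0)
            X[y] += rng.uniform(0, 1.5)
            fast = _loocv_scores(X, y)
            slow = brute_force_loocv_scores(X, y)
            np.testing.assert_allclose(fast, slow, rtol=1e-8, atol=1e-8)
            assert ((fast >= 0) == (slow >= 0)).all()


class TestGreedySearch:
    def _features_labels(self, seed, markers, n_mirna=60):
        cfg = SimulationConfig(
            planted_markers=markers, n_mirna=n_mirna, n_case=100, n_control=100,
            seed=seed,
        )
        matrix, samples = generate_cohort(cfg)
        spec = fit_normalization(matrix, cfg.control_mirna_ids)
        feats = log_transform(normalize_to_controls(matrix, spec))
        return feats, samples.labels(feats.sample_ids)

    def test_recovers_single_strong_marker(self):
        """One planted marker (effect 2.0) among ~50 nulls: the size-1 panel
        is the planted marker in >= 18/20 seeds."""
        markers = (MarkerSpec("miR-sim-up", 2.0, "up"),)
        hits = 0
        for seed in range(20):
            feats, y = self._features_labels(seed, markers)
            cands = [m for m in feats.mirna_ids if not m.startswith("miR-ctl")]
            trace = greedy_search(feats, y, cands, k_max=1, select=False)
            hits += trace.row(1).mirna_ids == ["miR-sim-up"]
        assert hits >= 18

    def test_size_one_equals_exhaustive_best_single(self):
        feats, y = self._features_labels(3, (MarkerSpec("miR-sim-up", 1.0, "up"),))
        cands = [m for m in feats.mirna_ids if not m.startswith("miR-ctl")][:25]
        trace = greedy_search(feats, y, cands, k_max=1, select=False)
        # exhaustive oracle by the same criterion (accuracy, then AUC, then id)
        from mirpanel.roc import _structural_components

        best = None
        for c in cands:
            x = feats.data.loc[c].to_numpy()[:, None]
            acc = loocv_metrics(x, y)[2]
            m = fit_fisher_lda(x, y)
            s = x.ravel() * m.coefficients[0] + m.intercept
            auc = _structural_components(s[y], s[~y])[0]
            key = (acc, auc, tuple(-ord(ch) for ch in c))
            if best is None or key > best[0]:
                best = (key, c)
        assert trace.row(1).mirna_ids == [best[1]]

    def test_identical_columns_tie_break_lexicographic(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = np.array([True] * 25 + [False] * 25)
        x[y] += 1.0
        feats = feature_matrix(np.column_stack([x, x]), ids=["mB", "mA"])
        trace = greedy_search(feats, y, ["mB", "mA"], k_max=1, select=False)
        assert trace.row(1).mirna_ids == ["mA"]

    def test_invariant_to_candidate_order(self):
        markers = (MarkerSpec("miR-sim-up", 1.5, "up"),)
        feats, y = self._features_labels(5, markers)
        cands = [m for m in feats.mirna_ids if not m.startswith("miR-ctl")][:20]
        t1 = greedy_search(feats, y, cands, k_max=3, select=False)
        t2 = greedy_search(feats, y, cands[::-1], k_max=3, select=False)
        assert t1.row(3).mirna_ids == t2.row(3).mirna_ids

    def test_forward_nesting_invariant(self):
        markers = (MarkerSpec("miR-sim-up", 1.5, "up"),)
        feats, y = self._features_labels(6, markers)
        cands = [m for m in feats.mirna_ids if not m.startswith("miR-ctl")][:15]
        trace = greedy_search(feats, y, cands, k_max=4, select=False)
        for k in range(2, 5):
            assert set(trace.row(k - 1).mirna_ids) < set(trace.row(k).mirna_ids)

    def test_k_max_truncated_with_warning(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        y = np.array([True] * 15 + [False] * 15)
        feats = feature_matrix(X, ids=["a", "b"])
        with pytest.warns(UserWarning, match="truncat"):
            trace = greedy_search(feats, y, ["a", "b"], k_max=5, select=False)
        assert trace.k_max == 2


class TestYouden:
    def test_enumerated_example_prefers_smaller_threshold(self):
        scores = np.array([1.0, 2.0, 3.0, -3.0, -2.0, 1.0])
        labels = np.array([True, True, True, False, False, False])
        # J max = 2/3, tied at t=1 (sens 1, spec 2/3) and t=2 (sens 2/3,
        # spec 1); smaller t wins
        assert youden_threshold(scores, labels) == 1.0

    def test_perfect_separation_picks_smallest_case_score(self):
        scores = np.array([5.0, 6.0, 7.0, -1.0, 0.0])
        labels = np.array([True, True, True, False, False])
        assert youden_threshold(scores, labels) == 5.0

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(size=n), 1)  # force ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            t = youden_threshold(scores, labels)
            # oracle: enumerate all observed thresholds explicitly
            best = None
            for cand in sorted(set(scores)):
                sens = (scores[labels] >= cand).mean()
                spec = (scores[~labels] < cand).mean()
                j = sens + spec - 1
                if best is None or j > best[0] + 1e-12:
                    best = (j, cand)
            assert t == best[1]

    def test_recentring_moves_optimum_to_zero(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(60, 3))
        y = np.array([True] * 30 + [False] * 30)
        X[y] += 1.0
        model = fit_fisher_lda(X, y)
        rec = recenter_youden(model, X, y)
        scores = X @ rec.coefficients + rec.intercept
        assert youden_threshold(scores, y) == pytest.approx(0.0, abs=1e-12)
        assert rec.cutoff == 0.0


def _fake_trace(p_values):
    """Trace skeleton carrying only the nested DeLong p-values."""
    rows = []
    for k in range(1, len(p_values) + 2):
        rows.append(
            TraceRow(
                k=k,
                mirna_ids=[f"m{i}" for i in range(k)],
                model=None,
                sensitivity=0.9, specificity=0.9, accuracy=0.9,
                sensitivity_ci=(0, 1), specificity_ci=(0, 1),
                accuracy_ci=(0, 1),
                auc=0.9, auc_ci=(0, 1),
                p_accuracy_vs_prev=None if k == 1 else 0.5,
                p_auc_vs_prev=None if k == 1 else p_values[k - 2],
                loocv_correct=90, n=100,
                insample_scores=np.zeros(1),
            )
        )
    return GreedySearchTrace(rows=rows)


class TestSelectModelSize:
    def test_published_pattern_selects_four(self):
        trace = _fake_trace([1e-6, 0.004, 0.003, 0.33])
        assert select_model_size(trace) == 4

    def test_nothing_significant_falls_back_to_one(self):
        trace = _fake_trace([0.2, 0.6, 0.9])
        assert select_model_size(trace) == 1

    def test_monotone_significance_selects_k_max(self):
        trace = _fake_trace([0.001, 0.002, 0.0001])
        assert select_model_size(trace) == 4
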