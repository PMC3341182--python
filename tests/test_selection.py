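import itertools

import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

from radcm import (
    CaseTable,
    ClassifierSpec,
    EvaluationProtocol,
    mrmr_rank,
    mrmr_select,
    mutual_information,
    rad_rank,
    rad_select,
    syndrome_symptom_rad,
)
from radcm.selection import _mi_table, _mrmr_order
from conftest import make_random_table


class TestMutualInformation:
    def test_identical_balanced_vectors_give_one_bit(self):
        x = np.array([1, 1, 0, 0])
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_vector_gives_zero(self):
        assert mutual_information([1, 1, 1, 1], [1, 0, 1, 0]) == 0.0

    def test_empirically_independent_gives_zero(self):
        assert mutual_information([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.0)

    def test_matches_sklearn_plugin_estimate(self, rng):
        for _ in range(20):
            x = rng.integers(0, 2, 50)
            y = rng.integers(0, 2, 50)
            ours = mutual_information(x, y)
            ref = mutual_info_score(x, y) / np.log(2)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            mutual_information([1, 0], [1])


class TestRadRank:
    def test_perfect_and_absent_symptoms_bracket_ranking(self):
        y = np.array([1, 1, 0, 1, 0])
        F = np.column_stack([y, 1 - y, np.array([1, 0, 0, 1, 0])])
        t = CaseTable(list("12345"), ["always", "never", "mid"], ["syn"],
                      F=F, L=y[:, None])
        ranked = rad_rank(t, "syn")
        assert ranked[0] == ("always", 1.0)
        assert ranked[-1] == ("never", 0.0)

    def test_matches_brute_force_conditional(self, rng):
        t = make_random_table(rng, n=40, s=9, k=1)
        if t.L[:, 0].sum() == 0:
            t.L[0, 0] = 1
        scores = dict(rad_rank(t, "syndr_0"))
        pos = t.L[:, 0] == 1
        for j, name in enumerate(t.symptom_names):
            expect = t.F[pos, j].sum() / pos.sum()
            assert scores[name] == pytest.approx(expect)

    def test_scores_equal_cross_rad_matrix_row(self, rng):
        t = make_random_table(rng, n=60, s=7, k=2)
        t.L[0, :] = 1
        cross = syndrome_symptom_rad(t)
        for k, syndrome in enumerate(t.syndrome_names):
            scores = dict(rad_rank(t, syndrome))
            for j, name in enumerate(t.symptom_names):
                assert scores[name] == pytest.approx(cross.C[k, j])

    def test_never_positive_label_errors(self):
        t = CaseTable(["1"], ["a"], ["syn"], F=[[1]], L=[[0]])
        with pytest.raises(ValueError, match="never positive"):
            rad_rank(t, "syn")


class TestMrmrRank:
    def test_duplicate_of_top_feature_deferred(self, rng):
        # two identical copies of the most relevant symptom plus a
        # weaker independent one: the duplicate's redundancy with the
        # first pick equals its entropy, so the weaker symptom wins
        y = rng.integers(0, 2, 400)
        strong = np.where(rng.random(400) < 0.9, y, 1 - y)
        weak = np.where(rng.random(400) < 0.65, y, 1 - y)
        t = CaseTable([str(i) for i in range(400)],
                      ["copy1", "copy2", "weak"], ["syn"],
                      F=np.column_stack([strong, strong, weak]), L=y[:, None])
        order = mrmr_rank(t, "syn")
        assert order[0] == "copy1"
        assert order[1] == "weak"

    def test_n_select_one_is_max_mi(self, rng):
        t = make_random_table(rng, n=50, s=6, k=1)
        t.L[:3, 0] = 1
        y = t.L[:, 0]
        mis = [mutual_information(t.F[:, j], y) for j in range(6)]
        assert mrmr_rank(t, "syndr_0", 1) == [t.symptom_names[int(np.argmax(mis))]]

    def test_greedy_step_matches_exhaustive_mid(self, rng):
        for _ in range(5):
            t = make_random_table(rng, n=35, s=7, k=1)
            t.L[0, 0] = 1
            y = t.L[:, 0]
            order = _mrmr_order(t.F, y)
            rel, red = _mi_table(t.F, y)
            chosen: list[int] = []
            for step_pick in order:
                cands = [j for j in range(7) if j not in chosen]
                if not chosen:
                    crit = {j: rel[j] for j in cands}
                else:
                    crit = {j: rel[j] - np.mean([red[j, s] for s in chosen])
                            for j in cands}
                best = max(crit, key=lambda j: (crit[j], -j))
                assert crit[step_pick] == pytest.approx(crit[best])
                chosen.append(int(step_pick))

    def test_zero_redundancy_weight_is_plain_mi_ranking(self, rng):
        t = make_random_table(rng, n=80, s=8, k=1)
        t.L[0, 0] = 1
        y = t.L[:, 0]
        order = mrmr_rank(t, "syndr_0", redundancy_weight=0.0)
        mis = np.array([mutual_information(t.F[:, j], y) for j in range(8)])
        expect = [t.symptom_names[j] for j in np.argsort(-mis, kind="stable")]
        assert order == expect

    def test_bad_n_select_errors(self, rng):
        t = make_random_table(rng, n=10, s=3, k=1)
        with pytest.raises(ValueError):
            mrmr_rank(t, "syndr_0", 4)


def informative_plus_noise_table(seed=5, n=500, noise_cols=10):
    """One symptom equal to the label plus pure-noise symptoms."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.3).astype(int)
    noise = (rng.random((n, noise_cols)) < 0.4).astype(int)
    left = min(5, noise_cols)
    F = np.column_stack([noise[:, :left], y, noise[:, left:]])
    names = [f"noise_{j}" for j in range(left)] + ["signal"] + \
            [f"noise_{j}" for j in range(left, noise_cols)]
    return CaseTable([str(i) for i in range(n)], names, ["syn"],
                     F=F, L=y[:, None])


class TestWrapper:
    protocol = EvaluationProtocol(folds=5, seed=42)

    @pytest.mark.parametrize("select_fn", [rad_select, mrmr_select])
    def test_recovers_single_informative_symptom(self, select_fn):
        t = informative_plus_noise_table()
        res = select_fn(t, "syn", ClassifierSpec("svm", seed=42), self.protocol)
        assert "signal" in res.selected
        full_gm = dict((s, g) for s, g in res.trace)[t.n_symptoms]
        assert res.best_gmeans >= full_gm

    def test_single_symptom_table(self):
        t = informative_plus_noise_table(noise_cols=0)
        t2 = CaseTable(t.case_ids, ["signal"], ["syn"],
                       F=t.F[:, [0]], L=t.L)
        res = rad_select(t2, "syn", ClassifierSpec("knn", k=3), self.protocol)
        assert res.selected == ["signal"]
        assert len(res.trace) == 1

    def test_trace_is_full_sweep_and_selected_is_prefix(self):
        t = informative_plus_noise_table()
        res = rad_select(t, "syn", ClassifierSpec("svm"), self.protocol)
        assert [s for s, _ in res.trace] == list(range(t.n_symptoms, 0, -1))
        assert res.selected == res.ranking[: len(res.selected)]
        assert res.best_gmeans == max(g for _, g in res.trace)

    @pytest.mark.parametrize("select_fn", [rad_select, mrmr_select])
    def test_fixed_seed_is_deterministic(self, select_fn):
        t = informative_plus_noise_table()
        kw = dict(clf=ClassifierSpec("svm", seed=7),
                  protocol=EvaluationProtocol(folds=4, seed=7))
        a = select_fn(t, "syn", **kw)
        b = select_fn(t, "syn", **kw)
        assert a.to_dict() == b.to_dict()

    def test_rank_on_all_variant_runs(self):
        t = informative_plus_noise_table()
        res = rad_select(t, "syn", ClassifierSpec("knn"), self.protocol,
                         rank_on_all=True)
        assert "signal" in res.selected

    def test_degenerate_label_errors(self):
        t = informative_plus_noise_table()
        t.L[:, 0] = 0
        t.L[0, 0] = 1  # one positive case cannot stratify into 5 folds
        with pytest.raises(ValueError, match="folds"):
            rad_select(t, "syn", ClassifierSpec("svm"), self.protocol)


class TestClassifierSpec:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("svm", c=0.0)
        with pytest.raises(ValueError):
            ClassifierSpec("knn", k=0)
        with pytest.raises(ValueError):
            ClassifierSpec("forest")

    def test_knn_tie_breaks_positive(self):
        # even k engineered to a 1-1 vote: tie goes to the positive class
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        model = ClassifierSpec("knn", k=2).build().fit(X, y)
        assert model.predict(np.array([[0.5]]))[0] == 1
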