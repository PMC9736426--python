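"""Pseudo-absence sampling, splits, model families, AUC, ensembles."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from nichecast import (
    auc,
    build_ensemble,
    evaluate_transfer,
    fit_member,
    predict_suitability,
    sample_occurrences,
    split_sample,
    stratified_pseudoabsences,
)
from nichecast.exceptions import (
    ParameterError,
    SizeError,
    SplitError,
    UndefinedAUCError,
)
from nichecast.sdm import (
    FAMILIES,
    FittedMember,
    SDMEnsemble,
    TrainingSample,
    _largest_remainder,
    glm_linear_coefficients,
    retain_members,
    weighted_consensus,
)
from nichecast.synthetic import OccurrenceSet, StrataMap


def make_training(X, y):
    return TrainingSample(
        X=np.asarray(X, float), y=np.asarray(y, int),
        cells=np.zeros((len(y), 2), int),
        provenance=np.array(["presence"] * len(y)),
        predictor_names=("a", "b", "c")[: np.asarray(X).shape[1]],
    )


class TestAllocation:
    @pytest.mark.parametrize(
        "sizes,n,expected",
        [
            ([30, 10], 8, [6, 2]),  # hand-computed largest remainder
            ([5, 3, 2], 3, [1, 1, 1]),  # quotas 1.5/0.9/0.6 -> floors + remainders
            ([100], 7, [7]),
            ([1, 1, 1], 3, [1, 1, 1]),
        ],
    )
    def test_largest_remainder_hand_cases(self, sizes, n, expected):
        sizes = np.array(sizes, float)
        alloc = _largest_remainder(sizes, n, sizes.astype(int))
        assert alloc.tolist() == expected

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        sizes=st.lists(st.integers(1, 50), min_size=1, max_size=6),
        frac=st.floats(0.01, 1.0),
    )
    def test_allocation_is_exact_and_proportional(self, sizes, frac):
        """Largest-remainder apportionment sums to n, respects caps, and
        never deviates from the exact quota by one whole unit or more."""
        sizes_arr = np.array(sizes, float)
        n = max(1, int(frac * sizes_arr.sum()))
        alloc = _largest_remainder(sizes_arr, n, sizes_arr.astype(int))
        assert alloc.sum() == n
        assert np.all(alloc <= sizes_arr)
        quotas = n * sizes_arr / sizes_arr.sum()
        assert np.all(np.abs(alloc - quotas) < 1.0)

    def test_allocation_never_exceeds_caps(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            sizes = rng.integers(1, 20, size=rng.integers(2, 6)).astype(float)
            n = int(rng.integers(1, sizes.sum() + 1))
            alloc = _largest_remainder(sizes, n, sizes.astype(int))
            assert alloc.sum() == n
            assert np.all(alloc <= sizes)


class TestStratifiedPseudoabsences:
    def make_world(self):
        labels = np.ones((10, 10), int)
        labels[:, 5:] = 2
        strata = StrataMap(labels=labels, k=2)
        pres = OccurrenceSet("sp", np.arange(5), np.arange(5),
                             np.ones(5, int), "all", "presence_only")
        background = np.array([(r, c) for r in range(10) for c in range(10)])
        return strata, pres, background

    def test_default_n_equals_presence_count(self):
        strata, pres, background = self.make_world()
        absences = stratified_pseudoabsences(pres, strata, background, seed=1)
        assert len(absences) == 5  # equal size as the presence sample

    def test_presence_cells_excluded(self):
        strata, pres, background = self.make_world()
        absences = stratified_pseudoabsences(pres, strata, background, n=80, seed=2)
        taken = set(map(tuple, absences))
        assert taken.isdisjoint(set(map(tuple, pres.presence_cells)))
        assert len(taken) == 80  # without replacement

    def test_single_stratum_is_simple_random_sample(self):
        strata, pres, background = self.make_world()
        strata = StrataMap(labels=np.ones((10, 10), int), k=1)
        absences = stratified_pseudoabsences(pres, strata, background, n=10, seed=3)
        assert len(absences) == 10

    def test_proportional_allocation(self):
        strata, pres, background = self.make_world()
        # background after exclusion: 47 cells in stratum 1, 48 in stratum 2
        absences = stratified_pseudoabsences(pres, strata, background, n=20, seed=4)
        in_s2 = (absences[:, 1] >= 5).sum()
        assert abs(in_s2 - 10) <= 1

    def test_background_too_small(self):
        strata, pres, background = self.make_world()
        with pytest.raises(SizeError):
            stratified_pseudoabsences(pres, strata, background[:3], n=10, seed=0)


class TestSplitSample:
    def test_seventy_thirty_balanced(self):
        X = np.random.default_rng(0).normal(size=(100, 3))
        y = np.repeat([0, 1], 50)
        train, test = split_sample(make_training(X, y), seed=1)
        assert len(train.y) == 70 and len(test.y) == 30
        assert train.y.sum() == 35 and test.y.sum() == 15

    def test_partition_disjoint_exhaustive(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.4).astype(int)
        sample = make_training(X, y)
        sample.cells = np.arange(80).reshape(40, 2)
        train, test = split_sample(sample, seed=2)
        ids = lambda s: set(map(tuple, s.cells))
        assert ids(train) | ids(test) == ids(sample)
        assert ids(train).isdisjoint(ids(test))

    def test_class_proportions_stable_across_seeds(self):
        X = np.random.default_rng(2).normal(size=(60, 3))
        y = np.repeat([0, 1], 30)
        for seed in range(10):
            train, _ = split_sample(make_training(X, y), seed=seed)
            assert abs(train.y.sum() - (len(train.y) - train.y.sum())) <= 1

    def test_tiny_class_raises(self):
        X = np.zeros((5, 3))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(SplitError):
            split_sample(make_training(X, y), seed=0)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(80, 3))
    y = (X[:, 0] > 0).astype(int)
    X[:, 0] += np.where(y == 1, 2.0, -2.0)  # widen the margin
    return make_training(X, y)


class TestFitMember:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_training_auc_is_one(self, separable, family):
        m = fit_member(family, separable, seed=0)
        assert auc(separable.y, m.predict(separable.X)) == pytest.approx(1.0)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_predictions_are_probabilities(self, separable, family):
        m = fit_member(family, separable, seed=0)
        p = m.predict(np.random.default_rng(4).normal(scale=5, size=(50, 3)))
        assert np.all((p >= 0) & (p <= 1))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_no_signal_auc_near_half(self, family):
        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(500, 3))
            y = np.repeat([0, 1], 250)
            sample = make_training(X, y)
            train, test = split_sample(sample, seed=seed)
            m = fit_member(family, train, seed=seed)
            aucs.append(auc(test.y, m.predict(test.X)))
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_unknown_family(self, separable):
        with pytest.raises(ParameterError):
            fit_member("MAXENT", separable, seed=0)

    def test_glm_recovers_logistic_coefficients(self):
        """GLM member estimates of a known logistic simulation agree with an
        independent maximum-likelihood fit within 3 standard errors."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        beta = np.array([1.0, -1.0, 0.0])
        X = rng.normal(size=(2000, 3))
        p = 1 / (1 + np.exp(-(X @ beta)))
        y = (rng.random(2000) < p).astype(int)
        member = fit_member("GLM", make_training(X, y), seed=0)
        est = glm_linear_coefficients(member)
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        se = oracle.bse[1:]
        assert np.all(np.abs(est - beta) < 3 * se)
        # and the two routes agree with each other
        assert np.all(np.abs(est - oracle.params[1:]) < 3 * se)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_textbook_pair_counting(self):
        # 3 of 4 presence-absence pairs concordant
        assert auc([1, 1, 0, 0], [0.9, 0.4, 0.8, 0.2]) == 0.75

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 2000)
        assert auc(labels, rng.random(4000)) == pytest.approx(0.5, abs=0.03)

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(7)
        labels = (rng.random(100) < 0.4).astype(int)
        scores = rng.normal(size=100)
        base = auc(labels, scores)
        assert auc(labels, np.exp(scores)) == pytest.approx(base, abs=1e-12)
        from scipy.stats import rankdata
        assert auc(labels, rankdata(scores)) == pytest.approx(base, abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        scores=st.lists(st.integers(0, 4), min_size=4, max_size=30),
        data=st.data(),
    )
    def test_complement_property(self, scores, data):
        """Flipping all labels maps AUC to 1 - AUC, for any tie pattern."""
        n = len(scores)
        labels = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)))
        if labels.sum() in (0, n):
            return  # AUC undefined; covered by the error test
        s = np.array(scores, float)
        assert auc(labels, s) == pytest.approx(1.0 - auc(1 - labels, s), abs=1e-12)

    def test_equals_mann_whitney_u(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n1 = int(rng.integers(2, 15))
            n0 = int(rng.integers(2, 15))
            labels = np.concatenate([np.ones(n1, int), np.zeros(n0, int)])
            scores = rng.integers(0, 6, size=n1 + n0).astype(float)  # heavy ties
            u = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                             alternative="two-sided").statistic
            assert auc(labels, scores) == pytest.approx(u / (n1 * n0), abs=1e-12)


class _ConstModel:
    def __init__(self, value):
        self.value = np.asarray(value, float)

    def predict_proba_pos(self, X):
        if self.value.ndim == 0:
            return np.full(len(X), float(self.value))
        return np.resize(self.value, len(X))


def const_ensemble(aucs, values):
    members = [FittedMember("GLM", i, _ConstModel(v), test_auc=a)
               for i, (a, v) in enumerate(zip(aucs, values))]
    import pandas as pd
    weights = np.asarray(aucs, float) / np.sum(aucs)
    return SDMEnsemble(
        species="x", members=members, weights=weights, all_members=members,
        auc_threshold=0.7, eval_table=pd.DataFrame(), member_table=pd.DataFrame(),
        predictor_names=("BIO5", "BIO6", "BIO12"),
    )


class TestEnsembleRules:
    def test_threshold_is_strict(self):
        mask, weights = retain_members(np.array([0.8, 0.6]), 0.7)
        assert mask.tolist() == [True, False]
        assert weights.tolist() == [1.0]
        mask, _ = retain_members(np.array([0.8, 0.7]), 0.7)
        assert mask.tolist() == [True, False]  # exactly 0.7 excluded

    def test_all_below_threshold_raises(self):
        from nichecast.exceptions import EmptyEnsembleError
        with pytest.raises(EmptyEnsembleError):
            retain_members(np.array([0.5, 0.65]), 0.7)

    def test_hand_computed_weighted_mean(self):
        # (0.8*0.2 + 0.9*0.4) / 1.7
        out = weighted_consensus(np.array([0.8, 0.9]),
                                 np.array([[0.2], [0.4]]))
        assert out[0] == pytest.approx(0.305882352941, abs=1e-9)

    def test_constant_members_project_their_value(self, env50):
        ens = const_ensemble([0.8, 0.9], [0.3, 0.3])
        smap = predict_suitability(ens, env50)
        np.testing.assert_allclose(smap.values, 0.3, atol=1e-12)

    def test_consensus_bounded_by_members(self, env50):
        ens = const_ensemble([0.8, 0.9], [0.2, 0.6])
        smap = predict_suitability(ens, env50)
        assert np.all(smap.values >= 0.2 - 1e-12)
        assert np.all(smap.values <= 0.6 + 1e-12)

    def test_weighted_sum_matches_per_cell_loop(self):
        rng = np.random.default_rng(9)
        aucs = np.array([0.75, 0.85, 0.95])
        preds = rng.random((3, 100))
        out = weighted_consensus(aucs, preds)
        for j in range(100):
            manual = sum(a * preds[i, j] for i, a in enumerate(aucs)) / aucs.sum()
            assert out[j] == pytest.approx(manual, abs=1e-12)


@pytest.fixture(scope="module")
def ensemble(env50, strata50, warm_species):
    occ = sample_occurrences(warm_species, env50, 120, "presence_only",
                             "native", seed=11)
    return occ, build_ensemble(occ, env50, strata50, R=3,
                               families=("GLM", "GAM", "FDA"), seed=12)


class TestBuildEnsemble:
    def test_weights_positive_and_normalized(self, ensemble):
        _, ens = ensemble
        assert np.all(ens.weights > 0)
        assert ens.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert all(m.test_auc > ens.auc_threshold for m in ens.members)

    def test_member_table_audit(self, ensemble):
        _, ens = ensemble
        t = ens.member_table
        dropped = t[~t["retained"]]
        assert np.all(dropped["weight"] == 0.0)
        assert np.all(dropped["test_auc"] <= ens.auc_threshold)
        assert t[t["retained"]]["weight"].sum() == pytest.approx(1.0)
        assert len(t) == 9  # 3 replicates x 3 families

    def test_deterministic_given_seed(self, env50, strata50, warm_species):
        occ = sample_occurrences(warm_species, env50, 80, "presence_only",
                                 "native", seed=13)
        a = build_ensemble(occ, env50, strata50, R=2, families=("GLM",), seed=5)
        b = build_ensemble(occ, env50, strata50, R=2, families=("GLM",), seed=5)
        assert a.member_table["test_auc"].tolist() == b.member_table["test_auc"].tolist()
        np.testing.assert_array_equal(
            predict_suitability(a, env50).values, predict_suitability(b, env50).values)

    def test_transfer_self_consistency(self, ensemble, env50, strata50):
        occ, ens = ensemble
        a = evaluate_transfer(ens, occ, env50, strata50, seed=77)
        b = evaluate_transfer(ens, occ, env50, strata50, seed=77)
        assert a == b
        assert 0.0 <= a <= 1.0
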