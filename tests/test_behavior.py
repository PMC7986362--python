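"""Feature extraction, balanced forest, HMM estimation and Viterbi smoothing."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dialact.behavior import (
    STATES,
    BalancedRandomForest,
    BehaviourModel,
    estimate_hmm,
    evaluate_model,
    extract_features,
    train_balanced_rf,
    viterbi_smooth,
    viterbi_smooth_batch,
)
from dialact.raw_io import EpochSeries

from .conftest import make_trace


def gaussian_classes(rng, n_per_class: int, separation: float, n_classes: int = 2, d: int = 4):
    X, y = [], []
    for k in range(n_classes):
        mu = np.zeros(d)
        mu[k % d] = separation
        X.append(rng.normal(size=(n_per_class, d)) + mu)
        y += [STATES[k]] * n_per_class
    return np.concatenate(X), np.asarray(y, dtype=object)


def random_model(rng, n_states: int) -> BehaviourModel:
    def stoch(shape):
        m = rng.random(shape) + 0.05
        return m / m.sum(axis=-1, keepdims=True)

    return BehaviourModel(
        states=STATES[:n_states],
        forest=None,
        hmm_prior=stoch(n_states),
        hmm_transitions=stoch((n_states, n_states)),
        hmm_emission=stoch((n_states, n_states)),
    )


def brute_force_viterbi(obs, prior, A, B, tol=1e-9):
    """Exhaustive enumeration oracle: all maximum-probability state paths.

    Distinct paths can tie exactly (e.g. swapping two adjacent states
    inside a same-state bracket under equal observations), so the oracle
    returns the full argmax set; the decoder must produce a member.
    """
    n = len(prior)
    scored = []
    for path in itertools.product(range(n), repeat=len(obs)):
        lp = np.log(prior[path[0]]) + np.log(B[path[0], obs[0]])
        for t in range(1, len(obs)):
            lp += np.log(A[path[t - 1], path[t]]) + np.log(B[path[t], obs[t]])
        scored.append((lp, path))
    best_lp = max(lp for lp, _ in scored)
    return best_lp, {path for lp, path in scored if lp >= best_lp - tol}


class TestExtractFeatures:
    def test_static_epoch(self):
        trace = make_trace(np.tile([0, 0, 1.0], (750, 1)))  # one 30-s epoch at 25 Hz
        X, valid = extract_features(trace=trace)
        assert valid.all()
        assert X[0, 0] == pytest.approx(0.0)  # mean vm
        assert X[0, 1] == pytest.approx(0.0)  # sd vm
        assert X[0, 14] == pytest.approx(0.0, abs=1e-9)  # dominant power share

    def test_dominant_frequency_2hz(self):
        # 2 Hz oscillation riding on the gravity axis
        t = np.arange(750) / 25.0
        xyz = np.column_stack([1.0 + 0.3 * np.sin(2 * np.pi * 2.0 * t), 0 * t, 0 * t])
        X, valid = extract_features(trace=make_trace(xyz))
        assert valid.all()
        assert X[0, 13] == pytest.approx(2.0, abs=1.0 / 30.0)

    def test_epoch_tier_passthrough(self):
        n = 10
        feats = np.random.default_rng(0).normal(size=(n, 6))
        ep = EpochSeries(
            epoch_length_s=30.0,
            start=np.datetime64("2016-11-07", "ns")
            + (np.arange(n) * 30_000_000_000).astype("timedelta64[ns]"),
            vm_mg=np.ones(n),
            wear=np.ones(n, dtype=bool),
            features=feats,
        )
        X, valid = extract_features(epochs=ep)
        assert X is feats
        assert valid.all()

    def test_mostly_missing_epoch_invalid(self):
        xyz = np.tile([0, 0, 1.0], (750, 1))
        xyz[: 500, :] = np.nan  # > 50% missing
        X, valid = extract_features(trace=make_trace(xyz))
        assert not valid[0]


class TestBalancedForest:
    def test_clean_separation_high_oob(self):
        X, y = gaussian_classes(np.random.default_rng(0), 100, separation=6.0)
        forest = BalancedRandomForest(n_estimators=50, random_state=0).fit(X, y)
        assert forest.oob_accuracy_ > 0.95

    def test_permuted_labels_at_chance(self):
        rng = np.random.default_rng(1)
        X, y = gaussian_classes(rng, 100, separation=4.0, n_classes=5)
        forest = BalancedRandomForest(n_estimators=50, random_state=1).fit(X, rng.permutation(y))
        n = int(forest.oob_confusion_.sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.2) / n
        assert lo <= forest.oob_accuracy_ <= hi

    def test_balanced_sample_counts_equal(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 3))
        y = np.asarray(["walking"] * 30 + ["sedentary"] * 180 + ["sleep"] * 90, dtype=object)
        forest = BalancedRandomForest(n_estimators=10, random_state=2).fit(X, y)
        assert (forest.balanced_sample_counts_ == 30).all()

    def test_rare_class_rejected_by_name(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(105, 3))
        y = np.asarray(["sedentary"] * 100 + ["walking"] * 5, dtype=object)
        with pytest.raises(ValueError, match="walking"):
            BalancedRandomForest().fit(X, y)

    def test_reproducible_under_seed(self):
        X, y = gaussian_classes(np.random.default_rng(4), 50, separation=2.0, n_classes=3)
        a = BalancedRandomForest(n_estimators=20, random_state=7).fit(X, y)
        b = BalancedRandomForest(n_estimators=20, random_state=7).fit(X, y)
        np.testing.assert_array_equal(a.oob_confusion_, b.oob_confusion_)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestEstimateHmm:
    def test_hand_bigram_counts(self):
        # A,A,B with alpha=1 over 2 states: P(A->A) = (1+1)/(2+2) = 0.5
        prior, trans, _ = estimate_hmm(
            [np.asarray(["walking", "walking", "light_tasks"], dtype=object)],
            np.eye(2),
            alpha=1.0,
            states=STATES[:2],
        )
        assert trans[0, 0] == pytest.approx(0.5)
        assert trans[0, 1] == pytest.approx(0.5)

    def test_alpha_zero_requires_full_support(self):
        seqs = [np.asarray(["walking", "walking"], dtype=object)]
        with pytest.raises(ValueError):
            estimate_hmm(seqs, np.eye(2), alpha=0.0, states=STATES[:2])

    def test_identity_confusion_small_alpha_emission_near_identity(self):
        seqs = [np.asarray(list(STATES[:2]) * 10, dtype=object)]
        _, _, emission = estimate_hmm(seqs, 1000 * np.eye(2), alpha=1e-6, states=STATES[:2])
        np.testing.assert_allclose(emission, np.eye(2), atol=1e-6)

    def test_rows_stochastic(self):
        rng = np.random.default_rng(5)
        seqs = [
            np.asarray(rng.choice(STATES, size=50), dtype=object) for _ in range(3)
        ]
        prior, trans, emission = estimate_hmm(seqs, rng.integers(0, 20, (5, 5)), alpha=1.0)
        assert prior.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(trans.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(emission.sum(axis=1), 1.0, atol=1e-12)
        assert (trans > 0).all() and (emission > 0).all()


class TestViterbi:
    def test_matches_brute_force(self):
        # exhaustive-enumeration oracle on small random instances: the
        # decoded path must be a maximum-probability path
        rng = np.random.default_rng(0)
        lut = {s: i for i, s in enumerate(STATES)}
        for trial in range(50):
            n_states = int(rng.integers(2, 5))
            T = int(rng.integers(1, 9))
            model = random_model(rng, n_states)
            obs = rng.integers(0, n_states, size=T)
            _, optimal = brute_force_viterbi(
                obs, model.hmm_prior, model.hmm_transitions, model.hmm_emission
            )
            got = viterbi_smooth(np.asarray(model.states, dtype=object)[obs], model)
            assert tuple(lut[s] for s in got) in optimal

    def test_all_tied_paths_break_to_lowest_state(self):
        # fully uniform model: every path ties; documented tie-break picks
        # the lowest state index throughout
        n = 3
        model = BehaviourModel(
            states=STATES[:n], forest=None,
            hmm_prior=np.full(n, 1 / n),
            hmm_transitions=np.full((n, n), 1 / n),
            hmm_emission=np.full((n, n), 1 / n),
        )
        got = viterbi_smooth(np.asarray(STATES[:n], dtype=object)[[2, 1, 0, 2]], model)
        assert (got == STATES[0]).all()

    def test_empty_sequence(self):
        model = random_model(np.random.default_rng(1), 3)
        assert len(viterbi_smooth(np.asarray([], dtype=object), model)) == 0

    def test_uniform_dynamics_reduce_to_emission_argmax(self):
        rng = np.random.default_rng(2)
        n = 3
        emission = np.asarray([[0.8, 0.1, 0.1], [0.2, 0.7, 0.1], [0.3, 0.3, 0.4]])
        model = BehaviourModel(
            states=STATES[:n],
            forest=None,
            hmm_prior=np.full(n, 1 / n),
            hmm_transitions=np.full((n, n), 1 / n),
            hmm_emission=emission,
        )
        obs = rng.integers(0, n, size=30)
        got = viterbi_smooth(np.asarray(model.states, dtype=object)[obs], model)
        expected = np.asarray(model.states, dtype=object)[emission[:, obs].argmax(axis=0)]
        np.testing.assert_array_equal(got, expected)

    def test_isolated_discordant_observation_smoothed(self):
        n = 2
        sticky = np.asarray([[0.999, 0.001], [0.001, 0.999]])
        emission = np.asarray([[0.9, 0.1], [0.1, 0.9]])
        model = BehaviourModel(
            states=STATES[:n],
            forest=None,
            hmm_prior=np.asarray([0.5, 0.5]),
            hmm_transitions=sticky,
            hmm_emission=emission,
        )
        obs = np.asarray([0, 0, 0, 1, 0, 0, 0])
        got = viterbi_smooth(np.asarray(model.states, dtype=object)[obs], model)
        # log-odds: two 0.999->0.001 switches (~13.8) outweigh one 0.1->0.9
        # emission flip (~2.2), so the lone discordant epoch is absorbed
        assert (got == model.states[0]).all()

    def test_probability_likelihood_mode(self):
        # one-hot probabilities under uniform dynamics reduce to argmax;
        # sticky transitions absorb a weakly discordant epoch
        from dialact.behavior import viterbi_smooth_proba

        n = 2
        uniform = BehaviourModel(
            states=STATES[:n], forest=None,
            hmm_prior=np.full(n, 0.5),
            hmm_transitions=np.full((n, n), 0.5),
            hmm_emission=np.full((n, n), 0.5),
        )
        proba = np.asarray([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
        got = viterbi_smooth_proba(proba, uniform)
        np.testing.assert_array_equal(
            got, np.asarray(STATES[:n], dtype=object)[proba.argmax(axis=1)]
        )
        sticky = BehaviourModel(
            states=STATES[:n], forest=None,
            hmm_prior=np.full(n, 0.5),
            hmm_transitions=np.asarray([[0.99, 0.01], [0.01, 0.99]]),
            hmm_emission=np.full((n, n), 0.5),
        )
        proba = np.asarray([[0.9, 0.1], [0.9, 0.1], [0.45, 0.55], [0.9, 0.1]])
        got = viterbi_smooth_proba(proba, sticky)
        assert (got == STATES[0]).all()

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(3)
        model = random_model(rng, 4)
        obs = rng.integers(0, 4, size=(6, 40))
        batch = viterbi_smooth_batch(obs, model)
        names = np.asarray(model.states, dtype=object)
        for i in range(len(obs)):
            np.testing.assert_array_equal(names[batch[i]], viterbi_smooth(names[obs[i]], model))

    def test_hmmlearn_cross_check(self):
        # independent decoder on the same parameters
        from hmmlearn.hmm import CategoricalHMM

        rng = np.random.default_rng(4)
        model = random_model(rng, 3)
        obs = rng.integers(0, 3, size=200)
        ref = CategoricalHMM(n_components=3)
        ref.startprob_ = model.hmm_prior
        ref.transmat_ = model.hmm_transitions
        ref.emissionprob_ = model.hmm_emission
        ref.n_features = 3
        _, ref_path = ref.decode(obs.reshape(-1, 1), algorithm="viterbi")
        got = viterbi_smooth(np.asarray(model.states, dtype=object)[obs], model)
        np.testing.assert_array_equal(got, np.asarray(model.states, dtype=object)[ref_path])


def noisy_semimarkov_instance(rng, n_states=5, T=400, run_mean=20, noise=0.2):
    """True semi-Markov sequence plus uniform label noise and its HMM."""
    truth = []
    while len(truth) < T:
        s = int(rng.integers(0, n_states))
        truth += [s] * int(rng.geometric(1.0 / run_mean))
    truth = np.asarray(truth[:T])
    obs = truth.copy()
    flip = rng.random(T) < noise
    obs[flip] = (truth[flip] + rng.integers(1, n_states, size=flip.sum())) % n_states
    conf = np.full((n_states, n_states), 100 * noise / (n_states - 1))
    np.fill_diagonal(conf, 100 * (1 - noise))
    names = np.asarray(STATES[:n_states], dtype=object)
    prior, trans, emission = estimate_hmm([names[truth]], conf, alpha=1.0, states=STATES[:n_states])
    model = BehaviourModel(
        states=STATES[:n_states], forest=None,
        hmm_prior=prior, hmm_transitions=trans, hmm_emission=emission,
    )
    return truth, obs, model


class TestSmoothingValue:
    def test_smoothing_does_not_reduce_mean_accuracy(self):
        rng = np.random.default_rng(11)
        before, after = [], []
        for _ in range(50):
            truth, obs, model = noisy_semimarkov_instance(rng)
            names = np.asarray(model.states, dtype=object)
            decoded = viterbi_smooth(names[obs], model)
            before.append((obs == truth).mean())
            after.append((decoded == names[truth]).mean())
        assert np.mean(after) >= np.mean(before)
        assert np.mean(after) > np.mean(before) + 0.05  # typically a clear gain


class TestEvaluate:
    def test_identity(self):
        seq = np.asarray(["walking", "sleep", "sedentary"] * 10, dtype=object)
        m = evaluate_model(seq, seq)
        assert m["accuracy"] == 1.0
        assert m["kappa"] == pytest.approx(1.0)

    def test_half_matching_two_balanced_classes(self):
        truth = np.asarray(["walking", "sleep"] * 20, dtype=object)
        pred = np.asarray(["walking", "sleep"] * 10 + ["sleep", "walking"] * 10, dtype=object)
        m = evaluate_model(pred, truth, states=("walking", "sleep"))
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["kappa"] == pytest.approx(0.0)

    def test_hand_confusion_accuracy(self):
        # AA:40 AB:10 BA:20 BB:30 -> accuracy 70/100
        truth = np.asarray(["walking"] * 50 + ["sleep"] * 50, dtype=object)
        pred = np.asarray(
            ["walking"] * 40 + ["sleep"] * 10 + ["walking"] * 20 + ["sleep"] * 30, dtype=object
        )
        m = evaluate_model(pred, truth, states=("walking", "sleep"))
        assert m["accuracy"] == pytest.approx(0.70)
        assert m["confusion"][0, 0] == 40 and m["confusion"][1, 0] == 20

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_model(np.asarray(["walking"]), np.asarray(["walking", "sleep"]))

    def test_train_balanced_rf_end_to_end(self):
        rng = np.random.default_rng(6)
        X, y = gaussian_classes(rng, 80, separation=5.0, n_classes=3)
        model = train_balanced_rf(X, y, n_trees=30, seed=3, states=STATES[:3])
        assert model.forest.oob_accuracy_ > 0.9
        np.testing.assert_allclose(model.hmm_emission.sum(axis=1), 1.0, atol=1e-12)
        pred_idx = model.forest.predict(X).astype(int)
        decoded = viterbi_smooth(np.asarray(model.states, dtype=object)[pred_idx], model)
        assert (decoded == y).mean() > 0.9
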