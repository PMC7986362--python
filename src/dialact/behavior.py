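"""Functional-behaviour classification: balanced random forest + HMM smoothing.

Thirty-second accelerometer epochs are classified into five functional
behaviours — walking, light tasks, moderate-intensity activity, sedentary,
sleep — by a random forest whose per-tree bootstrap samples down-sample
every class to the rarest class's count (a "balanced" forest, so rare
behaviours such as walking are not swamped by sedentary time). The
forest's per-epoch labels are then treated as noisy observations of a
hidden state sequence and smoothed by Viterbi decoding under empirically
estimated prior/transition matrices, with the emission matrix taken from
the forest's out-of-bag confusion. Smoothing enforces temporally
plausible behaviour runs (people do not alternate sleep and walking at
30-s cadence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import cohen_kappa_score, confusion_matrix
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .raw_io import EpochSeries, RawTrace

__all__ = [
    "STATES",
    "BalancedRandomForest",
    "BehaviourModel",
    "extract_features",
    "train_balanced_rf",
    "estimate_hmm",
    "viterbi_smooth",
    "viterbi_smooth_batch",
    "evaluate_model",
]

STATES: tuple[str, ...] = ("walking", "light_tasks", "moderate", "sedentary", "sleep")

FEATURE_NAMES: tuple[str, ...] = (
    "mean_vm_mg",
    "sd_vm_mg",
    "mean_x",
    "mean_y",
    "mean_z",
    "sd_x",
    "sd_y",
    "sd_z",
    "cov_xy",
    "cov_xz",
    "cov_yz",
    "pitch_deg",
    "roll_deg",
    "dominant_freq_hz",
    "dominant_power_share",
    "power_0_1hz",
    "power_1_3hz",
    "power_3_5hz",
    "autocorr_1s",
)


# ---------------------------------------------------------------------------
# Feature extraction


def extract_features(
    epochs: EpochSeries | None = None,
    trace: RawTrace | None = None,
    epoch_s: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch feature matrix for classification.

    Epoch-tier input (an :class:`EpochSeries` carrying a feature matrix)
    passes the generator's features through unchanged. Raw-tier input
    computes time- and frequency-domain features from each 30-s window:
    ENMO mean/sd, per-axis moments and covariances, mean pitch/roll from
    the gravity direction, dominant frequency and its power share, fixed
    band powers and the 1-s autocorrelation.

    Returns ``(X, valid)``: ``valid`` flags epochs with at least half of
    their samples present.
    """
    if epochs is not None and epochs.features is not None:
        valid = np.isfinite(epochs.features).all(axis=1) & epochs.wear
        return epochs.features, valid
    if trace is None:
        raise ValueError("need either epoch-tier features or a raw trace")

    rate = trace.sample_rate_hz
    w = int(round(epoch_s * rate))
    n_ep = len(trace.t) // w
    X = np.full((n_ep, len(FEATURE_NAMES)), np.nan)
    valid = np.zeros(n_ep, dtype=bool)
    for i in range(n_ep):
        xyz = trace.xyz[i * w : (i + 1) * w]
        ok = np.isfinite(xyz).all(axis=1)
        if ok.sum() < w / 2:
            continue
        valid[i] = True
        s = xyz[ok]
        norms = np.linalg.norm(s, axis=1)
        enmo = np.maximum(norms - 1.0, 0.0) * 1000.0
        means = s.mean(axis=0)
        sds = s.std(axis=0, ddof=0)
        cov = np.cov(s.T, ddof=0)
        pitch = np.degrees(np.arctan2(means[0], np.hypot(means[1], means[2])))
        roll = np.degrees(np.arctan2(means[1], np.hypot(means[0], means[2])))
        # spectral features on the vector magnitude, mean removed
        vm0 = norms - norms.mean()
        spec = np.abs(np.fft.rfft(vm0)) ** 2
        freqs = np.fft.rfftfreq(len(vm0), d=1.0 / rate)
        spec[0] = 0.0
        total = spec.sum()
        k = int(np.argmax(spec))
        dom_f = freqs[k]
        dom_share = spec[k] / total if total > 0 else 0.0
        def band(lo: float, hi: float) -> float:
            m = (freqs >= lo) & (freqs < hi)
            return float(spec[m].sum() / total) if total > 0 else 0.0
        lag = int(round(rate))
        if len(vm0) > lag and vm0.std() > 0:
            ac = float(np.corrcoef(vm0[:-lag], vm0[lag:])[0, 1])
        else:
            ac = 0.0
        X[i] = [
            enmo.mean(),
            enmo.std(ddof=0),
            means[0],
            means[1],
            means[2],
            sds[0],
            sds[1],
            sds[2],
            cov[0, 1],
            cov[0, 2],
            cov[1, 2],
            pitch,
            roll,
            dom_f,
            dom_share,
            band(0.0, 1.0),
            band(1.0, 3.0),
            band(3.0, 5.0),
            ac,
        ]
    return X, valid


# ---------------------------------------------------------------------------
# Balanced random forest


class BalancedRandomForest(BaseEstimator, ClassifierMixin):
    """Random forest with per-tree class-balanced bootstrap samples.

    Each tree is grown on a bootstrap in which every class is down-sampled
    (with replacement) to the rarest class's count, so no behaviour
    dominates the split criterion. Out-of-bag (OOB) predictions — each
    point scored only by trees whose bootstrap excluded it — are
    accumulated into ``oob_confusion_``, which doubles as the HMM
    emission estimate downstream.

    Parameters follow sklearn conventions; fitted attributes carry a
    trailing underscore.
    """

    def __init__(
        self,
        n_estimators: int = 100,
        max_features: str | int | float = "sqrt",
        max_depth: int | None = None,
        min_class_count: int = 10,
        random_state: int | None = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.min_class_count = min_class_count
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per label")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_idx, minlength=len(self.classes_))
        for cls, c in zip(self.classes_, counts):
            if c < self.min_class_count:
                raise ValueError(
                    f"class {cls!r} has {c} epochs, fewer than the required {self.min_class_count}"
                )
        n_classes = len(self.classes_)
        n_per_class = int(counts.min())
        class_rows = [np.flatnonzero(y_idx == k) for k in range(n_classes)]
        rng = np.random.default_rng(self.random_state)

        self.estimators_ = []
        self.balanced_sample_counts_ = np.full((self.n_estimators, n_classes), n_per_class)
        oob_votes = np.zeros((len(X), n_classes), dtype=np.int32)
        for _ in range(self.n_estimators):
            idx = np.concatenate(
                [rng.choice(rows, size=n_per_class, replace=True) for rows in class_rows]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)),
            )
            tree.fit(X[idx], y_idx[idx])
            self.estimators_.append(tree)
            oob_mask = np.ones(len(X), dtype=bool)
            oob_mask[idx] = False
            if oob_mask.any():
                pred = tree.predict(X[oob_mask]).astype(int)
                oob_votes[np.flatnonzero(oob_mask), pred] += 1

        scored = oob_votes.sum(axis=1) > 0
        oob_pred = oob_votes.argmax(axis=1)
        self.oob_confusion_ = np.zeros((n_classes, n_classes), dtype=np.int64)
        np.add.at(self.oob_confusion_, (y_idx[scored], oob_pred[scored]), 1)
        tot = self.oob_confusion_.sum()
        self.oob_accuracy_ = float(np.trace(self.oob_confusion_) / tot) if tot else float("nan")
        self.n_features_in_ = X.shape[1]
        return self

    def _votes(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        votes = np.zeros((len(X), len(self.classes_)), dtype=np.int32)
        rows = np.arange(len(X))
        for tree in self.estimators_:
            votes[rows, tree.predict(X).astype(int)] += 1
        return votes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        votes = self._votes(X)
        return votes / votes.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[self._votes(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# HMM estimation and Viterbi smoothing


@dataclass
class BehaviourModel:
    """Trained balanced forest plus HMM smoothing parameters."""

    states: tuple[str, ...]
    forest: BalancedRandomForest
    hmm_prior: np.ndarray
    hmm_transitions: np.ndarray
    hmm_emission: np.ndarray

    def __post_init__(self) -> None:
        for name in ("hmm_prior", "hmm_transitions", "hmm_emission"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            sums = arr.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")
            if (arr <= 0).any():
                raise ValueError(f"{name} must be strictly positive (smoothing floor)")

    def state_index(self, labels: np.ndarray) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.states)}
        return np.asarray([lut[s] for s in labels], dtype=int)


def estimate_hmm(
    label_sequences: list[np.ndarray],
    oob_confusion: np.ndarray,
    alpha: float = 1.0,
    states: tuple[str, ...] = STATES,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate HMM parameters from labelled state sequences.

    prior = normalised state frequencies; transitions = row-normalised
    (bigram counts + alpha); emission = row-normalised (OOB confusion +
    alpha). ``alpha`` is an additive pseudo-count; ``alpha = 0`` is legal
    only when every bigram/emission cell was observed, since Viterbi
    decoding in log space needs strictly positive matrices.
    """
    if not label_sequences:
        raise ValueError("need at least one sequence")
    n = len(states)
    lut = {s: i for i, s in enumerate(states)}
    counts = np.zeros(n)
    bigrams = np.zeros((n, n))
    for seq in label_sequences:
        idx = np.asarray([lut[s] for s in np.asarray(seq)])
        np.add.at(counts, idx, 1)
        if len(idx) > 1:
            np.add.at(bigrams, (idx[:-1], idx[1:]), 1)
    conf = np.asarray(oob_confusion, dtype=float)
    if alpha == 0 and ((bigrams == 0).any() or (conf == 0).any()):
        raise ValueError("alpha=0 requires every bigram and emission cell observed")
    prior = (counts + alpha) / (counts + alpha).sum()
    transitions = (bigrams + alpha) / (bigrams + alpha).sum(axis=1, keepdims=True)
    emission = (conf + alpha) / (conf + alpha).sum(axis=1, keepdims=True)
    return prior, transitions, emission


def _viterbi_core(logB: np.ndarray, log_prior: np.ndarray, logA: np.ndarray) -> np.ndarray:
    """Max-a-posteriori path; ``logB`` is (T, n) observation log-likelihood.

    Ties break toward the lowest state index (argmax returns the first max).
    """
    T, n = logB.shape
    delta = log_prior + logB[0]
    back = np.zeros((T, n), dtype=np.int32)
    for t in range(1, T):
        cand = delta[:, None] + logA  # (from, to)
        back[t] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + logB[t]
    path = np.zeros(T, dtype=int)
    path[-1] = int(delta.argmax())
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi_smooth(observed, model: BehaviourModel) -> np.ndarray:
    """Viterbi-decode a sequence of predicted labels into smoothed states.

    Observations are the forest's argmax labels; the emission matrix
    P(observed label | true state) comes from the smoothed OOB confusion.
    Computed in log space; an empty sequence gives an empty path.
    """
    observed = np.asarray(observed)
    if len(observed) == 0:
        return np.asarray([], dtype=object)
    obs_idx = model.state_index(observed)
    logB = np.log(model.hmm_emission)[:, obs_idx].T  # (T, n)
    path = _viterbi_core(logB, np.log(model.hmm_prior), np.log(model.hmm_transitions))
    return np.asarray(model.states, dtype=object)[path]


def viterbi_smooth_proba(proba: np.ndarray, model: BehaviourModel, floor: float = 1e-12) -> np.ndarray:
    """Viterbi decoding with forest class-probability vectors as likelihoods.

    Alternative observation mode: instead of collapsing each epoch to its
    argmax label, the (T, n_states) probability matrix enters directly as
    the per-epoch likelihood of each state (floored for log space).
    """
    proba = np.asarray(proba, dtype=float)
    if len(proba) == 0:
        return np.asarray([], dtype=object)
    logB = np.log(np.maximum(proba, floor))
    path = _viterbi_core(logB, np.log(model.hmm_prior), np.log(model.hmm_transitions))
    return np.asarray(model.states, dtype=object)[path]


def viterbi_smooth_batch(obs_idx: np.ndarray, model: BehaviourModel) -> np.ndarray:
    """Vectorised Viterbi over many equal-length sequences.

    ``obs_idx`` is (n_seq, T) of observed state indices; returns decoded
    state indices of the same shape. Used to smooth one day per row across
    a whole cohort in a single pass.
    """
    n_seq, T = obs_idx.shape
    n = len(model.states)
    logE = np.log(model.hmm_emission)  # (state, obs)
    logA = np.log(model.hmm_transitions)
    delta = np.log(model.hmm_prior)[None, :] + logE[:, obs_idx[:, 0]].T
    back = np.zeros((T, n_seq, n), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, :, None] + logA[None, :, :]  # (seq, from, to)
        back[t] = cand.argmax(axis=1)
        delta = cand.max(axis=1) + logE[:, obs_idx[:, t]].T
    path = np.zeros((n_seq, T), dtype=np.int8)
    path[:, -1] = delta.argmax(axis=1)
    rows = np.arange(n_seq)
    for t in range(T - 1, 0, -1):
        path[:, t - 1] = back[t, rows, path[:, t]]
    return path.astype(int)


def train_balanced_rf(
    X: np.ndarray,
    y: np.ndarray,
    sequences: list[np.ndarray] | None = None,
    n_trees: int = 100,
    alpha: float = 1.0,
    seed: int | None = None,
    states: tuple[str, ...] = STATES,
) -> BehaviourModel:
    """Train the balanced forest and estimate HMM smoothing parameters.

    ``sequences`` are the contiguous true-label sequences (e.g. one per
    camera day) used for the transition bigrams; if omitted, ``y`` is
    treated as a single sequence.
    """
    forest = BalancedRandomForest(n_estimators=n_trees, random_state=seed)
    forest.fit(X, _encode(y, states))
    seqs = sequences if sequences is not None else [np.asarray(y)]
    # forest classes_ are indices into `states`; align confusion to full state set
    conf = np.zeros((len(states), len(states)))
    cls = forest.classes_.astype(int)
    conf[np.ix_(cls, cls)] = forest.oob_confusion_
    prior, transitions, emission = estimate_hmm(seqs, conf, alpha=alpha, states=states)
    return BehaviourModel(
        states=states,
        forest=forest,
        hmm_prior=prior,
        hmm_transitions=transitions,
        hmm_emission=emission,
    )


def _encode(y: np.ndarray, states: tuple[str, ...]) -> np.ndarray:
    lut = {s: i for i, s in enumerate(states)}
    return np.asarray([lut[s] for s in np.asarray(y)], dtype=int)


def evaluate_model(predicted, truth, states: tuple[str, ...] = STATES) -> dict:
    """Epoch-level accuracy, per-class precision/recall, Cohen's kappa, confusion."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lengths differ")
    labels = list(states)
    conf = confusion_matrix(truth, predicted, labels=labels)
    acc = float(np.trace(conf) / conf.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.diag(conf) / conf.sum(axis=1)
        precision = np.diag(conf) / conf.sum(axis=0)
    kappa = float(cohen_kappa_score(truth, predicted, labels=labels))
    return {
        "accuracy": acc,
        "kappa": kappa,
        "precision": dict(zip(labels, precision)),
        "recall": dict(zip(labels, recall)),
        "confusion": conf,
    }
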