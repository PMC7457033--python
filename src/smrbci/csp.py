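"""CSP feature extraction and task/idle decoding, offline and online.

Common spatial patterns (CSP) finds spatial filters w maximising the
variance ratio between two classes by jointly diagonalising the class
covariance matrices: here we solve C_task w = λ (C_task + C_idle) w, sort
filters by eigenvalue descending, and keep the first and last n_pairs rows
of the filter matrix. Features are normalised log-variances of the filtered
trial. Offline performance is run-wise 3-fold cross-validation with a
random-forest (or LDA) classifier; online performance replays the session
trial-by-trial from a run-1 model with supervised adaptation — after every
test trial the revealed label enters a 30-trial ring buffer on which the CSP
filters and the LDA are refit.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier

from .io import IDLE, TASK, EpochSet
from .montage import CHANNELS_7

logger = logging.getLogger(__name__)

N_PAIRS_DEFAULT = 3
SHRINKAGE_DEFAULT = 1e-4
ADAPTATION_BUFFER = 30

CHANNEL_SETS = {"31": None, "7": CHANNELS_7, 31: None, 7: CHANNELS_7}


@dataclass
class CovarianceEstimate:
    """Average trace-normalised spatial covariance of one class."""

    cov: np.ndarray
    n_trials: int


@dataclass
class CSPFilterBank:
    """Spatial filters (rows of W) with their generalised eigenvalues."""

    W: np.ndarray  # (channels, channels), rows sorted by eigenvalue desc
    eigenvalues: np.ndarray
    n_pairs: int = N_PAIRS_DEFAULT

    @property
    def selected(self) -> np.ndarray:
        """First and last ``n_pairs`` filters (most discriminative rows)."""
        n = self.W.shape[0]
        k = min(self.n_pairs, n // 2)
        idx = np.r_[np.arange(k), np.arange(n - k, n)]
        return self.W[idx]


@dataclass
class AccuracyRecord:
    patient_id: str
    session_index: int
    mode: str  # "online" | "offline"
    channel_set: str  # "31" | "7"
    classifier: str
    n_trials: int
    accuracy: float


def estimate_class_covariances(epochs_task: np.ndarray, epochs_idle: np.ndarray,
                               shrinkage: float = SHRINKAGE_DEFAULT
                               ) -> tuple[CovarianceEstimate, CovarianceEstimate]:
    """Per-class mean of per-trial trace-normalised covariances.

    Shrinkage C ← (1−γ)C + γ (tr C / n) I keeps the estimates positive
    definite on rank-deficient inputs (flat channels, few trials).
    """
    out = []
    for X in (epochs_task, epochs_idle):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[0] < 2:
            raise ValueError("need >= 2 trials per class, (trials, channels, samples)")
        covs = np.einsum("tcs,tds->tcd", X, X)
        traces = np.trace(covs, axis1=1, axis2=2)
        if np.any(traces <= 0):
            raise ValueError("trial with zero total power")
        C = (covs / traces[:, None, None]).mean(axis=0)
        C = 0.5 * (C + C.T)
        n = C.shape[0]
        if np.linalg.matrix_rank(C) < n:
            logger.warning("rank-deficient class covariance; shrinkage applied")
        C = (1.0 - shrinkage) * C + shrinkage * (np.trace(C) / n) * np.eye(n)
        out.append(CovarianceEstimate(C, X.shape[0]))
    return out[0], out[1]


def fit_csp(cov_task: CovarianceEstimate | np.ndarray,
            cov_idle: CovarianceEstimate | np.ndarray,
            n_pairs: int = N_PAIRS_DEFAULT) -> CSPFilterBank:
    """Solve C_task w = λ (C_task + C_idle) w; rows of W sorted by λ desc.

    The eigh normalisation gives the whitening property
    W (C_task + C_idle) Wᵀ = I, and every λ lies in [0, 1]; the idle-class
    eigenvalue of the same filter is 1 − λ.
    """
    C1 = cov_task.cov if isinstance(cov_task, CovarianceEstimate) else np.asarray(cov_task, float)
    C2 = cov_idle.cov if isinstance(cov_idle, CovarianceEstimate) else np.asarray(cov_idle, float)
    vals, vecs = linalg.eigh(C1, C1 + C2)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite generalised eigenvalues")
    order = np.argsort(vals)[::-1]
    return CSPFilterBank(vecs[:, order].T, vals[order], n_pairs)


def extract_features(epochs: np.ndarray, bank: CSPFilterBank) -> np.ndarray:
    """Normalised log-variance features per trial: log(var_i / Σ var).

    Accepts one epoch (channels, samples) or a stack of trials. The
    normalisation cancels global amplitude scaling of the epoch.
    """
    X = np.asarray(epochs, dtype=np.float64)
    single = X.ndim == 2
    if single:
        X = X[None]
    W = bank.selected
    if X.shape[1] != W.shape[1]:
        raise ValueError("epoch channel count does not match the filter bank")
    proj = np.einsum("fc,tcs->tfs", W, X)
    var = proj.var(axis=2)
    total = var.sum(axis=1, keepdims=True)
    tiny = np.finfo(float).tiny
    if np.any(var <= 0):
        logger.warning("zero-variance projection floored at machine epsilon")
    feats = np.log(np.maximum(var, tiny) / np.maximum(total, tiny))
    return feats[0] if single else feats


def make_classifier(kind: str, seed: int | None = 0):
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind in ("rf", "random_forest"):
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _select_channels(epochs: EpochSet, channel_set) -> EpochSet:
    try:
        subset = CHANNEL_SETS[channel_set]
    except KeyError:
        raise ValueError(f"unknown channel set {channel_set!r}") from None
    return epochs if subset is None else epochs.select_channels(list(subset))


def _fit_model(train: EpochSet, classifier_kind: str, seed: int | None,
               n_pairs: int = N_PAIRS_DEFAULT):
    task = train.data[train.labels == TASK]
    idle = train.data[train.labels == IDLE]
    c1, c2 = estimate_class_covariances(task, idle)
    bank = fit_csp(c1, c2, n_pairs)
    clf = make_classifier(classifier_kind, seed)
    feats = extract_features(train.data, bank)
    clf.fit(feats, train.labels)
    return bank, clf


def offline_accuracy(session_epochs: EpochSet, channel_set="31",
                     classifier_kind: str = "rf", *, patient_id: str = "",
                     session_index: int = 0, seed: int | None = 0,
                     shuffle_folds: bool = False,
                     n_pairs: int = N_PAIRS_DEFAULT) -> AccuracyRecord:
    """Run-wise k-fold cross-validated accuracy (folds = acquisition runs).

    With ``shuffle_folds`` the trials are instead split into k random
    equal-size folds (k = number of runs), seeded.
    """
    ep = _select_channels(session_epochs, channel_set)
    runs = np.unique(ep.runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for cross-validation")
    if shuffle_folds:
        rng = np.random.default_rng(seed)
        fold_of = rng.permutation(ep.n_trials) % len(runs)
    else:
        fold_of = np.searchsorted(runs, ep.runs)
    correct = total = 0
    for k in range(len(runs)):
        train = ep.select_trials(fold_of != k)
        test = ep.select_trials(fold_of == k)
        bank, clf = _fit_model(train, classifier_kind, seed, n_pairs)
        pred = clf.predict(extract_features(test.data, bank))
        correct += int((pred == test.labels).sum())
        total += test.n_trials
    return AccuracyRecord(patient_id, session_index, "offline", str(channel_set),
                          classifier_kind, total, correct / total)


def online_accuracy(session_epochs: EpochSet, channel_set="31", *,
                    patient_id: str = "", session_index: int = 0,
                    adapt: bool = True, buffer_size: int = ADAPTATION_BUFFER,
                    eval_runs: str = "post1", seed: int | None = 0,
                    n_pairs: int = N_PAIRS_DEFAULT) -> AccuracyRecord:
    """Simulated online decoding with supervised adaptation.

    Run 1 trains the initial CSP + LDA model; later trials are classified
    one at a time in acquisition order. After each trial the true label is
    revealed and pushed into a ``buffer_size``-trial ring buffer (seeded with
    the run-1 trials) and, if ``adapt``, CSP and LDA are refit on the buffer.
    ``eval_runs``: "post1" scores every trial after run 1; "run2" scores run-2
    trials only.
    """
    ep = _select_channels(session_epochs, channel_set)
    runs = np.unique(ep.runs)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for online evaluation")
    first = runs[0]
    train = ep.select_trials(ep.runs == first)
    bank, clf = _fit_model(train, "lda", seed, n_pairs)
    buffer: deque = deque(zip(train.data, train.labels), maxlen=buffer_size)

    test_mask = ep.runs != first
    if eval_runs == "run2":
        test_mask &= ep.runs == runs[1]
    elif eval_runs != "post1":
        raise ValueError(f"unknown eval_runs {eval_runs!r}")
    order = np.nonzero(test_mask)[0]
    correct = 0
    skipped_refits = 0
    for i in order:
        feats = extract_features(ep.data[i], bank)
        correct += int(clf.predict(feats[None])[0] == ep.labels[i])
        buffer.append((ep.data[i], ep.labels[i]))
        if adapt:
            labels = np.array([l for _, l in buffer])
            if len(set(labels)) < 2:
                skipped_refits += 1
                continue
            X = np.stack([x for x, _ in buffer])
            c1, c2 = estimate_class_covariances(X[labels == TASK], X[labels == IDLE])
            bank = fit_csp(c1, c2, n_pairs)
            clf = make_classifier("lda", seed)
            clf.fit(extract_features(X, bank), labels)
    if skipped_refits:
        logger.info("online adaptation: %d refit(s) skipped (single-class buffer)",
                    skipped_refits)
    return AccuracyRecord(patient_id, session_index, "online", str(channel_set),
                          "lda", len(order), correct / len(order))


def session_trend_summary(records: list[AccuracyRecord]):
    """Best session, first/last-six subgroup, and mean over 12 sessions.

    Ties for the best accuracy resolve to the latest session. The subgroup is
    "last_six" iff the best session index is 7 or later.
    """
    if not records:
        raise ValueError("no accuracy records")
    modes = {(r.mode, r.channel_set) for r in records}
    if len(modes) > 1:
        raise ValueError("records mix modes/channel sets")
    by_session = {r.session_index: r.accuracy for r in records}
    if len(by_session) != len(records):
        raise ValueError("duplicate session indices")
    n = len(by_session)
    sessions = sorted(by_session)
    accs = np.array([by_session[s] for s in sessions])
    # latest session wins ties
    best = sessions[n - 1 - int(np.argmax(accs[::-1]))]
    subgroup = "last_six" if best > n // 2 else "first_six"
    return best, subgroup, float(accs.mean())
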