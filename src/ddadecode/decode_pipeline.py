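"""Subject-dependent (SD) and subject-independent (SI) decoding schemes.

SD: for each subject, structure selection (delay search) and classifier
training use *pseudo-trials* — surrogate trials assembled from temporally
shuffled windows of that subject's data — and the final model is tested on
the original time-connected trials.  SI: leave-one-subject-out; delay
search and training pool the time-connected trials of all but one subject,
evaluation uses the held-out subject.

Per-triple Gaussian-kernel SVMs (one-vs-one, kernel scale 2) produce class
membership scores; the arithmetic mean of the per-triple scores is the
fused score, and its argmax the prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler

from .dda_core import DelayPair, features_from_windows
from .delay_search import DelayRanking, make_svm, search_delays
from .signal_io import TrialSet, group_triples
from .windowing import WindowSet, WindowSpec, window_tensor

__all__ = [
    "CVSpec",
    "DecodeModel",
    "EvalResult",
    "make_pseudo_trials",
    "train_sd",
    "evaluate_sd",
    "run_si_loo",
    "fuse_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVSpec:
    """Cross-validation scheme and pseudo-trial settings.

    ``windows_per_pseudo`` and ``n_pseudo`` default to the per-trial window
    count and the real trial count (per class and subject), keeping feature
    dimensionality identical between pseudo (training) and real (test)
    trials.
    """

    scheme: str = "SD"
    n_folds: int = 5
    seed: int = 0
    windows_per_pseudo: int | None = None
    n_pseudo: int | None = None

    def __post_init__(self) -> None:
        if self.scheme not in ("SD", "SI"):
            raise ValueError("scheme must be 'SD' or 'SI'")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class DecodeModel:
    """Trained decoder: best delay pair plus one classifier per triple.

    Each classifier is a standardize+SVM pipeline whose z-scoring
    parameters come from the training features only.
    """

    pair: DelayPair
    triples: list
    classifiers: list[Pipeline]
    classes: np.ndarray
    wspec: WindowSpec
    ranking: DelayRanking | None = None


@dataclass
class EvalResult:
    """Per-trial scores, fused scores, predictions and truth."""

    scores: np.ndarray          # (n_trials, n_classes) fused
    per_triple_scores: np.ndarray  # (n_triples, n_trials, n_classes)
    predictions: np.ndarray
    labels: np.ndarray
    subjects: np.ndarray
    classes: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predictions == self.labels))


def _windowset(ts: TrialSet, wspec: WindowSpec) -> WindowSet:
    return WindowSet(
        windows=window_tensor(ts.data, ts.fs, wspec),
        labels=ts.labels,
        subjects=ts.subjects,
        channel_names=list(ts.channel_names),
    )


def make_pseudo_trials(
    trialset: TrialSet, wspec: WindowSpec, cv_spec: CVSpec, seed: int | None = None
) -> WindowSet:
    """Non-connected surrogate trials from temporally shuffled windows.

    Within each class and subject, all (trial, window) slots form a pool;
    a seeded global permutation of the pool is chunked into pseudo-trials,
    so each window is used at most once and never twice within a
    pseudo-trial.  All channels of a slot stay together.  Labels and
    subjects are inherited.  Requesting more windows than the pool holds
    raises with the required minimum.
    """
    rng = np.random.default_rng(cv_spec.seed if seed is None else seed)
    ws = _windowset(trialset, wspec)
    n_trials, n_ch, n_win, L = ws.windows.shape
    out_w, out_lab, out_sub = [], [], []
    for subj in np.unique(ws.subjects):
        for cls in np.unique(ws.labels):
            mask = (ws.subjects == subj) & (ws.labels == cls)
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                continue
            wpp = cv_spec.windows_per_pseudo or n_win
            n_pseudo = cv_spec.n_pseudo or idx.size
            pool = idx.size * n_win
            need = n_pseudo * wpp
            if need > pool:
                raise ValueError(
                    f"subject {subj}, class {cls}: {need} windows requested but the "
                    f"pool holds only {pool}; need at least "
                    f"{int(np.ceil(need / n_win))} trials"
                )
            slots = rng.permutation(pool)[:need]
            trial_ix, win_ix = np.divmod(slots, n_win)
            grabbed = ws.windows[idx[trial_ix], :, win_ix]  # (need, n_ch, L)
            pseudo = grabbed.reshape(n_pseudo, wpp, n_ch, L).transpose(0, 2, 1, 3)
            out_w.append(pseudo)
            out_lab.extend([cls] * n_pseudo)
            out_sub.extend([subj] * n_pseudo)
    return WindowSet(
        windows=np.concatenate(out_w),
        labels=np.asarray(out_lab),
        subjects=np.asarray(out_sub),
        channel_names=list(ws.channel_names),
    )


def _fit_classifiers(ws: WindowSet, triples, pair: DelayPair, seed: int):
    fm = features_from_windows(ws, triples, pair)
    y = fm.labels
    n_feat = len(fm.feature_names) // len(triples)
    clfs = []
    for ti in range(len(triples)):
        Xt = fm.values[:, ti * n_feat : (ti + 1) * n_feat]
        if np.isnan(Xt).any():
            raise ValueError(f"degenerate features for triple {ti} at {pair}")
        clf = make_pipeline(StandardScaler(), make_svm(probability=True, seed=seed))
        clf.fit(Xt, y)
        clfs.append(clf)
    return clfs, np.unique(y)


def train_sd(
    trialset: TrialSet,
    wspec: WindowSpec,
    cv_spec: CVSpec,
    tau_max: int,
    triples=None,
) -> DecodeModel:
    """Subject-dependent training on one subject's data.

    Pseudo-trials drive both the exhaustive delay search (5-fold CV per
    candidate pair) and the final per-triple classifier fits at the
    selected pair.  The returned model carries the full delay ranking.
    """
    if len(np.unique(trialset.labels)) < 2:
        raise ValueError("need at least 2 classes")
    if len(np.unique(trialset.subjects)) > 1:
        logger.warning("train_sd received multiple subjects; pooling them")
    if triples is None:
        triples = group_triples(trialset.channel_names)
    pseudo = make_pseudo_trials(trialset, wspec, cv_spec)
    ranking, best = search_delays(pseudo, triples, wspec, cv_spec, tau_max)
    clfs, classes = _fit_classifiers(pseudo, triples, best, cv_spec.seed)
    return DecodeModel(
        pair=best, triples=list(triples), classifiers=clfs, classes=classes,
        wspec=wspec, ranking=ranking,
    )


def fuse_scores(per_triple_scores: np.ndarray, classes: np.ndarray):
    """Mean score across triples; argmax prediction (ties -> first class).

    ``per_triple_scores`` has shape (n_triples, n_trials, n_classes) with
    identical trial counts and class sets across triples.
    """
    arr = np.asarray(per_triple_scores, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n_triples, n_trials, n_classes)")
    fused = arr.mean(axis=0)
    preds = classes[np.argmax(fused, axis=1)]
    return fused, preds


def _score_windowset(model: DecodeModel, ws: WindowSet) -> EvalResult:
    fm = features_from_windows(ws, model.triples, model.pair)
    n_feat = len(fm.feature_names) // len(model.triples)
    expected = model.classifiers[0].named_steps["standardscaler"].n_features_in_
    if n_feat != expected:
        raise ValueError(f"feature dimension {n_feat} != model's {expected}")
    per_triple = []
    for ti, clf in enumerate(model.classifiers):
        Xt = fm.values[:, ti * n_feat : (ti + 1) * n_feat]
        proba = np.full((Xt.shape[0], len(model.classes)), np.nan)
        ok = np.isfinite(Xt).all(axis=1)
        if ok.any():
            p = clf.predict_proba(Xt[ok])
            order = [list(clf.classes_).index(c) for c in model.classes]
            proba[ok] = p[:, order]
        per_triple.append(proba)
    per_triple = np.stack(per_triple)
    fused, preds = fuse_scores(per_triple, model.classes)
    return EvalResult(
        scores=fused, per_triple_scores=per_triple, predictions=preds,
        labels=fm.labels, subjects=fm.subjects, classes=model.classes,
    )


def evaluate_sd(model: DecodeModel, trialset: TrialSet, wspec: WindowSpec | None = None) -> EvalResult:
    """Evaluate a trained model on time-connected trials.

    Features are extracted at the model's delay pair and standardized with
    the training-set parameters stored in each classifier pipeline.
    """
    ws = _windowset(trialset, wspec or model.wspec)
    return _score_windowset(model, ws)


def run_si_loo(
    trialset: TrialSet,
    wspec: WindowSpec,
    cv_spec: CVSpec,
    tau_max: int,
    triples=None,
) -> dict:
    """Leave-one-subject-out decoding over time-connected trials.

    For every held-out subject, delay search and classifier training use
    the pooled trials of all other subjects; returns one EvalResult per
    subject.
    """
    subjects = np.unique(trialset.subjects)
    if subjects.size < 2:
        raise ValueError("SI requires at least 2 subjects")
    if triples is None:
        triples = group_triples(trialset.channel_names)
    results = {}
    for subj in subjects:
        train_ts = trialset.subject_subset([s for s in subjects if s != subj])
        test_ts = trialset.subject_subset(subj)
        if test_ts.n_trials == 0:
            logger.warning("subject %s has no trials; skipped", subj)
            continue
        train_ws = _windowset(train_ts, wspec)
        ranking, best = search_delays(train_ws, triples, wspec, cv_spec, tau_max)
        clfs, classes = _fit_classifiers(train_ws, triples, best, cv_spec.seed)
        model = DecodeModel(
            pair=best, triples=list(triples), classifiers=clfs, classes=classes,
            wspec=wspec, ranking=ranking,
        )
        results[subj] = _score_windowset(model, _windowset(test_ts, wspec))
    return results
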