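"""Exhaustive delay-pair search: score, rank, min-max scale, select.

Every ordered pair (tau1, tau2) with 1 <= tau_i <= tau_max and
tau1 != tau2 is scored by cross-validated classification performance of
the features it induces; per-unit ranks (one unit per subject/triple,
rank 1 = worst) are averaged and min-max scaled to [0, 1].  The exact
diagonal of the resulting grid is missing-coded because the model
structure requires two distinct delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .dda_core import DelayPair, features_from_windows
from .signal_io import TrialSet
from .windowing import WindowSet, WindowSpec, window_tensor

__all__ = [
    "DelayRanking",
    "candidate_pairs",
    "score_pair",
    "rank_pairs",
    "select_best",
    "search_delays",
]

#: Gaussian kernel scale s in K(x, y) = exp(-||x - y||^2 / s^2).
KERNEL_SCALE = 2.0


def make_svm(probability: bool = False, seed: int | None = None):
    """Gaussian-kernel SVM, one-vs-one coding, kernel scale 2.

    With ``probability`` the machine is wrapped in Platt calibration so it
    emits pairwise-coupled class membership estimates in [0, 1].
    """
    svc = SVC(kernel="rbf", gamma=1.0 / KERNEL_SCALE**2, random_state=seed)
    if probability:
        return CalibratedClassifierCV(svc, ensemble=False)
    return svc


@dataclass
class DelayRanking:
    """Min-max-scaled mean-rank grid over candidate delay pairs.

    ``grid[t1-1, t2-1]`` is 0 for the worst pair and 1 for the best; the
    diagonal (and any unscored pair) is NaN.  Raw per-pair scores are
    retained in ``scores``.
    """

    grid: np.ndarray
    tau_max: int
    scores: dict = field(default_factory=dict)

    def value(self, d: DelayPair) -> float:
        return float(self.grid[d.tau1 - 1, d.tau2 - 1])


def candidate_pairs(tau_max: int) -> list[DelayPair]:
    """All ordered off-diagonal pairs up to tau_max, lexicographic order."""
    if tau_max < 2:
        raise ValueError("tau_max must be >= 2")
    return [
        DelayPair(t1, t2)
        for t1 in range(1, tau_max + 1)
        for t2 in range(1, tau_max + 1)
        if t1 != t2
    ]


def _as_windowset(data, wspec: WindowSpec) -> WindowSet:
    if isinstance(data, WindowSet):
        return data
    if isinstance(data, TrialSet):
        return WindowSet(
            windows=window_tensor(data.data, data.fs, wspec),
            labels=data.labels,
            subjects=data.subjects,
            channel_names=list(data.channel_names),
        )
    raise TypeError("expected TrialSet or WindowSet")


def _problem_metric(labels: np.ndarray) -> str:
    """Accuracy for balanced multiclass, macro-AUC for binary/unbalanced."""
    _, counts = np.unique(labels, return_counts=True)
    if len(counts) == 2 or counts.min() != counts.max():
        return "macro_auc"
    return "accuracy"


def score_pair(data, triples, d: DelayPair, wspec: WindowSpec, cv_spec) -> np.ndarray:
    """Cross-validated score of one delay pair, one value per triple.

    ``data`` is a TrialSet or an already-windowed WindowSet (pseudo-trials).
    Scoring is stratified k-fold with a standardize+SVM pipeline; balanced
    multiclass problems are scored by accuracy, binary or unbalanced ones
    by macro one-vs-all AUC.  Degenerate (NaN) features give a NaN score.
    """
    from .evalmetrics import roc_ovr  # local import: evalmetrics is leaf-level

    ws = _as_windowset(data, wspec)
    fm = features_from_windows(ws, triples, d)
    y = fm.labels
    classes = np.unique(y)
    metric = _problem_metric(y)
    n_feat = len(fm.feature_names) // len(triples)
    skf = StratifiedKFold(n_splits=cv_spec.n_folds, shuffle=True, random_state=cv_spec.seed)
    out = np.full(len(triples), np.nan)
    for ti in range(len(triples)):
        Xt = fm.values[:, ti * n_feat : (ti + 1) * n_feat]
        if np.isnan(Xt).any():
            continue
        fold_scores = []
        for tr, te in skf.split(Xt, y):
            clf = make_pipeline(StandardScaler(), make_svm(seed=cv_spec.seed))
            clf.fit(Xt[tr], y[tr])
            if metric == "accuracy":
                fold_scores.append(float(np.mean(clf.predict(Xt[te]) == y[te])))
            else:
                dec = clf.decision_function(Xt[te])
                if dec.ndim == 1:  # binary: score for the second class
                    dec = np.column_stack([-dec, dec])
                _, _, aucs = roc_ovr(dec, y[te], classes=classes)
                fold_scores.append(float(np.nanmean(aucs)))
        out[ti] = float(np.mean(fold_scores))
    return out


def rank_pairs(scores: dict) -> DelayRanking:
    """Rank pairs per unit (rank 1 = worst), average, min-max scale.

    ``scores`` maps each DelayPair to a scalar or an array of per-unit
    scores (e.g. one per subject and triple).  Missing (NaN) scores are
    excluded from a unit's ranking.  If every pair scores identically the
    scaling is degenerate and the grid is filled with 0.5.
    """
    pairs = sorted(scores)
    if len(pairs) < 2:
        raise ValueError("need at least 2 scored pairs")
    mat = np.array([np.atleast_1d(np.asarray(scores[p], dtype=float)) for p in pairs])
    # mat: (n_pairs, n_units); rank within each unit across pairs
    ranks = np.full_like(mat, np.nan)
    for u in range(mat.shape[1]):
        col = mat[:, u]
        ok = np.isfinite(col)
        if ok.any():
            ranks[ok, u] = rankdata(col[ok])
    mean_rank = np.full(len(pairs), np.nan)
    for i in range(len(pairs)):
        ok = np.isfinite(ranks[i])
        if ok.any():
            mean_rank[i] = ranks[i, ok].mean()
    tau_max = max(max(p.tau1, p.tau2) for p in pairs)
    grid = np.full((tau_max, tau_max), np.nan)
    finite = mean_rank[np.isfinite(mean_rank)]
    if finite.size:
        lo, hi = finite.min(), finite.max()
        for p, r in zip(pairs, mean_rank):
            if not np.isfinite(r):
                continue
            grid[p.tau1 - 1, p.tau2 - 1] = 0.5 if hi == lo else (r - lo) / (hi - lo)
    return DelayRanking(grid=grid, tau_max=tau_max, scores=dict(scores))


def select_best(ranking: DelayRanking) -> DelayPair:
    """Pair with maximal scaled rank; ties broken by smaller tau1+tau2,
    then lexicographically."""
    grid = ranking.grid
    if not np.isfinite(grid).any():
        raise ValueError("ranking has no scored pairs")
    best = np.nanmax(grid)
    cands = [
        DelayPair(int(i) + 1, int(j) + 1)
        for i, j in zip(*np.nonzero(grid == best))
    ]
    return min(cands, key=lambda p: (p.tau1 + p.tau2, p.tau1, p.tau2))


def search_delays(data, triples, wspec: WindowSpec, cv_spec, tau_max: int):
    """Exhaustive search: score all candidate pairs, rank, select the best.

    Returns ``(ranking, best_pair)``.  Windowing is done once and reused
    across pairs.
    """
    ws = _as_windowset(data, wspec)
    scores = {d: score_pair(ws, triples, d, wspec, cv_spec) for d in candidate_pairs(tau_max)}
    ranking = rank_pairs(scores)
    return ranking, select_best(ranking)
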