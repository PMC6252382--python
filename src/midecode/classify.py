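"""Pairwise linear-SVM classification with nested cross-validated feature
subset selection.

The procedure distinguishes two task conditions from 1 s EEG segments:

* three-layer nested cross-validation — an outer 3-fold split estimates
  generalization; within each outer training set a middle 5-fold loop
  assesses feature-selection consistency; within each middle training set an
  inner 5-fold loop scores candidate feature vectors;
* greedy forward selection over a t-test ranking, gated by monotone
  accuracy/sensitivity/specificity constraints, capped at 30 features during
  the search and 31 after cross-run consensus voting;
* all folds group segments by trial: the six sub-segments of a trial never
  straddle a fold boundary, so no trial leaks between training and test data
  at any layer.

Accuracies are pooled counts of correctly classified segments, which makes
them directly comparable with the maximum-chance criterion statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spectral import FeatureTable

__all__ = [
    "ClassifierParams",
    "FoldPlan",
    "EvalResult",
    "SelectionResult",
    "ClassificationOutcome",
    "make_fold_plan",
    "train_linear_svm",
    "rank_features",
    "evaluate_feature_set",
    "greedy_select",
    "consensus_select",
    "nested_classify",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable constants of the classification pipeline."""

    C: float = 1.0
    standardize: bool = True
    max_features: int = 30  # cap during greedy search
    max_consensus: int = 31  # cap on the final consensus vector
    sensitivity_threshold: float = 0.75
    specificity_threshold: float = 0.5
    outer_folds: int = 3
    middle_folds: int = 5
    inner_folds: int = 5


@dataclass(frozen=True)
class FoldPlan:
    """Trial-grouped partition of segment indices into k folds."""

    layer: str  # "outer" | "middle" | "inner"
    folds: tuple[np.ndarray, ...]
    grouping: np.ndarray  # trial id per segment (aligned with the index space)

    def test_train(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        test = self.folds[i]
        train = np.concatenate([f for j, f in enumerate(self.folds) if j != i])
        return test, np.sort(train)

    def assert_no_leakage(self) -> None:
        for i, fi in enumerate(self.folds):
            trials_i = set(self.grouping[fi].tolist())
            for fj in self.folds[i + 1 :]:
                overlap = trials_i & set(self.grouping[fj].tolist())
                if overlap:
                    raise AssertionError(f"trials {sorted(overlap)} span folds")


def make_fold_plan(
    condition: np.ndarray,
    trial_id: np.ndarray,
    k: int,
    seed: int,
    layer: str = "outer",
    indices: np.ndarray | None = None,
) -> FoldPlan:
    """Seeded trial-level split into k folds, stratified by condition.

    Whole trials (all six sub-segments) are assigned to folds; per condition
    the trial counts across folds differ by at most one.  ``indices``
    restricts the plan to a subset of segments (still indexed in the original
    space), which is how inner plans are built on outer training sets.
    """
    condition = np.asarray(condition)
    trial_id = np.asarray(trial_id)
    if indices is None:
        indices = np.arange(condition.size)
    rng = np.random.default_rng(seed)
    fold_members: list[list[int]] = [[] for _ in range(k)]
    for cond in sorted(set(condition[indices].tolist())):
        sel = indices[condition[indices] == cond]
        trials = np.unique(trial_id[sel])
        if trials.size < k:
            raise ValueError(
                f"condition {cond!r} has {trials.size} trials, fewer than {k} folds"
            )
        rng.shuffle(trials)
        for f, chunk in enumerate(np.array_split(trials, k)):
            members = sel[np.isin(trial_id[sel], chunk)]
            fold_members[f].extend(members.tolist())
    folds = tuple(np.sort(np.array(f, dtype=int)) for f in fold_members)
    return FoldPlan(layer=layer, folds=folds, grouping=trial_id)


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, standardize: bool = True
) -> Pipeline:
    """Soft-margin linear SVM (optionally on standardized features).

    Returns a fitted predictor whose decision function is a deterministic
    linear form; predictions are the sign of the decision value.
    """
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data contains a single class")
    steps = []
    if standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="linear", C=C)))
    return Pipeline(steps).fit(np.asarray(X, float), y)


def rank_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Feature indices sorted by ascending two-sample pooled-variance t-test p.

    Zero-variance features get p := 1 and therefore rank last; ties keep the
    original index order.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    labels = sorted(set(y.tolist()))
    if len(labels) != 2:
        raise ValueError("rank_features needs exactly two classes")
    a, b = X[y == labels[0]], X[y == labels[1]]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 samples per class")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    from scipy.stats import t as t_dist

    p = 2.0 * t_dist.sf(np.abs(t), df=na + nb - 2)
    p = np.where(denom == 0, 1.0, p)
    return np.argsort(p, kind="stable")


@dataclass(frozen=True)
class EvalResult:
    """Pooled correct counts of one cross-validated evaluation.

    ``pos`` refers to the first condition of the pair (sensitivity), ``neg``
    to the second (specificity).
    """

    correct: int
    n: int
    correct_pos: int
    n_pos: int
    correct_neg: int
    n_neg: int

    @property
    def accuracy(self) -> float:
        return self.correct / self.n

    @property
    def sensitivity(self) -> float:
        return self.correct_pos / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity(self) -> float:
        return self.correct_neg / self.n_neg if self.n_neg else float("nan")


def _score_fold(model, X, y, pos_label) -> tuple[int, int, int, int, int, int]:
    pred = model.predict(X)
    correct = pred == y
    pos = y == pos_label
    return (
        int(correct.sum()), len(y),
        int(correct[pos].sum()), int(pos.sum()),
        int(correct[~pos].sum()), int((~pos).sum()),
    )


def evaluate_feature_set(
    X: np.ndarray,
    y: np.ndarray,
    feature_idx,
    fold_plan: FoldPlan,
    pos_label,
    params: ClassifierParams = ClassifierParams(),
) -> EvalResult:
    """Pooled cross-validated accuracy of one feature subset."""
    feature_idx = np.asarray(feature_idx, dtype=int)
    if feature_idx.size == 0:
        raise ValueError("empty feature set")
    totals = np.zeros(6, dtype=int)
    for i in range(len(fold_plan.folds)):
        test, train = fold_plan.test_train(i)
        model = train_linear_svm(
            X[np.ix_(train, feature_idx)], y[train], params.C, params.standardize
        )
        totals += np.array(
            _score_fold(model, X[np.ix_(test, feature_idx)], y[test], pos_label)
        )
    return EvalResult(*totals.tolist())


@dataclass(frozen=True)
class GreedyResult:
    selected: tuple[int, ...]
    final: EvalResult
    trace: tuple[dict, ...] = field(repr=False)


def greedy_select(
    ranking: np.ndarray,
    eval_fn,
    params: ClassifierParams = ClassifierParams(),
) -> GreedyResult:
    """Greedy forward selection down a feature ranking.

    Starts from the top-ranked feature and walks the ranking; a candidate is
    accepted iff (a) pooled accuracy is at least the best accuracy of any
    previously accepted vector, (b) while the best sensitivity so far is below
    0.75 the candidate may not reduce it, and (c) while the best specificity
    so far is below 0.5 the candidate must strictly improve it.  The walk
    stops when the ranking is exhausted, 30 features are accepted, or the run
    of consecutive rejections exceeds 10% of the available features (at least
    100 candidates).
    """
    ranking = np.asarray(ranking, dtype=int)
    n_features = ranking.size
    streak_limit = max(math.ceil(0.10 * n_features), 100)

    selected = [int(ranking[0])]
    best = eval_fn(selected)
    best_correct = best.correct
    best_sens = best.sensitivity
    best_spec = best.specificity
    trace = [
        {"feature": selected[0], "accepted": True, "accuracy": best.accuracy,
         "sensitivity": best.sensitivity, "specificity": best.specificity}
    ]
    streak = 0
    for cand in ranking[1:]:
        if len(selected) >= params.max_features:
            break
        res = eval_fn(selected + [int(cand)])
        ok = res.correct >= best_correct
        if ok and best_sens < params.sensitivity_threshold:
            ok = res.sensitivity >= best_sens
        if ok and best_spec < params.specificity_threshold:
            ok = res.specificity > best_spec
        trace.append(
            {"feature": int(cand), "accepted": bool(ok), "accuracy": res.accuracy,
             "sensitivity": res.sensitivity, "specificity": res.specificity}
        )
        if ok:
            selected.append(int(cand))
            best = res
            best_correct = max(best_correct, res.correct)
            best_sens = max(best_sens, res.sensitivity)
            best_spec = max(best_spec, res.specificity)
            streak = 0
        else:
            streak += 1
            if streak > streak_limit:
                break
    return GreedyResult(selected=tuple(selected), final=best, trace=tuple(trace))


@dataclass(frozen=True)
class SelectionResult:
    """Aggregate of the five middle-layer selection runs for one outer fold."""

    runs: tuple[tuple[int, ...], ...]
    selection_counts: dict[int, int]
    consensus: tuple[int, ...]
    mean_run_length: float
    run_accuracies: tuple[float, ...]
    traces: tuple[tuple[dict, ...], ...] = field(repr=False, default=())


def consensus_select(
    runs,
    rank_position: dict[int, int],
    max_consensus: int = 31,
) -> tuple[tuple[int, ...], dict[int, int], float]:
    """Consensus over exactly five selection runs.

    Keeps features selected in at least 2 of 5 runs (falling back to 1 of 5 if
    that is empty); if the consensus exceeds the mean run length, only the 31
    most-selected features are retained, ties broken by better t-test rank.
    """
    runs = [tuple(r) for r in runs]
    if len(runs) != 5:
        raise ValueError("consensus requires exactly 5 selection runs")
    counts: dict[int, int] = {}
    for run in runs:
        for f in set(run):
            counts[f] = counts.get(f, 0) + 1
    if not counts:
        raise ValueError("all selection runs are empty (degenerate data)")
    mean_len = sum(len(r) for r in runs) / 5.0
    chosen = [f for f, c in counts.items() if c >= 2]
    if not chosen:
        chosen = list(counts)
    big = max(rank_position.values(), default=0) + 1
    chosen.sort(key=lambda f: (-counts[f], rank_position.get(f, big), f))
    if len(chosen) > mean_len:
        chosen = chosen[:max_consensus]
    return tuple(chosen), counts, mean_len


@dataclass(frozen=True)
class ClassificationOutcome:
    """Pooled outer-fold result of one pairwise classification run."""

    h0: int  # correctly classified outer-test segments, pooled
    n: int  # total outer-test segments (= all segments)
    correct_pos: int
    n_pos: int
    correct_neg: int
    n_neg: int
    pair: tuple[str, str]
    selections: tuple[SelectionResult, ...]
    outer_plan: FoldPlan
    seed: int
    identity: dict = field(default_factory=dict)

    @property
    def accuracy(self) -> float:
        return self.h0 / self.n

    @property
    def sensitivity(self) -> float:
        return self.correct_pos / self.n_pos

    @property
    def specificity(self) -> float:
        return self.correct_neg / self.n_neg

    @property
    def n_features(self) -> float:
        """Mean consensus feature-vector length over outer folds."""
        return float(np.mean([len(s.consensus) for s in self.selections]))


def nested_classify(
    features: FeatureTable,
    condition: np.ndarray,
    trial_id: np.ndarray,
    pair: tuple[str, str],
    params: ClassifierParams = ClassifierParams(),
    seed: int = 0,
    identity: dict | None = None,
) -> ClassificationOutcome:
    """Three-layer nested cross-validated classification of one condition pair.

    The outer 3-fold plan pools every segment into a test set exactly once, so
    ``h0`` out of ``n`` is directly comparable with the maximum-chance
    criterion.
    """
    X = features.values
    y = np.asarray(condition)
    trial_id = np.asarray(trial_id)
    present = set(y.tolist())
    if present != set(pair):
        raise ValueError(f"expected exactly the conditions {pair}, got {sorted(present)}")
    pos_label = pair[0]

    rng = np.random.default_rng(seed)
    seeds = iter(rng.integers(0, 2**31 - 1, size=1 + params.outer_folds * (1 + params.middle_folds)).tolist())

    outer = make_fold_plan(y, trial_id, params.outer_folds, next(seeds), "outer")
    outer.assert_no_leakage()

    totals = np.zeros(6, dtype=int)
    selections: list[SelectionResult] = []
    for i in range(params.outer_folds):
        test_idx, train_idx = outer.test_train(i)
        middle = make_fold_plan(
            y, trial_id, params.middle_folds, next(seeds), "middle", indices=train_idx
        )
        middle.assert_no_leakage()
        runs, accs, traces = [], [], []
        rank_position: dict[int, int] = {}
        for j in range(params.middle_folds):
            _, mid_train = middle.test_train(j)
            ranking = rank_features(X[mid_train], y[mid_train])
            for pos, f in enumerate(ranking):
                f = int(f)
                if pos < rank_position.get(f, len(ranking)):
                    rank_position[f] = pos
            inner = make_fold_plan(
                y, trial_id, params.inner_folds, next(seeds), "inner", indices=mid_train
            )
            inner.assert_no_leakage()

            # inner evaluation indexes X in the original segment space
            def eval_fn(feat, _inner=inner):
                return evaluate_feature_set(X, y, feat, _inner, pos_label, params)

            result = greedy_select(ranking, eval_fn, params)
            runs.append(result.selected)
            accs.append(result.final.accuracy)
            traces.append(result.trace)
        consensus, counts, mean_len = consensus_select(
            runs, rank_position, params.max_consensus
        )
        selections.append(
            SelectionResult(
                runs=tuple(runs),
                selection_counts=counts,
                consensus=consensus,
                mean_run_length=mean_len,
                run_accuracies=tuple(accs),
                traces=tuple(traces),
            )
        )
        model = train_linear_svm(
            X[np.ix_(train_idx, np.asarray(consensus))], y[train_idx],
            params.C, params.standardize,
        )
        totals += np.array(
            _score_fold(model, X[np.ix_(test_idx, np.asarray(consensus))],
                        y[test_idx], pos_label)
        )

    return ClassificationOutcome(
        h0=int(totals[0]),
        n=int(totals[1]),
        correct_pos=int(totals[2]),
        n_pos=int(totals[3]),
        correct_neg=int(totals[4]),
        n_neg=int(totals[5]),
        pair=tuple(pair),
        selections=tuple(selections),
        outer_plan=outer,
        seed=seed,
        identity=identity or {},
    )
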