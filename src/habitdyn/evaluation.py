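"""Model evaluation: nested grouped CV, metrics battery, McNemar tests.

The comparison protocol is a two-level hierarchical k-fold cross-validation.
Participants (never single days) are partitioned into k folds, so no
person contributes to both training and testing of the same model.  In each
outer round one fold is held out for testing; inside the remaining k-1
training folds, one fold is reserved as the tuning test set and the other
k-2 train candidate models during hyperparameter search (1000-step random
search over the five dynamics parameters, each drawn from U(0,1); 100-step
grid over the discount gamma in {0.01, ..., 1.00}).  The search objective
is AUC on the tuning fold; the first best candidate wins ties, which makes
the search reproducible under a fixed seed.  Out-of-fold predictions are
pooled across outer rounds into a single ROC curve, and threshold-dependent
metrics are computed at each model's own Youden-optimal threshold.

Study 1 uses 9 folds (4 participants each), Study 2 uses 5 folds (15 each);
both are just :func:`make_group_folds` calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .features import ModelSpec, StudyArrays, feature_matrix
from .dynamics import AccessParams, HabitParams
from .modeling import DegenerateFitError, FittedClassifier, fit_logistic, predict_proba

__all__ = [
    "CVPlan",
    "TuningBudget",
    "CVResult",
    "MetricsReport",
    "McNemarResult",
    "TransferResult",
    "ComparisonResult",
    "UndefinedMetricError",
    "make_group_folds",
    "roc_auc",
    "optimal_threshold",
    "metrics_report",
    "no_skill_accuracy",
    "mcnemar_test",
    "tune_parameters",
    "nested_cv",
    "cross_dataset_evaluate",
    "compare_models",
    "tuning_curve",
    "default_budget",
]

THEORY_PARAM_NAMES = ("hdp", "hgp", "adp", "agp_beh", "agp_rem")


class UndefinedMetricError(ValueError):
    """Raised when a metric needs both classes and only one is present."""


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVPlan:
    """Participant-grouped fold assignment (fold sizes differ by at most 1)."""

    k: int
    assignment: Mapping[str, int]
    seed: int

    def fold_of(self, pids: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[p] for p in pids])

    def participants_in(self, fold: int) -> list[str]:
        return sorted(p for p, f in self.assignment.items() if f == fold)


def make_group_folds(participants: Iterable[str], k: int, seed: int) -> CVPlan:
    """Random balanced partition of participants into k folds."""
    pids = sorted(set(map(str, participants)))
    if k < 2:
        raise ValueError("k must be at least 2 (one fold must be held out)")
    if k > len(pids):
        raise ValueError(f"k={k} exceeds the {len(pids)} participants")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pids))
    assignment = {pids[j]: int(i % k) for i, j in enumerate(order)}
    return CVPlan(k=k, assignment=assignment, seed=int(seed))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def roc_auc(probabilities, labels) -> tuple[float, pd.DataFrame]:
    """Rank-based AUC (ties get half credit) plus the ROC curve points."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUC undefined: only one class present")
    auc = float(roc_auc_score(y, p))
    fpr, tpr, thr = roc_curve(y, p)
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return auc, curve


def optimal_threshold(curve: pd.DataFrame) -> float:
    """Threshold maximizing Youden's J = TPR - FPR (ties -> lower FPR)."""
    j = curve["tpr"].to_numpy() - curve["fpr"].to_numpy()
    best = j.max()
    candidates = curve[np.isclose(j, best)]
    row = candidates.loc[candidates["fpr"].idxmin()]
    return float(row["threshold"])


@dataclass
class MetricsReport:
    """Threshold-dependent battery plus AUC; positive = non-brushing day."""

    auc: float
    mcc: float
    accuracy: float
    tpr: float
    fpr: float
    precision: float
    f1: float
    npv: float
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "mcc": self.mcc, "accuracy": self.accuracy,
            "tpr": self.tpr, "fpr": self.fpr, "precision": self.precision,
            "f1": self.f1, "npv": self.npv, "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "undefined": list(self.undefined),
        }


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def metrics_report(probabilities, labels, threshold: float | None = None) -> MetricsReport:
    """Confusion-matrix battery at ``threshold`` (score >= threshold is positive).

    ``threshold=None`` picks the Youden-optimal threshold from the ROC curve
    of these predictions.  Undefined ratios (zero denominators) are reported
    as NaN and named in ``undefined``.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    auc, curve = roc_auc(p, y)
    if threshold is None:
        threshold = optimal_threshold(curve)
    pred = (p >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    undef: list[str] = []
    tpr = _safe_div(tp, tp + fn, "tpr", undef)
    fpr = _safe_div(fp, fp + tn, "fpr", undef)
    prec = _safe_div(tp, tp + fp, "precision", undef)
    npv = _safe_div(tn, tn + fn, "npv", undef)
    acc = (tp + tn) / len(y)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "f1", undef)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        undef.append("mcc")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricsReport(
        auc=auc, mcc=float(mcc), accuracy=float(acc), tpr=tpr, fpr=fpr,
        precision=prec, f1=f1, npv=npv, threshold=float(threshold),
        tp=tp, fp=fp, tn=tn, fn=fn, undefined=undef,
    )


def no_skill_accuracy(n_positive: int, n_total: int) -> int:
    """Majority-class accuracy as an integer percentage.

    The floor any learned model must beat: always predict the more common
    class.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive must lie in [0, n_total]")
    frac = max(n_positive, n_total - n_positive) / n_total
    return int(np.floor(100.0 * frac + 0.5))


@dataclass
class McNemarResult:
    statistic: float
    p_value: float
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    degenerate: bool = False


def mcnemar_test(correct_a, correct_b) -> McNemarResult:
    """Continuity-corrected McNemar chi-squared test on paired correctness.

    Tests whether two classifiers, scored on the same observations, are
    equally good: only the discordant pairs (one right, one wrong) carry
    information.  ``chi2 = (|b - c| - 1)^2 / (b + c)`` on 1 df.
    """
    a = np.asarray(correct_a, dtype=bool)
    b_arr = np.asarray(correct_b, dtype=bool)
    if a.shape != b_arr.shape:
        raise ValueError("correctness vectors must be paired (same length)")
    b = int((a & ~b_arr).sum())
    c = int((~a & b_arr).sum())
    if b + c == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, b=b, c=c, degenerate=True)
    stat = (abs(b - c) - 1) ** 2 / (b + c)
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(statistic=float(stat), p_value=p, b=b, c=c)


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningBudget:
    """Search strategy for a tunable spec.

    ``random``: ``steps`` draws of every theory parameter from U(0,1).
    ``grid``: the discount gamma over {0.01, 0.02, ..., 1.00} (steps=100).
    """

    method: str = "random"
    steps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("random", "grid"):
            raise ValueError(f"unknown search method {self.method!r}")
        if self.steps <= 0:
            raise ValueError("steps must be positive")


def default_budget(spec: ModelSpec, seed: int = 0) -> TuningBudget | None:
    """The study protocol's budget for a spec: 1000-step random search for
    the theory model, 100-step gamma grid for weighted past-BR, none
    otherwise."""
    if spec.name == "theory":
        return TuningBudget(method="random", steps=1000, seed=seed)
    if spec.name == "weighted_br":
        return TuningBudget(method="grid", steps=100, seed=seed)
    return None


def _candidates(spec: ModelSpec, budget: TuningBudget) -> list[ModelSpec]:
    if spec.name == "theory":
        if budget.method != "random":
            raise ValueError("theory parameters are tuned by random search")
        rng = np.random.default_rng(budget.seed)
        draws = rng.uniform(0.0, 1.0, size=(budget.steps, 5))
        return [
            spec.with_params(
                habit_params=HabitParams(hdp=d[0], hgp=d[1]),
                access_params=AccessParams(adp=d[2], agp_beh=d[3], agp_rem=d[4]),
            )
            for d in draws
        ]
    if spec.name == "weighted_br":
        if budget.method != "grid":
            raise ValueError("gamma is tuned by grid search")
        grid = np.round(np.linspace(0.01, 1.00, budget.steps), 10)
        return [spec.with_params(gamma=float(g)) for g in grid]
    raise ValueError(f"spec {spec.name!r} has no tunable parameters")


def _spec_params(spec: ModelSpec) -> dict[str, float]:
    if spec.name == "theory":
        hp, ap = spec.habit_params, spec.access_params
        return {"hdp": float(hp.hdp), "hgp": float(hp.hgp), "adp": float(ap.adp),
                "agp_beh": float(ap.agp_beh), "agp_rem": float(ap.agp_rem)}
    if spec.name == "weighted_br":
        return {"gamma": float(spec.gamma)}
    return {}


def _eval_candidate(
    arrays: StudyArrays,
    cand: ModelSpec,
    train_folds: set[int],
    test_folds: set[int],
    fold_of_participant: np.ndarray,
    ridge: float,
) -> float:
    x, y, pid_idx, _ = feature_matrix(arrays, cand)
    row_fold = fold_of_participant[pid_idx]
    tr = np.isin(row_fold, list(train_folds))
    te = np.isin(row_fold, list(test_folds))
    try:
        model = fit_logistic(x[tr], y[tr], feature_names=cand.feature_names, ridge=ridge)
        return float(roc_auc_score(y[te], predict_proba(model, x[te])))
    except (DegenerateFitError, ValueError):
        return -np.inf


def tune_parameters(
    arrays: StudyArrays,
    fold_of_participant: np.ndarray,
    train_folds: Iterable[int],
    tune_folds: Iterable[int],
    spec: ModelSpec,
    budget: TuningBudget,
    ridge: float = 0.0,
    return_trace: bool = False,
):
    """Search the spec's parameter space; maximize AUC on the tuning folds.

    ``fold_of_participant`` maps the row-order of ``arrays.pids`` to outer
    folds.  Returns ``(best_spec, best_auc)`` (plus a per-step trace when
    requested); the earliest best step wins ties.
    """
    train_folds, tune_folds = set(train_folds), set(tune_folds)
    if not train_folds or not tune_folds or train_folds & tune_folds:
        raise ValueError("train and tuning folds must be disjoint and non-empty")
    best_spec, best_auc = None, -np.inf
    trace = []
    for cand in _candidates(spec, budget):
        auc = _eval_candidate(
            arrays, cand, train_folds, tune_folds, fold_of_participant, ridge
        )
        if return_trace:
            trace.append({**_spec_params(cand), "auc": auc})
        if auc > best_auc:  # strict: first best wins ties
            best_auc, best_spec = auc, cand
    if best_spec is None:  # pragma: no cover
        raise RuntimeError("no admissible candidate found")
    if return_trace:
        return best_spec, float(best_auc), pd.DataFrame(trace)
    return best_spec, float(best_auc)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Pooled out-of-fold predictions and per-fold tuned parameters."""

    spec: ModelSpec
    predictions: pd.DataFrame  # participant_id, day, fold, prob, label
    fold_params: list[dict[str, float]]
    fold_inner_auc: list[float]

    @property
    def mean_params(self) -> dict[str, float]:
        if not self.fold_params or not self.fold_params[0]:
            return {}
        keys = self.fold_params[0].keys()
        return {k: float(np.mean([p[k] for p in self.fold_params])) for k in keys}

    def metrics(self, threshold: float | None = None) -> MetricsReport:
        return metrics_report(
            self.predictions["prob"], self.predictions["label"], threshold
        )


def nested_cv(
    logs: pd.DataFrame,
    surveys: pd.DataFrame | None,
    spec: ModelSpec,
    plan: CVPlan,
    budget: TuningBudget | None = None,
    ridge: float = 0.0,
    inner_rotation: bool = False,
) -> CVResult:
    """Two-level hierarchical grouped CV for one feature set.

    Outer fold f is the test set; within the other k-1 folds, fold
    ``(f+1) mod k`` is the single tuning test set (full inner rotation over
    all k-1 training folds is available via ``inner_rotation``).  Specs
    without tunables skip the inner loop entirely — a plain grouped k-fold.
    Every predictable row is predicted exactly once.
    """
    arrays = StudyArrays.from_frames(logs, surveys)
    missing = [p for p in arrays.pids if p not in plan.assignment]
    if missing:
        raise ValueError(f"plan lacks fold assignment for participants {missing}")
    fold_of_participant = plan.fold_of(arrays.pids)
    if budget is None and spec.is_tunable:
        budget = default_budget(spec)

    frames, fold_params, fold_inner = [], [], []
    for f in range(plan.k):
        train_folds = [g for g in range(plan.k) if g != f]
        if spec.is_tunable:
            fold_budget = TuningBudget(
                method=budget.method, steps=budget.steps,
                seed=int(np.random.default_rng([budget.seed, f]).integers(2**31)),
            )
            if inner_rotation:
                # average tuning AUC over every choice of inner test fold
                cands = _candidates(spec, fold_budget)
                scores = np.zeros(len(cands))
                for g in train_folds:
                    inner_train = set(train_folds) - {g}
                    for ci, cand in enumerate(cands):
                        scores[ci] += _eval_candidate(
                            arrays, cand, inner_train, {g},
                            fold_of_participant, ridge,
                        )
                best_i = int(np.argmax(scores))
                tuned, inner_auc = cands[best_i], scores[best_i] / len(train_folds)
            else:
                inner_test = train_folds[f % len(train_folds)]  # == (f+1) mod k
                inner_train = set(train_folds) - {inner_test}
                tuned, inner_auc = tune_parameters(
                    arrays, fold_of_participant, inner_train, {inner_test},
                    spec, fold_budget, ridge,
                )
        else:
            tuned, inner_auc = spec, float("nan")

        x, y, pid_idx, day = feature_matrix(arrays, tuned)
        row_fold = fold_of_participant[pid_idx]
        tr, te = row_fold != f, row_fold == f
        if not te.any():
            warnings.warn(f"outer fold {f} has no predictable rows; skipped", stacklevel=2)
            continue
        model = fit_logistic(x[tr], y[tr], feature_names=tuned.feature_names, ridge=ridge)
        probs = predict_proba(model, x[te])
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": arrays.pids[pid_idx[te]],
                    "day": day[te],
                    "fold": f,
                    "prob": probs,
                    "label": y[te],
                }
            )
        )
        fold_params.append(_spec_params(tuned))
        fold_inner.append(float(inner_auc))

    predictions = pd.concat(frames, ignore_index=True)
    if predictions.duplicated(["participant_id", "day"]).any():  # pragma: no cover
        raise RuntimeError("a row was predicted more than once")
    return CVResult(
        spec=spec, predictions=predictions,
        fold_params=fold_params, fold_inner_auc=fold_inner,
    )


# ---------------------------------------------------------------------------
# cross-dataset transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferResult:
    spec: ModelSpec
    tuned_params: dict[str, float]
    metrics: MetricsReport
    predictions: pd.DataFrame
    model: FittedClassifier


def cross_dataset_evaluate(
    train_logs: pd.DataFrame,
    train_surveys: pd.DataFrame | None,
    test_logs: pd.DataFrame,
    test_surveys: pd.DataFrame | None,
    spec: ModelSpec,
    k: int,
    budget: TuningBudget | None = None,
    seed: int = 0,
    ridge: float = 0.0,
) -> TransferResult:
    """Train on one whole study, evaluate once on the other.

    Tunable parameters are chosen by grouped k-fold CV on the entire
    training study (pooled out-of-fold AUC as the objective), the model is
    refit on all training data with those parameters, and the held-out
    study is predicted a single time.
    """
    arrays_tr = StudyArrays.from_frames(train_logs, train_surveys)
    arrays_te = StudyArrays.from_frames(test_logs, test_surveys)
    tuned = spec
    if spec.is_tunable:
        if budget is None:
            budget = default_budget(spec, seed)
        plan = make_group_folds(arrays_tr.pids, k, seed)
        fold_of_participant = plan.fold_of(arrays_tr.pids)
        best_auc = -np.inf
        for cand in _candidates(spec, budget):
            x, y, pid_idx, _ = feature_matrix(arrays_tr, cand)
            row_fold = fold_of_participant[pid_idx]
            pooled = np.full(len(y), np.nan)
            try:
                for g in range(k):
                    te = row_fold == g
                    model = fit_logistic(
                        x[~te], y[~te], feature_names=cand.feature_names, ridge=ridge
                    )
                    pooled[te] = predict_proba(model, x[te])
                auc = float(roc_auc_score(y, pooled))
            except (DegenerateFitError, ValueError):
                auc = -np.inf
            if auc > best_auc:
                best_auc, tuned = auc, cand

    x_tr, y_tr, _, _ = feature_matrix(arrays_tr, tuned)
    model = fit_logistic(x_tr, y_tr, feature_names=tuned.feature_names, ridge=ridge)
    x_te, y_te, pid_idx, day = feature_matrix(arrays_te, tuned)
    probs = predict_proba(model, x_te)
    predictions = pd.DataFrame(
        {
            "participant_id": arrays_te.pids[pid_idx],
            "day": day,
            "prob": probs,
            "label": y_te,
        }
    )
    return TransferResult(
        spec=spec,
        tuned_params=_spec_params(tuned),
        metrics=metrics_report(probs, y_te),
        predictions=predictions,
        model=model,
    )


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    table: pd.DataFrame          # one row per spec, MetricsReport columns
    mcnemar_statistic: pd.DataFrame
    mcnemar_p: pd.DataFrame
    results: dict[str, CVResult]


def compare_models(
    logs: pd.DataFrame,
    surveys: pd.DataFrame | None,
    specs: Sequence[ModelSpec],
    plan: CVPlan,
    budgets: Mapping[str, TuningBudget] | None = None,
    ridge: float = 0.0,
) -> ComparisonResult:
    """Run nested CV for every spec and compare them pairwise.

    Correctness for the McNemar pairing is judged at each model's own
    Youden-optimal threshold on its pooled predictions, on the intersection
    of rows all models predicted.
    """
    if len(specs) < 2:
        raise ValueError("need at least two specs to compare")
    budgets = budgets or {}
    results: dict[str, CVResult] = {}
    for spec in specs:
        results[spec.name] = nested_cv(
            logs, surveys, spec, plan,
            budget=budgets.get(spec.name), ridge=ridge,
        )

    rows = []
    correct: dict[str, pd.Series] = {}
    common: pd.Index | None = None
    for name, res in results.items():
        rep = res.metrics()
        rows.append({"model": name, **{k: v for k, v in rep.to_dict().items() if k != "undefined"}})
        preds = res.predictions.set_index(["participant_id", "day"])
        correct[name] = (preds["prob"] >= rep.threshold).astype(int) == preds["label"]
        common = correct[name].index if common is None else common.intersection(correct[name].index)

    names = list(results)
    stat = pd.DataFrame(np.nan, index=names, columns=names)
    pval = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = mcnemar_test(correct[a].loc[common], correct[b].loc[common])
            stat.loc[a, b] = stat.loc[b, a] = res.statistic
            pval.loc[a, b] = pval.loc[b, a] = res.p_value
    return ComparisonResult(
        table=pd.DataFrame(rows).set_index("model"),
        mcnemar_statistic=stat,
        mcnemar_p=pval,
        results=results,
    )


# ---------------------------------------------------------------------------
# tuning curves (one-parameter sweeps)
# ---------------------------------------------------------------------------

def tuning_curve(
    logs: pd.DataFrame,
    surveys: pd.DataFrame | None,
    spec: ModelSpec,
    param: str,
    values: Sequence[float],
    plan: CVPlan,
    ridge: float = 0.0,
) -> pd.DataFrame:
    """AUC as a function of one dynamics parameter, others held fixed.

    For each value, the parameter is substituted into ``spec`` and the
    pooled grouped-CV AUC under ``plan`` is computed — the one-dimensional
    analogue of the random-search landscape, used to see whether a
    parameter has an interior optimum or a flat profile.
    """
    if spec.name != "theory":
        raise ValueError("tuning curves are defined for the theory spec")
    if param not in THEORY_PARAM_NAMES:
        raise ValueError(f"unknown parameter {param!r}; expected one of {THEORY_PARAM_NAMES}")
    arrays = StudyArrays.from_frames(logs, surveys)
    fold_of_participant = plan.fold_of(arrays.pids)
    out = []
    for v in values:
        hp, ap = spec.habit_params, spec.access_params
        kw = {"hdp": hp.hdp, "hgp": hp.hgp, "adp": ap.adp,
              "agp_beh": ap.agp_beh, "agp_rem": ap.agp_rem}
        kw[param] = float(v)
        cand = spec.with_params(
            habit_params=HabitParams(kw["hdp"], kw["hgp"]),
            access_params=AccessParams(kw["adp"], kw["agp_beh"], kw["agp_rem"]),
        )
        x, y, pid_idx, _ = feature_matrix(arrays, cand)
        row_fold = fold_of_participant[pid_idx]
        pooled = np.full(len(y), np.nan)
        for g in range(plan.k):
            te = row_fold == g
            model = fit_logistic(x[~te], y[~te], feature_names=cand.feature_names, ridge=ridge)
            pooled[te] = predict_proba(model, x[te])
        out.append({"param": param, "value": float(v), "auc": float(roc_auc_score(y, pooled))})
    return pd.DataFrame(out)
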