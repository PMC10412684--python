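"""Classifier families, leave-one-patient-out validation, and feature importance.

The evaluation design holds out *all* instances of one patient as the test
set; the remaining instances are randomly split 80/20 into train and
validation, with 5-fold cross-validation folds available inside the train
portion.  One model per held-out patient is tuned (Bayesian optimization on
a Gaussian-process surrogate, except a neuron-count grid for the
perceptron), and the overall performance is the mean +- SD over patients.

The positive class is *clean*: a true positive is a clean block classified
clean, a true negative a noisy block classified noisy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as _stats
from sklearn.base import BaseEstimator, TransformerMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import accuracy_score, f1_score, make_scorer, matthews_corrcoef
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .dataset import DatasetMatrix, ScalingParams, apply_feature_scaler, fit_feature_scaler

FAMILIES = ("knn", "dtree", "linear_svm", "slp", "rforest")

#: hyperparameter fields allowed per family
_FAMILY_PARAMS = {
    "knn": {"k"},
    "dtree": {"msl"},
    "linear_svm": {"s", "c"},
    "slp": {"neurons", "l2"},
    "rforest": {"msl", "nfeats", "ntrees"},
}

#: hidden-layer sizes of the tuned perceptron per held-out patient,
#: as reported for the study cohort (patient id -> neurons)
SLP_NEURON_PRESETS = {"2": 55, "4": 40, "6": 50, "7": 55, "9": 60, "10": 55}


# ---------------------------------------------------------------------------
# Metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with *clean* as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, recall, precision, F1, MCC and its [0,1]-normalized form."""

    acc: float
    re: float
    pr: float
    f1: float
    mcc: float
    nmcc: float

    def rounded(self, ndigits: int = 2) -> "MetricsReport":
        return MetricsReport(
            *(round(getattr(self, f), ndigits)
              for f in ("acc", "re", "pr", "f1", "mcc", "nmcc"))
        )

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in ("acc", "re", "pr", "f1", "mcc", "nmcc")}


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Standard binary metrics from confusion counts.

    Zero-denominator conventions: recall, precision and F1 fall back to 0;
    MCC is 0 whenever any marginal is 0.  nMCC = (MCC + 1) / 2.
    """
    if c.total == 0:
        raise ValueError("all-zero confusion counts")
    acc = (c.tp + c.tn) / c.total
    re = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    pr = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    f1 = 2 * re * pr / (re + pr) if (re + pr) else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    return MetricsReport(acc=acc, re=re, pr=pr, f1=f1, mcc=mcc, nmcc=(mcc + 1) / 2)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally confusion counts; targets use 1 = clean, 0 = noisy."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/target length mismatch")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


# ---------------------------------------------------------------------------
# Classifier construction


@dataclass(frozen=True)
class ModelConfig:
    """One classifier family plus exactly its hyperparameters."""

    family: str
    params: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; pick from {FAMILIES}")
        allowed = _FAMILY_PARAMS[self.family]
        extra = set(self.params) - allowed
        if extra:
            raise ValueError(f"{self.family}: unexpected hyperparameters {sorted(extra)}")


class KernelScale(BaseEstimator, TransformerMixin):
    """Divides features by a kernel scale ``s`` (linear-SVM scaling knob)."""

    def __init__(self, s: float = 1.0):
        self.s = s

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return np.asarray(X) / self.s


def build_classifier(cfg: ModelConfig):
    """Instantiate an untrained sklearn estimator for the given configuration."""
    p = cfg.params
    if cfg.family == "knn":
        return KNeighborsClassifier(n_neighbors=int(p.get("k", 5)), metric="euclidean")
    if cfg.family == "dtree":
        return DecisionTreeClassifier(
            min_samples_leaf=int(p.get("msl", 1)), random_state=cfg.seed
        )
    if cfg.family == "linear_svm":
        return Pipeline(
            [
                ("scale", KernelScale(float(p.get("s", 1.0)))),
                ("svm", SVC(kernel="linear", C=float(p.get("c", 1.0)))),
            ]
        )
    if cfg.family == "slp":
        return MLPClassifier(
            hidden_layer_sizes=(int(p.get("neurons", 50)),),
            solver="sgd",
            learning_rate_init=0.05,
            momentum=0.9,
            alpha=float(p.get("l2", 1e-4)),
            max_iter=400,
            early_stopping=True,
            n_iter_no_change=15,
            random_state=cfg.seed,
        )
    if cfg.family == "rforest":
        return RandomForestClassifier(
            n_estimators=int(p.get("ntrees", 100)),
            min_samples_leaf=int(p.get("msl", 1)),
            max_features=int(p.get("nfeats", 4)),
            random_state=cfg.seed,
        )
    raise ValueError(cfg.family)


# ---------------------------------------------------------------------------
# Split plans


@dataclass
class SplitPlan:
    """Leave-one-patient-out split with an 80/20 train/validation partition."""

    test_patient: str
    test_idx: np.ndarray
    train_idx: np.ndarray
    val_idx: np.ndarray
    cv_folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int


def make_split_plan(ds: DatasetMatrix, test_patient: str, seed: int) -> SplitPlan:
    """All instances of ``test_patient`` go to test; the rest split 80/20.

    The non-test instances are shuffled with ``seed``; the first 80% form the
    train portion (with a 5-fold CV partition inside it) and the remainder
    the validation set.  Deterministic given (dataset, test_patient, seed).
    """
    pids = ds.patient_ids.astype(str)
    mask = pids == str(test_patient)
    if not mask.any():
        raise ValueError(f"unknown patient {test_patient!r}")
    others = np.flatnonzero(~mask)
    if np.unique(pids[others]).size < 2:
        raise ValueError("need at least 2 non-test patients")
    rng = np.random.default_rng(seed)
    others = rng.permutation(others)
    n_train = int(round(0.8 * others.size))
    train_idx, val_idx = others[:n_train], others[n_train:]
    kf = KFold(n_splits=5, shuffle=True, random_state=seed % (2**32))
    cv_folds = [
        (train_idx[tr], train_idx[va]) for tr, va in kf.split(train_idx)
    ]
    return SplitPlan(
        test_patient=str(test_patient),
        test_idx=np.flatnonzero(mask),
        train_idx=train_idx,
        val_idx=val_idx,
        cv_folds=cv_folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hyperparameter tuning


#: default search spaces; bounds bracket the hyperparameter values the tuned
#: study models landed on.  ("log" dims are searched in log10 space.)
DEFAULT_SEARCH_SPACES = {
    "knn": {"k": ("int", 1, 51)},
    "dtree": {"msl": ("int", 1, 100)},
    "linear_svm": {"s": ("logfloat", 0.1, 150.0), "c": ("logfloat", 0.1, 50.0)},
    "slp": {"neurons": ("grid", tuple(range(5, 105, 5)))},
    "rforest": {
        "msl": ("int", 1, 60),
        "nfeats": ("int", 1, 16),
        "ntrees": ("int", 50, 250),
    },
}


def _decode_point(space: dict, u: np.ndarray) -> dict:
    """Map a unit-cube point to concrete hyperparameter values."""
    params = {}
    for (name, (kind, lo, hi)), ui in zip(space.items(), u):
        if kind == "int":
            params[name] = int(round(lo + ui * (hi - lo)))
        elif kind == "float":
            params[name] = float(lo + ui * (hi - lo))
        elif kind == "logfloat":
            params[name] = float(10 ** (math.log10(lo) + ui * (math.log10(hi) - math.log10(lo))))
        else:
            raise ValueError(f"dimension kind {kind!r} not continuous")
    return params


def _expected_improvement(mu: np.ndarray, sd: np.ndarray, best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (mu - best) / sd
    return (mu - best) * _stats.norm.cdf(z) + sd * _stats.norm.pdf(z)


def tune_hyperparameters(
    ds: DatasetMatrix,
    plan: SplitPlan,
    family: str,
    search_space: dict | None = None,
    budget: int = 16,
    seed: int = 0,
) -> ModelConfig:
    """Pick the hyperparameters maximizing validation F1.

    Continuous/integer spaces are searched with Bayesian optimization
    (expected improvement over a Matern-kernel Gaussian-process surrogate,
    random initialization of ~1/3 of the budget); a ``("grid", values)``
    space — the perceptron's neuron counts — is searched exhaustively.
    Deterministic given (dataset, plan, seed).
    """
    space = search_space or DEFAULT_SEARCH_SPACES[family]
    if not space:
        raise ValueError("empty search space")
    scaler = fit_feature_scaler(ds.X[plan.train_idx])
    Xtr = apply_feature_scaler(ds.X[plan.train_idx], scaler)
    ytr = ds.y[plan.train_idx]
    Xva = apply_feature_scaler(ds.X[plan.val_idx], scaler)
    yva = ds.y[plan.val_idx]

    def objective(params: dict) -> float:
        cfg = ModelConfig(family, params, seed=seed)
        model = build_classifier(cfg)
        model.fit(Xtr, ytr)
        return float(f1_score(yva, model.predict(Xva), zero_division=0))

    grid_dims = [k for k, v in space.items() if v[0] == "grid"]
    if grid_dims:
        if len(space) != len(grid_dims) or len(grid_dims) != 1:
            raise ValueError("grid search supports exactly one grid dimension")
        name = grid_dims[0]
        values = space[name][1]
        scores = [objective({name: v}) for v in values]
        best = values[int(np.argmax(scores))]
        return ModelConfig(family, {name: best}, seed=seed)

    rng = np.random.default_rng(seed)
    dims = len(space)
    n_init = max(3, min(budget, budget // 3 + 2))
    U = list(rng.random((n_init, dims)))
    scores = [objective(_decode_point(space, u)) for u in U]
    while len(scores) < budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-6, normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            # with few observations of a stepwise objective the marginal
            # likelihood often pins the length scale at a bound
            warnings.simplefilter("ignore", ConvergenceWarning)
            gp.fit(np.vstack(U), np.asarray(scores))
        cand = rng.random((256, dims))
        mu, sd = gp.predict(cand, return_std=True)
        u = cand[int(np.argmax(_expected_improvement(mu, sd, max(scores))))]
        U.append(u)
        scores.append(objective(_decode_point(space, u)))
    best_u = U[int(np.argmax(scores))]
    return ModelConfig(family, _decode_point(space, best_u), seed=seed)


# ---------------------------------------------------------------------------
# Patient rotation


@dataclass
class PatientResult:
    """Evaluation of one held-out patient."""

    patient_id: str
    config: ModelConfig
    confusion: ConfusionCounts
    metrics: MetricsReport
    model: object = field(repr=False, default=None)
    scaler: ScalingParams | None = field(repr=False, default=None)
    plan: SplitPlan | None = field(repr=False, default=None)


@dataclass
class RotationReport:
    """Per-held-out-patient results plus mean/SD aggregates for one family."""

    family: str
    per_patient: dict[str, PatientResult]
    seed: int
    tuning_budget: int
    refit_with_validation: bool
    feature_subset: tuple[int, ...] | None = None

    def aggregate(self) -> dict[str, tuple[float, float]]:
        """Mean and SD of each metric over the held-out patients."""
        out = {}
        for m in ("acc", "re", "pr", "f1", "mcc", "nmcc"):
            vals = np.array(
                [getattr(r.metrics, m) for r in self.per_patient.values()]
            )
            out[m] = (float(vals.mean()), float(vals.std(ddof=0)))
        return out


def _evaluate_patient(
    ds: DatasetMatrix,
    plan: SplitPlan,
    cfg: ModelConfig,
    refit_with_validation: bool,
) -> PatientResult:
    if refit_with_validation:
        fit_idx = np.concatenate([plan.train_idx, plan.val_idx])
    else:
        fit_idx = plan.train_idx
    scaler = fit_feature_scaler(ds.X[fit_idx])
    model = build_classifier(cfg)
    model.fit(apply_feature_scaler(ds.X[fit_idx], scaler), ds.y[fit_idx])
    y_pred = model.predict(apply_feature_scaler(ds.X[plan.test_idx], scaler))
    conf = confusion_from_predictions(ds.y[plan.test_idx], y_pred)
    return PatientResult(
        patient_id=plan.test_patient,
        config=cfg,
        confusion=conf,
        metrics=compute_metrics(conf),
        model=model,
        scaler=scaler,
        plan=plan,
    )


def run_patient_rotation(
    ds: DatasetMatrix,
    families=("slp",),
    seed: int = 0,
    tuning_budget: int = 16,
    refit_with_validation: bool = True,
    search_spaces: dict | None = None,
) -> dict[str, RotationReport]:
    """Full leave-one-patient-out evaluation for each requested family.

    For every patient in the dataset: build the split plan, tune on the
    validation set, refit on train(+validation), and score on the held-out
    patient.  The feature scaler is always fit inside the rotation's own
    training data, never on the test patient.
    """
    patients = sorted(np.unique(ds.patient_ids.astype(str)))
    if len(patients) < 3:
        raise ValueError("patient rotation needs at least 3 patients")
    reports: dict[str, RotationReport] = {}
    for family in families:
        per_patient: dict[str, PatientResult] = {}
        for i, pid in enumerate(patients):
            plan_seed = (seed * 1_000_003 + i * 7919) % (2**31)
            plan = make_split_plan(ds, pid, plan_seed)
            space = (search_spaces or {}).get(family)
            cfg = tune_hyperparameters(
                ds, plan, family, search_space=space,
                budget=tuning_budget, seed=plan_seed,
            )
            per_patient[pid] = _evaluate_patient(ds, plan, cfg, refit_with_validation)
        reports[family] = RotationReport(
            family=family,
            per_patient=per_patient,
            seed=seed,
            tuning_budget=tuning_budget,
            refit_with_validation=refit_with_validation,
        )
    return reports


# ---------------------------------------------------------------------------
# Permutation feature importance


def permutation_feature_importance(
    model,
    X: np.ndarray,
    y: np.ndarray,
    metric: str = "f1",
    n_repeats: int = 10,
    seed: int = 0,
    feature_names: tuple[str, ...] | None = None,
) -> list[dict]:
    """Drop in a fitted model's score when each feature column is shuffled.

    Shuffling happens within the evaluation set only; the result is sorted by
    decreasing mean importance.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    scorers = {
        "f1": make_scorer(f1_score, zero_division=0),
        "accuracy": make_scorer(accuracy_score),
        "nmcc": make_scorer(lambda yt, yp: (matthews_corrcoef(yt, yp) + 1) / 2),
    }
    try:
        scorer = scorers[metric]
    except KeyError:
        raise ValueError(f"unknown metric {metric!r}") from None
    res = _sk_permutation_importance(
        model, np.asarray(X, float), np.asarray(y),
        scoring=scorer, n_repeats=n_repeats, random_state=seed,
    )
    names = feature_names or tuple(f"x{j + 1}" for j in range(np.asarray(X).shape[1]))
    ranked = sorted(
        (
            {"feature": names[j], "index": j,
             "mean": float(res.importances_mean[j]),
             "std": float(res.importances_std[j])}
            for j in range(len(names))
        ),
        key=lambda d: d["mean"],
        reverse=True,
    )
    return ranked


def rank_features_from_rotation(
    ds: DatasetMatrix,
    report: RotationReport,
    metric: str = "f1",
    n_repeats: int = 10,
) -> list[int]:
    """Feature indices ranked by mean permutation importance over rotations.

    Each rotation's model is probed on its own validation set (scaled with
    the model's training scaler), so the test patients stay untouched.
    """
    n_feat = ds.X.shape[1]
    acc = np.zeros(n_feat)
    for res in report.per_patient.values():
        Z = apply_feature_scaler(ds.X[res.plan.val_idx], res.scaler)
        ranked = permutation_feature_importance(
            res.model, Z, ds.y[res.plan.val_idx],
            metric=metric, n_repeats=n_repeats, seed=res.plan.seed,
        )
        for d in ranked:
            acc[d["index"]] += d["mean"]
    return list(np.argsort(-acc))


def retrain_with_top_features(
    ds: DatasetMatrix,
    report: RotationReport,
    k: int,
    metric: str = "f1",
    n_repeats: int = 10,
) -> RotationReport:
    """Repeat the rotation keeping only the top-``k`` features by importance."""
    if not (1 <= k <= ds.X.shape[1]):
        raise ValueError(f"k must be in [1, {ds.X.shape[1]}], got {k}")
    order = rank_features_from_rotation(ds, report, metric=metric, n_repeats=n_repeats)
    top = tuple(sorted(order[:k]))
    sub = DatasetMatrix(
        X=ds.X[:, list(top)],
        y=ds.y,
        patient_ids=ds.patient_ids,
        feature_names=tuple(ds.feature_names[j] for j in top),
    )
    new = run_patient_rotation(
        sub,
        families=(report.family,),
        seed=report.seed,
        tuning_budget=report.tuning_budget,
        refit_with_validation=report.refit_with_validation,
    )[report.family]
    return replace(new, feature_subset=top)
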