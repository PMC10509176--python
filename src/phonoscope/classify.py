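"""Pairwise SVM classification with participant-grouped stratified CV.

The bespoke content here is the protocol, not the solver: folds are built
over participants (never splitting one participant's samples across folds)
while balancing classes, the box constraint is tuned per training split by
expected-improvement Bayesian search (grid fallback), and the whole
pipeline is repeated with independent fold seeds so that metrics and
importance scores average over the randomness of the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, WhiteKernel
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .assembly import FEATURE_NAMES

PAIRS_DEFAULT = (("HC", "SSD"), ("HC", "MDD"), ("SSD", "MDD"))
KERNEL_DEGREES_DEFAULT = (1, 2, 3)


@dataclass
class SVMConfig:
    kernel_degree: int = 3
    box_constraint: float | None = None  # None -> tuned per training split
    kernel_scale: str | float = "auto"
    optimizer: str = "bayes"  # bayes | grid
    bayes_iterations: int = 30
    inner_folds: int = 3
    standardization: str = "leakage_safe"  # leakage_safe | paper_faithful

    def __post_init__(self) -> None:
        if self.kernel_degree not in (1, 2, 3):
            raise ValueError("kernel_degree must be 1, 2 or 3")
        if self.optimizer not in ("bayes", "grid"):
            raise ValueError("optimizer must be 'bayes' or 'grid'")


@dataclass
class FoldAssignment:
    """sample_row -> fold in {0..k-1}; all of a participant's rows share a fold."""

    fold_of_row: np.ndarray
    k: int
    seed: int

    def val_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_row == fold)

    def train_rows(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_row != fold)


@dataclass
class FoldModel:
    """A trained per-fold model retained for permutation importance."""

    model: SVC
    scaler: StandardScaler | None
    val_rows: np.ndarray
    accuracy: float


@dataclass
class ModelMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_fold: pd.DataFrame | None = None
    fold_models: list[FoldModel] = field(default_factory=list)


def make_grouped_stratified_folds(
    table: pd.DataFrame, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Deal participants round-robin to folds, shuffled within each class.

    Guarantees that no participant's samples are split across folds and
    that per-fold class counts differ by at most one participant.
    """
    rng = np.random.default_rng(seed)
    fold_of_participant: dict[str, int] = {}
    for group in sorted(table["group"].unique()):
        pids = sorted(table.loc[table["group"] == group, "participant_id"].unique())
        if len(pids) < k:
            raise ValueError(
                f"class {group} has {len(pids)} participants, fewer than k={k}"
            )
        pids = list(rng.permutation(pids))
        for i, pid in enumerate(pids):
            fold_of_participant[pid] = i % k
    fold_of_row = table["participant_id"].map(fold_of_participant).to_numpy()
    return FoldAssignment(fold_of_row.astype(int), k, seed)


def _make_svc(degree: int, c: float, gamma: float) -> SVC:
    if degree == 1:
        return SVC(kernel="linear", C=c)
    return SVC(kernel="poly", degree=degree, C=c, gamma=gamma, coef0=1.0)


def _auto_scale(x: np.ndarray) -> float:
    v = x.var()
    return 1.0 / (x.shape[1] * v) if v > 0 else 1.0


def _inner_cv_accuracy(
    x: np.ndarray,
    y: np.ndarray,
    pids: np.ndarray,
    c: float,
    cfg: SVMConfig,
    seed: int,
) -> float:
    inner = make_grouped_stratified_folds(
        pd.DataFrame({"participant_id": pids, "group": y}),
        k=cfg.inner_folds,
        seed=seed,
    )
    accs = []
    for f in range(cfg.inner_folds):
        tr, va = inner.train_rows(f), inner.val_rows(f)
        if len(np.unique(y[va])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        scaler = StandardScaler().fit(x[tr])
        xt, xv = scaler.transform(x[tr]), scaler.transform(x[va])
        model = _make_svc(cfg.kernel_degree, c, _auto_scale(xt)).fit(xt, y[tr])
        accs.append(float((model.predict(xv) == y[va]).mean()))
    if not accs:
        raise RuntimeError("no valid inner folds for hyperparameter tuning")
    return float(np.mean(accs))


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    from scipy.stats import norm as _norm

    sigma = np.maximum(sigma, 1e-9)
    z = (mu - best) / sigma
    return (mu - best) * _norm.cdf(z) + sigma * _norm.pdf(z)


def optimize_box_constraint(
    x: np.ndarray,
    y: np.ndarray,
    pids: np.ndarray,
    cfg: SVMConfig,
    seed: int = 0,
    log_c_range: tuple[float, float] = (-3.0, 3.0),
) -> float:
    """Tune C over a log range by inner grouped-CV accuracy.

    ``bayes`` runs expected-improvement Bayesian search on a Gaussian
    process over log10(C) (5 space-filling initial points, then sequential
    acquisitions up to ``bayes_iterations`` total evaluations); ``grid``
    evaluates 13 log-spaced candidates.  Ties prefer the smaller C.
    """
    rng = np.random.default_rng(seed)
    lo, hi = log_c_range

    def objective(log_c: float) -> float:
        return _inner_cv_accuracy(x, y, pids, 10.0**log_c, cfg, seed)

    if cfg.optimizer == "grid":
        grid = np.linspace(lo, hi, 13)
        scores = np.array([objective(g) for g in grid])
        return float(10.0 ** grid[int(np.argmax(scores))])

    n_init = min(5, cfg.bayes_iterations)
    # space-filling start: stratified jittered points over the range
    edges = np.linspace(lo, hi, n_init + 1)
    tried = list(edges[:-1] + rng.uniform(0, 1, n_init) * np.diff(edges))
    scores = [objective(t) for t in tried]
    gp = GaussianProcessRegressor(
        kernel=1.0 * RBF(length_scale=1.0) + WhiteKernel(1e-3),
        normalize_y=True,
        random_state=int(rng.integers(2**31 - 1)),
    )
    candidates = np.linspace(lo, hi, 241)
    for _ in range(cfg.bayes_iterations - n_init):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.asarray(tried)[:, None], np.asarray(scores))
            mu, sigma = gp.predict(candidates[:, None], return_std=True)
        ei = _expected_improvement(mu, sigma, max(scores))
        pick = float(candidates[int(np.argmax(ei))])
        if any(abs(pick - t) < 1e-6 for t in tried):
            pick = float(rng.uniform(lo, hi))
        tried.append(pick)
        scores.append(objective(pick))
    best = np.max(scores)
    # among near-ties, prefer the least complex model (smallest C)
    winners = [t for t, s in zip(tried, scores) if s >= best - 1e-12]
    return float(10.0 ** min(winners))


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray, positive) -> dict:
    tp = float(np.sum((y_pred == positive) & (y_true == positive)))
    fp = float(np.sum((y_pred == positive) & (y_true != positive)))
    fn = float(np.sum((y_pred != positive) & (y_true == positive)))
    acc = float((y_pred == y_true).mean())
    prec = tp / (tp + fp) if tp + fp > 0 else 0.0
    rec = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1}


def positive_class(labels: tuple[str, str]) -> str:
    """The patient group for HC-vs-patient pairs; MDD for SSD-vs-MDD."""
    a, b = labels
    if "HC" in labels:
        return b if a == "HC" else a
    return "MDD" if "MDD" in labels else sorted(labels)[1]


def crossval_evaluate(
    table: pd.DataFrame,
    folds: FoldAssignment,
    cfg: SVMConfig,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ModelMetrics:
    """Train/validate over the k folds and average the four metrics.

    In ``leakage_safe`` mode the standardization is fitted on each
    training split; ``paper_faithful`` expects a pre-standardized table.
    Folds whose validation split contains a single class are flagged and
    excluded from the mean.
    """
    feats = feature_names or [c for c in FEATURE_NAMES if c in table.columns]
    x_all = table[feats].to_numpy(float)
    y_all = table["group"].to_numpy()
    pids = table["participant_id"].to_numpy()
    pos = positive_class(tuple(sorted(np.unique(y_all))))

    rows = []
    fold_models: list[FoldModel] = []
    for f in range(folds.k):
        tr, va = folds.train_rows(f), folds.val_rows(f)
        if len(np.unique(y_all[va])) < 2:
            warnings.warn(f"fold {f}: single-class validation split, excluded")
            continue
        scaler = None
        xt, xv = x_all[tr], x_all[va]
        if cfg.standardization == "leakage_safe":
            scaler = StandardScaler().fit(xt)
            xt, xv = scaler.transform(xt), scaler.transform(xv)
        c = cfg.box_constraint
        if c is None:
            c = optimize_box_constraint(
                x_all[tr], y_all[tr], pids[tr], cfg, seed=seed + f
            )
        model = _make_svc(cfg.kernel_degree, c, _auto_scale(xt)).fit(xt, y_all[tr])
        m = _binary_metrics(y_all[va], model.predict(xv), pos)
        m["fold"] = f
        m["box_constraint"] = c
        rows.append(m)
        fold_models.append(FoldModel(model, scaler, va, m["accuracy"]))
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise RuntimeError("no usable folds")
    return ModelMetrics(
        accuracy=float(per_fold["accuracy"].mean()),
        precision=float(per_fold["precision"].mean()),
        recall=float(per_fold["recall"].mean()),
        f1=float(per_fold["f1"].mean()),
        per_fold=per_fold,
        fold_models=fold_models,
    )


@dataclass
class RepetitionResult:
    """Metrics and retained fold models for one repetition of the pipeline."""

    metrics: ModelMetrics
    folds: FoldAssignment
    table: pd.DataFrame  # the (possibly standardized) table the models saw
    feature_names: list[str]


def repeat_pipeline(
    table: pd.DataFrame,
    cfg: SVMConfig,
    n_reps: int = 100,
    k: int = 5,
    master_seed: int = 0,
) -> tuple[pd.DataFrame, list[RepetitionResult]]:
    """Repeat fold construction + CV ``n_reps`` times with independent seeds.

    Returns per-repetition metric rows plus the retained models needed by
    permutation importance.  Deterministic under ``master_seed``.
    """
    from .assembly import standardize

    feats = [c for c in FEATURE_NAMES if c in table.columns]
    work = table.dropna(subset=feats).reset_index(drop=True)
    if cfg.standardization == "paper_faithful":
        work = standardize(work, mode="paper_faithful")
        feats = [c for c in feats if c in work.columns]
    seeds = np.random.SeedSequence(master_seed).generate_state(n_reps) % (2**31 - 1)
    rows = []
    reps: list[RepetitionResult] = []
    for r, s in enumerate(seeds):
        folds = make_grouped_stratified_folds(work, k=k, seed=int(s))
        metrics = crossval_evaluate(work, folds, cfg, seed=int(s), feature_names=feats)
        rows.append(
            {
                "repetition": r,
                "accuracy": metrics.accuracy,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f1": metrics.f1,
            }
        )
        reps.append(RepetitionResult(metrics, folds, work, feats))
    return pd.DataFrame(rows), reps
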