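"""Permutation feature importance over retained cross-validation models.

A feature's importance (FI) is the drop in validation accuracy when its
column is shuffled within the validation fold — labels and every other
column held fixed — averaged over 20 shuffles, the folds, and the pipeline
repetitions.  The cross-model aggregate (the sum of per-model FIs over the
pairwise models) ranks features by how much every comparison relies on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import FoldModel, RepetitionResult


@dataclass
class ImportanceResult:
    """Per-feature FI per model plus the cross-model aggregate and ranks."""

    per_model: pd.DataFrame  # index: feature, columns: model names
    aggregate: pd.Series  # cross-model sum (or mean, per ``aggregate_mode``)
    ranks: pd.Series  # 1 = most important; ties broken by feature name
    aggregate_mode: str = "sum"


def permutation_importance(
    fold_model: FoldModel,
    x_val: np.ndarray,
    y_val: np.ndarray,
    feature_idx: int,
    n_perm: int = 20,
    rng: np.random.Generator | None = None,
) -> float:
    """FI of one feature on one fold: baseline minus mean permuted accuracy.

    A feature constant within the fold is a permutation no-op, so its FI is
    exactly 0.
    """
    rng = rng or np.random.default_rng(0)
    col = x_val[:, feature_idx]
    if np.ptp(col) == 0:
        return 0.0
    if fold_model.scaler is not None:
        x_val = fold_model.scaler.transform(x_val)
    baseline = float((fold_model.model.predict(x_val) == y_val).mean())
    accs = np.empty(n_perm)
    xp = x_val.copy()
    for p in range(n_perm):
        xp[:, feature_idx] = x_val[rng.permutation(len(x_val)), feature_idx]
        accs[p] = (fold_model.model.predict(xp) == y_val).mean()
    return baseline - float(accs.mean())


def importance_from_repetitions(
    reps: list[RepetitionResult],
    n_perm: int = 20,
    seed: int = 0,
) -> pd.Series:
    """Per-feature FI averaged over folds and repetitions of one model."""
    if not reps:
        raise ValueError("no repetitions supplied")
    feats = reps[0].feature_names
    rng = np.random.default_rng(seed)
    fis = np.zeros((len(reps), len(feats)))
    counts = np.zeros(len(reps))
    for r, rep in enumerate(reps):
        x_all = rep.table[feats].to_numpy(float)
        y_all = rep.table["group"].to_numpy()
        per_fold = np.zeros((len(rep.metrics.fold_models), len(feats)))
        for fi_idx, fm in enumerate(rep.metrics.fold_models):
            xv = x_all[fm.val_rows]
            yv = y_all[fm.val_rows]
            for j in range(len(feats)):
                per_fold[fi_idx, j] = permutation_importance(
                    fm, xv, yv, j, n_perm=n_perm, rng=rng
                )
        fis[r] = per_fold.mean(axis=0)
        counts[r] = len(rep.metrics.fold_models)
    return pd.Series(fis.mean(axis=0), index=feats, name="fi")


def aggregate_importance(
    per_model: dict[str, pd.Series], mode: str = "sum"
) -> ImportanceResult:
    """Combine per-model FIs into a single cross-model ranking.

    ``sum`` (default) adds the per-model mean FIs; ``mean`` averages them.
    Ranks are over the aggregate, ties broken lexicographically by name.
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    pm = pd.DataFrame(per_model)
    agg = pm.sum(axis=1) if mode == "sum" else pm.mean(axis=1)
    order = sorted(agg.index, key=lambda f: (-agg[f], f))
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order, name="rank"
    ).reindex(agg.index)
    return ImportanceResult(pm, agg, ranks, mode)


def top_fraction(fi: pd.Series, fraction: float = 0.25) -> list[str]:
    """The ceil(fraction * n) features with the highest FI (name tie-break)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = int(np.ceil(fraction * len(fi)))
    order = sorted(fi.index, key=lambda f: (-fi[f], f))
    return order[:k]
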