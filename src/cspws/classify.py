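"""Feature selection, random-forest tuning, and repeated stratified CV.

The evaluation protocol is patient-level, leakage-free by default: within
every training fold, recursive feature elimination (random-forest importance,
dropping the lowest 20 % per round until the panel size is reached) is
followed by grid-search tuning and the final fit; held-out patients are
scored once.  Sensitivity and specificity are reported at the Youden-optimal
threshold of the training scores.  Metrics are summarized as mean +- SD over
the n_folds x n_repeats evaluations.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DEFAULT_RF_GRID",
    "SelectionResult",
    "CVConfig",
    "CVResult",
    "roc_auc",
    "youden_threshold",
    "rfe_select",
    "tune_random_forest",
    "evaluate_repeated_cv",
    "roc_points",
]

#: Grid-search space for the random forest (ties broken by listed order).
DEFAULT_RF_GRID: tuple[dict, ...] = tuple(
    {"n_estimators": n, "max_depth": d, "min_samples_leaf": leaf}
    for n, d, leaf in itertools.product((100, 300, 500), (None, 8), (1, 3))
)


def roc_auc(scores, labels) -> float:
    """Rank-based AUC (Mann-Whitney), ties credited 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 0.5 credit
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def youden_threshold(scores, labels) -> tuple[float, float, float]:
    """Operating point maximizing Se + Sp - 1; ties -> lowest threshold.

    Classification rule: predicted positive iff score >= threshold.
    Returns (threshold, sensitivity, specificity) at that point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    candidates = np.concatenate([uniq, [uniq[-1] + 1.0]])  # include all-negative
    best = None
    for t in candidates:
        pred = scores >= t
        se = float((pred & pos).sum()) / n1
        sp = float((~pred & ~pos).sum()) / n0
        j = se + sp - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, se, sp)
    _, t, se, sp = best
    return float(t), se, sp


def _rf(params: dict, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(random_state=int(seed), n_jobs=1, **params)


@dataclass
class SelectionResult:
    selected_indices: np.ndarray
    elimination_trace: list
    seed: int


def rfe_select(
    features,
    labels,
    n_keep: int = 40,
    step_fraction: float = 0.2,
    seed: int = 0,
    rf_params: dict | None = None,
) -> SelectionResult:
    """Recursive feature elimination with random-forest importance.

    Each round fits a forest on the surviving features and drops the lowest-
    importance ``step_fraction`` of them (never going below ``n_keep``).
    Deterministic given the seed.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    if not 0 < n_keep < x.shape[1]:
        raise ValueError(f"n_keep must be in (0, n_features={x.shape[1]})")
    params = rf_params or {"n_estimators": 100}
    surviving = np.arange(x.shape[1])
    trace = [int(surviving.size)]
    round_i = 0
    while surviving.size > n_keep:
        rf = _rf(params, seed + round_i)
        rf.fit(x[:, surviving], y)
        importance = rf.feature_importances_
        n_next = max(n_keep, int(np.floor(surviving.size * (1.0 - step_fraction))))
        order = np.argsort(importance, kind="stable")[::-1]  # most important first
        surviving = np.sort(surviving[order[:n_next]])
        trace.append(int(surviving.size))
        round_i += 1
    return SelectionResult(
        selected_indices=surviving, elimination_trace=trace, seed=seed
    )


def tune_random_forest(
    features,
    labels,
    grid=DEFAULT_RF_GRID,
    seed: int = 0,
    inner_folds: int = 3,
) -> dict:
    """Exhaustive grid search scored by inner-CV AUC; first-listed wins ties."""
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")
    if len(grid) == 1:
        return dict(grid[0])
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    n_min = int(min(np.sum(y == 1), np.sum(y == 0)))
    folds = max(2, min(inner_folds, n_min))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(x, y))
    best_params, best_auc = None, -np.inf
    for params in grid:
        aucs = []
        for tr, te in splits:
            rf = _rf(params, seed)
            rf.fit(x[tr], y[tr])
            aucs.append(roc_auc(rf.predict_proba(x[te])[:, 1], y[te]))
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:  # strict: ties keep the first-listed set
            best_auc, best_params = mean_auc, params
    return dict(best_params)


@dataclass(frozen=True)
class CVConfig:
    n_folds: int = 4
    n_repeats: int = 5
    stratified: bool = True
    seed: int = 0
    rf_grid: tuple = DEFAULT_RF_GRID
    n_keep: int = 40
    step_fraction: float = 0.2
    pooled_selection: bool = False  # leakage-prone variant, off by default
    tune: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("need n_folds >= 2 and n_repeats >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rf_grid"] = [dict(g) for g in self.rf_grid]
        return d


@dataclass
class Evaluation:
    repeat: int
    fold: int
    auc: float
    sensitivity: float
    specificity: float
    threshold: float
    panel: np.ndarray
    params: dict
    train_index: np.ndarray
    test_index: np.ndarray
    test_scores: np.ndarray


@dataclass
class CVResult:
    evaluations: list
    summary: dict
    config: CVConfig

    def to_json(self, path=None) -> str:
        payload = {
            "summary": self.summary,
            "config": self.config.to_dict(),
            "evaluations": [
                {
                    "repeat": e.repeat,
                    "fold": e.fold,
                    "auc": e.auc,
                    "sensitivity": e.sensitivity,
                    "specificity": e.specificity,
                    "threshold": e.threshold,
                    "panel": e.panel.tolist(),
                    "params": {k: (None if v is None else v) for k, v in e.params.items()},
                    "test_index": e.test_index.tolist(),
                    "test_scores": e.test_scores.tolist(),
                }
                for e in self.evaluations
            ],
        }
        text = json.dumps(payload, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def roc_points(scores, labels) -> np.ndarray:
    """ROC coordinates (threshold, fpr, tpr) at every distinct score cut."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    cuts = np.concatenate([np.unique(scores), [np.inf]])[::-1]
    rows = []
    for t in cuts:
        pred = scores >= t
        rows.append((t, float((pred & ~pos).sum()) / n0,
                     float((pred & pos).sum()) / n1))
    return np.asarray(rows)


def evaluate_repeated_cv(features, labels, cfg: CVConfig | None = None) -> CVResult:
    """Repeated stratified k-fold CV with nested selection and tuning.

    Selection and tuning see only training patients in each evaluation
    (unless ``pooled_selection`` is explicitly enabled, mirroring the
    leakage-prone reading of selecting on all data).  The summary reports
    mean +- SD (ddof=1) of AUC/Se/Sp over all n_folds x n_repeats
    evaluations; the +- convention is recorded in the output metadata.
    """
    cfg = cfg or CVConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n1, n0 = int(np.sum(y == 1)), int(np.sum(y == 0))
    if min(n1, n0) < cfg.n_folds:
        raise ValueError(
            f"class sizes ({n1}, {n0}) too small for {cfg.n_folds}-fold stratification"
        )
    do_select = 0 < cfg.n_keep < x.shape[1]
    pooled_panel = None
    if cfg.pooled_selection and do_select:
        pooled_panel = rfe_select(
            x, y, cfg.n_keep, cfg.step_fraction, seed=cfg.seed
        ).selected_indices
    evaluations: list[Evaluation] = []
    for rep in range(cfg.n_repeats):
        rep_seed = cfg.seed * 1000 + rep
        skf = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=rep_seed
        )
        for fold, (tr, te) in enumerate(skf.split(x, y)):
            if pooled_panel is not None:
                panel = pooled_panel
            elif do_select:
                panel = rfe_select(
                    x[tr], y[tr], cfg.n_keep, cfg.step_fraction, seed=rep_seed
                ).selected_indices
            else:
                panel = np.arange(x.shape[1])
            xtr, xte = x[tr][:, panel], x[te][:, panel]
            if cfg.tune and len(cfg.rf_grid) > 1:
                params = tune_random_forest(xtr, y[tr], cfg.rf_grid, seed=rep_seed)
            else:
                params = dict(cfg.rf_grid[0])
            rf = _rf(params, rep_seed)
            rf.set_params(oob_score=True)
            rf.fit(xtr, y[tr])
            # operating point from the training patients' out-of-bag scores:
            # in-sample forest probabilities are overfit toward 0/1 and would
            # misplace the threshold relative to held-out score scales
            oob = rf.oob_decision_function_[:, 1]
            valid = np.isfinite(oob)
            if valid.sum() >= 4 and len(np.unique(y[tr][valid])) == 2:
                thr, _, _ = youden_threshold(oob[valid], y[tr][valid])
            else:
                thr, _, _ = youden_threshold(rf.predict_proba(xtr)[:, 1], y[tr])
            test_scores = rf.predict_proba(xte)[:, 1]
            auc = roc_auc(test_scores, y[te])
            pred = test_scores >= thr
            pos = y[te] == 1
            se = float((pred & pos).sum()) / max(int(pos.sum()), 1)
            sp = float((~pred & ~pos).sum()) / max(int((~pos).sum()), 1)
            evaluations.append(
                Evaluation(
                    repeat=rep, fold=fold, auc=auc, sensitivity=se,
                    specificity=sp, threshold=thr, panel=np.asarray(panel),
                    params=params, train_index=np.asarray(tr),
                    test_index=np.asarray(te), test_scores=test_scores,
                )
            )
    summary = {"dispersion": "sd over n_folds*n_repeats evaluations (ddof=1)"}
    for name in ("auc", "sensitivity", "specificity"):
        vals = np.array([getattr(e, name) for e in evaluations])
        summary[f"{name}_mean"] = float(vals.mean())
        summary[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return CVResult(evaluations=evaluations, summary=summary, config=cfg)
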