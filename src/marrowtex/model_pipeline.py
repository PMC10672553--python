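"""Discriminant protocol: importance ranking, combinatorial subset search,
class balancing, repeated split + stratified-CV evaluation.

Feature columns are addressed as "<SEQUENCE>:<descriptor>", e.g.
"PDFSE:glcm_joint_max"; each subject contributes one row with the 162
columns of both sequences.

Balancing (bootstrap augmentation followed by SMOTE-style interpolation
to equalize the classes) is applied to training partitions only by
default; ``paper_order=True`` balances before the 70/30 split instead,
reproducing the source protocol at the cost of leaking synthetic copies
of test subjects into training.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .errors import ParameterError, ValidationError
from .feature_names import ALL_FEATURES
from .roi_io import GROUPS, SEQUENCES

DEFAULT_TREE_GRID = (100, 300, 500)
DEFAULT_DEPTH_GRID = (None, 5, 10)
SMOTE_NEIGHBORS = 5


def to_wide(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Join both sequences per subject into one 162-column row."""
    parts = []
    for seq in SEQUENCES:
        sub = table[table["sequence"] == seq].set_index("subject_id")
        part = sub[ALL_FEATURES].rename(columns=lambda c: f"{seq}:{c}")
        parts.append(part)
    wide = parts[0].join(parts[1], how="outer")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValidationError(f"subjects missing one sequence: {missing[:5]}")
    groups = table.drop_duplicates("subject_id").set_index("subject_id")["group"]
    y = groups.loc[wide.index]
    return wide, y


def rank_importance(table: pd.DataFrame, seed: int) -> list[str]:
    """All 162 feature names sorted by random-forest impurity importance, descending."""
    X, y = to_wide(table)
    forest = RandomForestClassifier(n_estimators=500, random_state=seed, n_jobs=1)
    forest.fit(X.to_numpy(), y.to_numpy())
    order = np.argsort(forest.feature_importances_, kind="stable")[::-1]
    return [X.columns[k] for k in order]


def enumerate_combinations(
    top: list[str], k_top: int = 20, max_size: int = 5
) -> list[tuple[str, ...]]:
    """All subsets of the first ``k_top`` features with 1..max_size members."""
    if k_top > len(top):
        raise ParameterError(f"k_top={k_top} exceeds available features ({len(top)})")
    head = list(top[:k_top])
    combos: list[tuple[str, ...]] = []
    for size in range(1, max_size + 1):
        combos.extend(itertools.combinations(head, size))
    return combos


def _smote_synthesize(
    X_class: np.ndarray, n_new: int, rng: np.random.Generator, k: int = SMOTE_NEIGHBORS
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated minority samples; returns (samples, endpoint index pairs)."""
    n = X_class.shape[0]
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_class)
    _, neighbor_idx = nn.kneighbors(X_class)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)  # skip self at position 0
    partner = neighbor_idx[base, pick]
    lam = rng.uniform(0.0, 1.0, size=(n_new, 1))
    synthetic = X_class[base] + lam * (X_class[partner] - X_class[base])
    return synthetic, np.stack([base, partner], axis=1)


def balance_training_set(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    factor: int = 2,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, ...]]]:
    """Bootstrap-augment each class by ``factor``, then SMOTE-equalize the classes.

    Returns (X', y', provenance) where provenance[i] holds the indices of
    the input rows that row i of X' was derived from: a singleton for an
    original or bootstrapped row, an index pair for an interpolated one.
    A class with fewer than 6 members falls back to k = n - 1 neighbors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    aug_X, aug_y, provenance = [], [], []
    for cls in classes:
        idx = np.where(y == cls)[0]
        keep = list(idx)
        n_boot = (factor - 1) * idx.size
        if n_boot > 0:
            keep += list(rng.choice(idx, size=n_boot, replace=True))
        aug_X.append(X[keep])
        aug_y.append(np.full(len(keep), cls, dtype=y.dtype))
        provenance.extend((int(i),) for i in keep)
    sizes = {cls: (y == cls).sum() * factor for cls in classes}
    target = max(sizes.values())
    out_X, out_y = list(aug_X), list(aug_y)
    offset = 0
    for cls, Xc in zip(classes, aug_X):
        n_new = target - Xc.shape[0]
        if n_new > 0:
            class_prov = [provenance[offset + t][0] for t in range(Xc.shape[0])]
            synth, pairs = _smote_synthesize(Xc, n_new, rng)
            out_X.append(synth)
            out_y.append(np.full(n_new, cls, dtype=y.dtype))
            provenance.extend(
                (class_prov[a], class_prov[b]) for a, b in pairs
            )
        offset += Xc.shape[0]
    return np.concatenate(out_X), np.concatenate(out_y), provenance


def _fit_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    seed: int,
    fast: bool,
    tree_grid=DEFAULT_TREE_GRID,
    depth_grid=DEFAULT_DEPTH_GRID,
    cv_folds: int = 10,
):
    if fast:
        model = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        model.fit(X_train, y_train)
        return model
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed, n_jobs=1),
        param_grid={"n_estimators": list(tree_grid), "max_depth": list(depth_grid)},
        cv=cv,
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X_train, y_train)
    return search.best_estimator_


def _test_metrics(model, X_test: np.ndarray, y_test: np.ndarray) -> dict[str, float]:
    pred = model.predict(X_test)
    proba = model.predict_proba(X_test)
    cm = confusion_matrix(y_test, pred, labels=list(GROUPS))
    acc = float(np.trace(cm) / cm.sum())
    metrics = {"acc": acc}
    for gi, g in enumerate(GROUPS):
        row = cm[gi]
        metrics[f"tpr_{g.lower()}"] = float(row[gi] / row.sum()) if row.sum() else 0.0
    metrics["auc"] = float(
        roc_auc_score(
            y_test, proba, multi_class="ovr", average="macro", labels=list(model.classes_)
        )
    )
    return metrics


def evaluate_combination(
    table: pd.DataFrame,
    features: tuple[str, ...] | list[str],
    seed: int,
    paper_order: bool = False,
    factor: int = 2,
    fast: bool = False,
    cv_folds: int = 10,
    tree_grid=DEFAULT_TREE_GRID,
    depth_grid=DEFAULT_DEPTH_GRID,
) -> dict:
    """One stratified 70/30 repetition for one feature combination.

    Balancing and (unless ``fast``) the stratified 10-fold grid search
    touch only the 70% partition; the final model is refit on the full
    balanced training partition and scored on the untouched 30%.
    Returns the test metrics plus row-provenance bookkeeping.
    """
    X, y = to_wide(table)
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ValidationError(f"unknown feature columns: {missing}")
    Xf = X[list(features)].to_numpy()
    yv = y.to_numpy()
    row_ids = np.arange(len(yv))
    if paper_order:
        Xb, yb, prov = balance_training_set(Xf, yv, seed, factor)
        balanced_ids = np.arange(len(yb))
        train_b, test_b = train_test_split(
            balanced_ids, test_size=0.3, stratify=yb, random_state=seed
        )
        X_train, y_train = Xb[train_b], yb[train_b]
        X_test, y_test = Xb[test_b], yb[test_b]
        train_rows = sorted({i for b in train_b for i in prov[b]})
        test_rows = sorted({i for b in test_b for i in prov[b]})
        provenance = [prov[b] for b in train_b]
    else:
        train_idx, test_idx = train_test_split(
            row_ids, test_size=0.3, stratify=yv, random_state=seed
        )
        X_train, y_train, provenance = balance_training_set(
            Xf[train_idx], yv[train_idx], seed, factor
        )
        provenance = [tuple(int(train_idx[i]) for i in tup) for tup in provenance]
        X_test, y_test = Xf[test_idx], yv[test_idx]
        train_rows = sorted(int(i) for i in train_idx)
        test_rows = sorted(int(i) for i in test_idx)
    model = _fit_model(
        X_train, y_train, seed, fast,
        tree_grid=tree_grid, depth_grid=depth_grid, cv_folds=cv_folds,
    )
    metrics = _test_metrics(model, X_test, y_test)
    return {
        **metrics,
        "features": tuple(features),
        "seed": seed,
        "train_rows": train_rows,
        "test_rows": test_rows,
        "train_provenance": provenance,
    }


@dataclass
class ModelEvalReport:
    """Per-repetition test metrics with mean/std aggregates."""

    per_rep: pd.DataFrame
    features: tuple[str, ...]
    base_seed: int

    METRICS = ("acc", "tpr_bme", "tpr_inj", "tpr_ost", "auc")

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.per_rep[m].mean()) for m in self.METRICS}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(self.per_rep[m].std(ddof=1)) for m in self.METRICS}

    def to_frame(self) -> pd.DataFrame:
        """Table with one row per repetition plus an aggregate row."""
        rows = self.per_rep[["repetition", *self.METRICS]].copy()
        agg = {"repetition": "mean (std)"}
        for m in self.METRICS:
            agg[m] = f"{self.mean[m]:.3f} ({self.std[m]:.3f})"
        return pd.concat([rows, pd.DataFrame([agg])], ignore_index=True)


def repeat_evaluation(
    table: pd.DataFrame,
    features,
    base_seed: int,
    n_rep: int = 10,
    paper_order: bool = False,
    factor: int = 2,
    fast: bool = False,
) -> ModelEvalReport:
    """``n_rep`` independent 70/30 repetitions (seeds base_seed..base_seed+n_rep-1)."""
    rows = []
    for r in range(n_rep):
        result = evaluate_combination(
            table, features, base_seed + r, paper_order=paper_order,
            factor=factor, fast=fast,
        )
        rows.append(
            {"repetition": r + 1, **{m: result[m] for m in ModelEvalReport.METRICS}}
        )
    return ModelEvalReport(
        per_rep=pd.DataFrame(rows), features=tuple(features), base_seed=base_seed
    )


def _budget_subsample(
    combos: list[tuple[str, ...]],
    top: list[str],
    budget: int,
    max_size: int,
    rng: np.random.Generator,
) -> list[tuple[str, ...]]:
    """Deterministic budget cut: exhaust the highest-ranked prefix, sample the rest."""
    if budget >= len(combos):
        return combos
    m = 1
    while m < len(top):
        count = sum(
            math.comb(m + 1, k) for k in range(1, min(max_size, m + 1) + 1)
        )
        if count > budget // 2:
            break
        m += 1
    prefix = set(top[:m])
    kept = [c for c in combos if set(c) <= prefix]
    rest = [c for c in combos if not set(c) <= prefix]
    n_fill = budget - len(kept)
    if n_fill > 0 and rest:
        picked = rng.choice(len(rest), size=min(n_fill, len(rest)), replace=False)
        kept += [rest[i] for i in sorted(picked)]
    return kept


def select_composite(
    table: pd.DataFrame,
    base_seed: int,
    n_rep: int = 10,
    k_top: int = 20,
    max_size: int = 5,
    budget: int | None = None,
    factor: int = 2,
    search_trees: int = 50,
) -> tuple[tuple[str, ...], ModelEvalReport]:
    """Search feature combinations across repetitions and return the majority composite.

    Per repetition: one stratified 70/30 split, training-partition
    balancing, a fast random forest per candidate combination, best
    combination by test AUC (ties broken by smaller size, then name
    order).  The composite is the set of features appearing in the
    majority of the per-repetition winners; its performance is
    re-measured with :func:`repeat_evaluation`.  ``budget`` caps the
    number of combinations searched per repetition (exhaustive over the
    highest-ranked prefix, seeded random sample of the remainder).
    """
    ranked = rank_importance(table, base_seed)
    top = ranked[:k_top]
    combos = enumerate_combinations(ranked, k_top=k_top, max_size=max_size)
    if budget is not None:
        rng = np.random.default_rng(base_seed)
        combos = _budget_subsample(combos, top, budget, max_size, rng)

    X, y = to_wide(table)
    X_top = X[top]
    yv = y.to_numpy()
    winners: list[tuple[str, ...]] = []
    winner_aucs: list[float] = []
    for r in range(n_rep):
        seed = base_seed + r
        train_idx, test_idx = train_test_split(
            np.arange(len(yv)), test_size=0.3, stratify=yv, random_state=seed
        )
        # balance once per repetition on the full top-k block; combination
        # columns are then sliced out (interpolation is coordinatewise).
        Xb, yb, _ = balance_training_set(
            X_top.to_numpy()[train_idx], yv[train_idx], seed, factor
        )
        col_of = {name: k for k, name in enumerate(top)}
        best: tuple | None = None
        for combo in combos:
            cols = [col_of[f] for f in combo]
            model = RandomForestClassifier(
                n_estimators=search_trees, random_state=seed, n_jobs=1
            )
            model.fit(Xb[:, cols], yb)
            proba = model.predict_proba(X_top.to_numpy()[test_idx][:, cols])
            auc = roc_auc_score(
                yv[test_idx], proba, multi_class="ovr", average="macro",
                labels=list(model.classes_),
            )
            key = (-auc, len(combo), combo)
            if best is None or key < best[0]:
                best = (key, combo)
        winners.append(best[1])
        winner_aucs.append(-best[0][0])

    counts: dict[str, int] = {}
    for combo in winners:
        for f in combo:
            counts[f] = counts.get(f, 0) + 1
    majority = n_rep // 2 + 1
    composite = tuple(sorted(f for f, c in counts.items() if c >= majority))
    if len(composite) < 2:
        # no stable cross-repetition consensus: fall back to the winning
        # combination with the highest test AUC across repetitions
        composite = tuple(sorted(winners[int(np.argmax(winner_aucs))]))
    report = repeat_evaluation(
        table, composite, base_seed, n_rep=n_rep, factor=factor, fast=True
    )
    return composite, report
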