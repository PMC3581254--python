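"""RBF-kernel SVM classifier with balanced subsampling and protein-level CV.

Catalytic residues are extremely rare (a fraction of a percent of all
residues), so training uses balanced subsets: every positive plus an
equal-sized uniform draw of negatives. Cross-validation folds split
*proteins*, never residues, so no chain contributes rows to both the training
and the test side of a fold. The SVM is a C-SVC with RBF kernel; cost and
gamma are tuned by an inner stratified 5-fold grid search maximizing the
Matthews correlation coefficient, and class probabilities come from Platt
scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ctxflex.features import FeatureTable

__all__ = [
    "SVMConfig", "TrainedModel", "PredictionTable",
    "balanced_subsample", "cv_split", "tune_and_train", "predict",
    "cross_validate", "CVResult",
]

#: libsvm-style default tuning grids.
DEFAULT_COST_GRID = [2.0**k for k in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**k for k in range(-15, 4, 2)]


@dataclass
class SVMConfig:
    """Settings of the training protocol."""

    cost_grid: list[float] = field(default_factory=lambda: list(DEFAULT_COST_GRID))
    gamma_grid: list[float] = field(default_factory=lambda: list(DEFAULT_GAMMA_GRID))
    n_folds: int = 5
    seed: int = 0
    balance: bool = True

    def __post_init__(self) -> None:
        if not self.cost_grid or not self.gamma_grid:
            raise ValueError("tuning grids must be non-empty")
        if any(c <= 0 for c in self.cost_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ValueError("cost and gamma values must be positive")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class TrainedModel:
    """A fitted C-SVC with its chosen hyper-parameters and provenance."""

    estimator: SVC
    cost: float
    gamma: float
    feature_names: list[str]
    inner_cv_mcc: float
    training_keys: list[tuple[str, str, int, str]]  # (pdb, chain, res_seq, icode)


def balanced_subsample(table: FeatureTable, seed: int) -> FeatureTable:
    """All positives plus an equal-count uniform draw of negatives.

    Sampling is without replacement and deterministic given ``seed``.
    """
    pos = np.flatnonzero(table.y == 1)
    neg = np.flatnonzero(table.y == 0)
    if len(pos) == 0:
        raise ValueError("no positive rows to balance against")
    if len(neg) < len(pos):
        raise ValueError(
            f"insufficient negatives ({len(neg)}) for {len(pos)} positives"
        )
    rng = np.random.default_rng(seed)
    chosen_neg = rng.choice(neg, size=len(pos), replace=False)
    idx = np.sort(np.concatenate([pos, chosen_neg]))
    return table.subset(idx)


def cv_split(table: FeatureTable, n_folds: int, seed: int) -> np.ndarray:
    """Assign each row a fold index by partitioning proteins, not residues.

    Proteins are shuffled and split into ``n_folds`` groups of near-equal
    protein count; every residue inherits its protein's fold.
    """
    proteins = table.proteins
    if len(proteins) < n_folds:
        raise ValueError(f"{len(proteins)} proteins < {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    fold_of_protein: dict[tuple[str, str], int] = {}
    for fold, chunk in enumerate(np.array_split(order, n_folds)):
        for i in chunk:
            fold_of_protein[proteins[i]] = fold
    return np.array([fold_of_protein[g] for g in table.groups], dtype=int)


def tune_and_train(train_table: FeatureTable, config: SVMConfig) -> TrainedModel:
    """Grid-search cost x gamma by inner stratified CV on MCC, then refit.

    Ties prefer the smallest cost, then the smallest gamma. The final model
    is refit on the full training table with Platt-scaled probabilities.
    """
    X, y = train_table.X, train_table.y
    if len(np.unique(y)) < 2:
        raise ValueError("training table must contain both classes")
    inner = StratifiedKFold(
        n_splits=config.n_folds, shuffle=True, random_state=config.seed
    )
    splits = list(inner.split(X, y))
    best = (-np.inf, None, None)
    for cost in sorted(config.cost_grid):
        for gamma in sorted(config.gamma_grid):
            preds = np.empty_like(y)
            for tr, te in splits:
                clf = SVC(C=cost, gamma=gamma, kernel="rbf")
                clf.fit(X[tr], y[tr])
                preds[te] = clf.predict(X[te])
            score = matthews_corrcoef(y, preds)
            if score > best[0]:
                best = (score, cost, gamma)
    mcc, cost, gamma = best
    final = SVC(
        C=cost, gamma=gamma, kernel="rbf", probability=True,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        # libsvm's built-in Platt scaling is the calibration we want
        warnings.filterwarnings("ignore", message=".*probability.*", category=FutureWarning)
        final.fit(X, y)
    keys = [
        (g[0], g[1], k[0], k[1])
        for g, k in zip(train_table.groups, train_table.res_keys)
    ]
    return TrainedModel(
        estimator=final,
        cost=cost,
        gamma=gamma,
        feature_names=list(train_table.feature_names),
        inner_cv_mcc=float(mcc),
        training_keys=keys,
    )


#: Columns of a prediction table.
PredictionTable = pd.DataFrame


def predict(model: TrainedModel, table: FeatureTable) -> pd.DataFrame:
    """Score residues: probability of the catalytic class, rank per protein.

    Ranking is by descending probability; ties break by ascending residue
    number (then insertion code). The hard label uses a 0.5 threshold.
    """
    if list(table.feature_names) != list(model.feature_names):
        raise ValueError(
            f"feature mismatch: model has {model.feature_names}, "
            f"table has {table.feature_names}"
        )
    classes = list(model.estimator.classes_)
    proba = model.estimator.predict_proba(table.X)[:, classes.index(1)]
    df = pd.DataFrame({
        "pdb_id": [g[0] for g in table.groups],
        "chain_id": [g[1] for g in table.groups],
        "res_seq": [k[0] for k in table.res_keys],
        "icode": [k[1] for k in table.res_keys],
        "probability": proba,
        "y_true": table.y.astype(int),
    })
    df["predicted"] = (df["probability"] >= 0.5).astype(int)
    df = df.sort_values(
        ["pdb_id", "chain_id", "probability", "res_seq", "icode"],
        ascending=[True, True, False, True, True],
        kind="mergesort",
    )
    df["rank"] = df.groupby(["pdb_id", "chain_id"]).cumcount() + 1
    return df.sort_index()


@dataclass
class CVResult:
    """Outcome of one full balanced-subsampling cross-validation run."""

    predictions: pd.DataFrame           # unbalanced held-out scores (for ROC)
    balanced_predictions: pd.DataFrame  # balanced held-out scores (for MCC tables)
    fold_models: list[TrainedModel]
    fold_of_row: np.ndarray


def cross_validate(
    table: FeatureTable, config: SVMConfig, balance_test: bool = True
) -> CVResult:
    """Run the full protocol: protein folds, balanced training, held-out scoring.

    For each outer fold the training rows are balanced-subsampled (when
    ``config.balance``), cost/gamma are tuned on that subset, and the model
    scores the held-out proteins twice: on all residues (the unbalanced view
    used for ROC analysis) and, when ``balance_test``, on a balanced subsample
    (the view used for sensitivity/specificity/MCC comparisons).
    """
    folds = cv_split(table, config.n_folds, config.seed)
    ss = np.random.SeedSequence(config.seed)
    fold_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(config.n_folds)]
    all_preds: list[pd.DataFrame] = []
    bal_preds: list[pd.DataFrame] = []
    models: list[TrainedModel] = []
    for fold in range(config.n_folds):
        tr_idx = np.flatnonzero(folds != fold)
        te_idx = np.flatnonzero(folds == fold)
        train = table.subset(tr_idx)
        test = table.subset(te_idx)
        if config.balance:
            train = balanced_subsample(train, seed=fold_seeds[fold])
        fold_cfg = SVMConfig(
            cost_grid=config.cost_grid, gamma_grid=config.gamma_grid,
            n_folds=config.n_folds, seed=fold_seeds[fold], balance=config.balance,
        )
        model = tune_and_train(train, fold_cfg)
        models.append(model)
        pred = predict(model, test)
        pred["fold"] = fold
        all_preds.append(pred)
        n_neg_test = len(test) - test.n_positive
        if balance_test and 0 < test.n_positive <= n_neg_test:
            bal_test = balanced_subsample(test, seed=fold_seeds[fold] + 1)
            bpred = predict(model, bal_test)
            bpred["fold"] = fold
            bal_preds.append(bpred)
    return CVResult(
        predictions=pd.concat(all_preds, ignore_index=True),
        balanced_predictions=(
            pd.concat(bal_preds, ignore_index=True) if bal_preds else pd.DataFrame()
        ),
        fold_models=models,
        fold_of_row=folds,
    )
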