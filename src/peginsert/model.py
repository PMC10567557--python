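"""Gradient-boosted prediction of relative insertion efficiency.

The regression target is the z-scored (per screen and replicate) insertion
efficiency; the model is an XGBoost tree ensemble over the ten-feature
vector. Splitting is grouped by insert sequence: every measurement of an
insert, across all sites and cell lines, lands on the same side of the
train/test divide, so held-out performance reflects unseen sequences.

Feature attribution uses exact tree-path additive contributions (the
TreeExplainer algorithm as implemented inside XGBoost): per-feature
contributions plus the bias term sum exactly to the model prediction.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.stats import pearsonr

from peginsert.core import ScreenContext
from peginsert.features import CORE_MANIFEST

#: Final-model hyperparameters: minimum loss reduction 0.1, 100 trees,
#: learning rate 0.1, depth 4, 1e-5 L1 / 0.1 L2 on weights, full column
#: subsample.
DEFAULT_HYPERPARAMS = {
    "gamma": 0.1,
    "n_estimators": 100,
    "learning_rate": 0.1,
    "max_depth": 4,
    "reg_alpha": 0.00001,
    "reg_lambda": 0.1,
    "colsample_bytree": 1.0,
}

#: Default tuning grid for the boosted-tree model.
XGB_GRID = {
    "n_estimators": [1, 5, 10, 50, 100, 500, 1000],
    "max_depth": [1, 2, 3, 4, 5, 7, 10],
    "reg_alpha": [0, 0.001, 0.01, 0.1, 0.5, 1],
    "reg_lambda": [0, 0.001, 0.01, 0.1, 0.5, 1],
    "colsample_bytree": [0.1, 0.3, 0.5, 0.7, 0.9, 1],
    "gamma": [0.001, 0.01, 0.1, 0.5, 1],
    "learning_rate": [0.0001, 0.001, 0.01, 0.1, 0.3, 0.5],
}

#: Feature groups mirrored by the cross-validation comparison: the screen
#: "system" (MMR state, poly-A run), individual sequence effects, and the
#: combined ten-feature model.
FEATURE_SETS = {
    "system": ["mmr_proficient", "max_A_run"],
    "length": ["length"],
    "rtt_structure": ["rtt_structure_z"],
    "composition": ["pct_C", "pct_A", "pct_T"],
    "sequence_total": ["length", "rtt_structure_z", "pct_C", "pct_A", "pct_T"],
    "model": list(CORE_MANIFEST),
}


@dataclass(frozen=True)
class SplitSpec:
    """Grouped train/test partition of unique insert ids."""

    train_ids: frozenset
    test_ids: frozenset
    ratio: float
    seed: int

    def side(self, insert_id: str) -> str:
        return "train" if insert_id in self.train_ids else "test"


def grouped_split(insert_ids: Sequence[str], ratio: float = 0.7, seed: int = 0) -> SplitSpec:
    """Split unique insert ids into train/test at ``ratio``.

    Grouping happens at the sequence level: the returned id sets are
    disjoint, and a caller assigning rows by insert id automatically keeps
    all measurements of one insert on one side.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    unique = sorted(set(insert_ids))
    if len(unique) < 10:
        raise ValueError("need >= 10 unique inserts to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    n_train = int(round(ratio * len(unique)))
    train = frozenset(unique[i] for i in perm[:n_train])
    test = frozenset(unique[i] for i in perm[n_train:])
    return SplitSpec(train_ids=train, test_ids=test, ratio=ratio, seed=seed)


@dataclass
class TrainedModel:
    """A fitted boosted-tree ensemble plus its feature manifest and metadata."""

    booster: xgb.Booster
    manifest: list
    metadata: dict = field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted z-scores for a feature matrix matching the manifest."""
        missing = set(self.manifest) - set(X.columns)
        if missing:
            raise ValueError(f"feature matrix missing columns: {sorted(missing)}")
        dm = xgb.DMatrix(X[self.manifest].to_numpy(dtype=np.float32))
        return self.booster.predict(dm)

    def save(self, path: str | Path) -> None:
        self.booster.set_attr(
            peginsert_manifest=json.dumps(self.manifest),
            peginsert_metadata=json.dumps(self.metadata),
        )
        self.booster.save_model(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        booster = xgb.Booster()
        booster.load_model(str(path))
        manifest = json.loads(booster.attr("peginsert_manifest") or "[]")
        metadata = json.loads(booster.attr("peginsert_metadata") or "{}")
        return cls(booster=booster, manifest=manifest, metadata=metadata)


def _check_features(X: pd.DataFrame) -> None:
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"NaN values in features: {bad}")


def train(
    X: pd.DataFrame,
    y: Sequence[float],
    hyperparams: Optional[dict] = None,
    seed: int = 0,
    metadata: Optional[dict] = None,
) -> TrainedModel:
    """Fit the boosted-tree regressor on z-scored efficiencies."""
    _check_features(X)
    hp = dict(DEFAULT_HYPERPARAMS if hyperparams is None else hyperparams)
    manifest = list(X.columns)
    reg = xgb.XGBRegressor(
        objective="reg:squarederror",
        random_state=seed,
        n_jobs=1,
        **hp,
    )
    reg.fit(X.to_numpy(dtype=np.float32), np.asarray(y, dtype=np.float32))
    meta = {"seed": seed, "hyperparams": hp, "n_rows": len(X)}
    meta.update(metadata or {})
    return TrainedModel(booster=reg.get_booster(), manifest=manifest, metadata=meta)


def _pearson(a, b) -> float:
    return float(pearsonr(np.asarray(a, float), np.asarray(b, float))[0])


def _grouped_folds(groups: np.ndarray, k: int, seed: int):
    """Yield (train_idx, test_idx) with whole groups per fold."""
    unique = np.array(sorted(set(groups)))
    if k > len(unique):
        raise ValueError("k exceeds the number of unique groups")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    fold_of = {}
    for pos, gi in enumerate(perm):
        fold_of[unique[gi]] = pos % k
    fold_ids = np.array([fold_of[g] for g in groups])
    for f in range(k):
        test = np.where(fold_ids == f)[0]
        trainidx = np.where(fold_ids != f)[0]
        yield trainidx, test


def cross_validate(
    X: pd.DataFrame,
    y: Sequence[float],
    groups: Sequence[str],
    feature_sets: Optional[dict] = None,
    k: int = 10,
    hyperparams: Optional[dict] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Grouped k-fold CV performance (Pearson R) per feature set.

    Returns one row per feature set with mean and sd of the per-fold test
    correlation, plus RMSE as a secondary metric.
    """
    sets = FEATURE_SETS if feature_sets is None else feature_sets
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    folds = list(_grouped_folds(groups, k, seed))
    # folds partition the rows exactly
    all_test = np.sort(np.concatenate([t for _, t in folds]))
    assert np.array_equal(all_test, np.arange(len(X)))
    rows = []
    for name, cols in sets.items():
        rs, rmses = [], []
        for tr, te in folds:
            model = train(X.iloc[tr][cols], y[tr], hyperparams, seed=seed)
            pred = model.predict(X.iloc[te][cols])
            if len(te) >= 2 and np.std(pred) > 0:
                rs.append(_pearson(y[te], pred))
            rmses.append(float(np.sqrt(np.mean((y[te] - pred) ** 2))))
        rows.append(
            {
                "feature_set": name,
                "mean_r": float(np.mean(rs)) if rs else float("nan"),
                "sd_r": float(np.std(rs)) if rs else float("nan"),
                "mean_rmse": float(np.mean(rmses)),
                "k": k,
            }
        )
    return pd.DataFrame(rows)


def tune_hyperparameters(
    X: pd.DataFrame,
    y: Sequence[float],
    groups: Sequence[str],
    grid: Optional[dict] = None,
    k: int = 5,
    seed: int = 0,
) -> dict:
    """Pick the grid point with the best mean grouped-CV Pearson R.

    Ties are broken toward the simpler model: fewer trees, then lower
    depth. The full default grid is large; pass a sub-grid for smoke use.
    """
    grid = XGB_GRID if grid is None else grid
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be non-empty")
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    folds = list(_grouped_folds(groups, k, seed))
    best: Optional[tuple] = None
    best_hp: Optional[dict] = None
    keys = list(grid)
    for values in itertools.product(*(grid[kk] for kk in keys)):
        hp = dict(DEFAULT_HYPERPARAMS)
        hp.update(dict(zip(keys, values)))
        rs = []
        for tr, te in folds:
            model = train(X.iloc[tr], y[tr], hp, seed=seed)
            pred = model.predict(X.iloc[te])
            rs.append(_pearson(y[te], pred) if np.std(pred) > 0 else -1.0)
        score = (
            float(np.mean(rs)),
            -hp.get("n_estimators", 0),
            -hp.get("max_depth", 0),
        )
        if best is None or score > best:
            best, best_hp = score, hp
    assert best_hp is not None
    return best_hp


def to_rate(z, context: ScreenContext) -> np.ndarray:
    """Invert model z-scores to percent efficiencies for one screen.

    rate = screen mean + z * screen sd, floored at 0.
    """
    if context.mean_log_efficiency is None or context.sd_log_efficiency is None:
        raise ValueError("context must carry mean/sd to invert z-scores to rates")
    rate = context.mean_log_efficiency + np.asarray(z, float) * context.sd_log_efficiency
    return np.maximum(rate, 0.0)


def attribute(model: TrainedModel, X: pd.DataFrame) -> pd.DataFrame:
    """Exact additive per-feature contributions for each row.

    Columns are the manifest features plus ``bias``; each row sums to the
    model prediction for that row (additivity contract).
    """
    missing = set(model.manifest) - set(X.columns)
    if missing:
        raise ValueError(f"feature matrix missing columns: {sorted(missing)}")
    dm = xgb.DMatrix(X[model.manifest].to_numpy(dtype=np.float32))
    contribs = model.booster.predict(dm, pred_contribs=True)
    return pd.DataFrame(contribs, columns=list(model.manifest) + ["bias"], index=X.index)
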