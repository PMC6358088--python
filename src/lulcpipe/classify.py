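"""Randomized-tree ensemble classification of annual feature tables.

A single 500-tree bagged random-forest model (scikit-learn's
``RandomForestClassifier``, bootstrap resampling, floor(sqrt(7)) = 2
candidate predictors per split, modal vote across trees) is trained on the
labeled site table and applied to every year's features to produce one
categorical map per year. Accuracy is reported on a stratified held-out
20% of sites rather than out-of-bag, which tends to be optimistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .filtering import PREDICTORS


@dataclass(frozen=True)
class EnsembleSpec:
    n_trees: int = 500
    train_fraction: float = 0.8
    predictors: tuple[str, ...] = tuple(PREDICTORS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @property
    def predictors_per_split(self) -> int:
        return max(1, math.floor(math.sqrt(len(self.predictors))))


def split_train_test(table: pd.DataFrame, spec: EnsembleSpec
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-class seeded 80/20 partition, disjoint and exhaustive.

    A class with a single row cannot be stratified; it goes to the training
    side with a warning.
    """
    if len(table) == 0:
        raise ValueError("empty training table")
    rng = np.random.default_rng(spec.seed)
    test_idx: list[np.ndarray] = []
    for lbl, grp in table.groupby("label", sort=True):
        n = len(grp)
        if n < 2:
            warnings.warn(f"class {lbl} has a single row; kept in train")
            continue
        n_test = int(round(n * (1.0 - spec.train_fraction)))
        n_test = min(max(n_test, 1), n - 1)
        take = rng.choice(grp.index.to_numpy(), size=n_test, replace=False)
        test_idx.append(take)
    test_idx = np.sort(np.concatenate(test_idx)) if test_idx else \
        np.empty(0, dtype=int)
    test_mask = table.index.isin(test_idx)
    return table[~test_mask].copy(), table[test_mask].copy()


def train_ensemble(train: pd.DataFrame,
                   spec: EnsembleSpec) -> RandomForestClassifier:
    """Fit the ensemble on the training rows (label + seven predictors)."""
    labels = train["label"].to_numpy()
    if len(np.unique(labels)) < 2:
        raise ValueError("training table must contain at least two classes")
    model = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.predictors_per_split,
        bootstrap=True,
        random_state=int(np.random.SeedSequence(spec.seed)
                         .generate_state(1)[0]) % (2**31),
        n_jobs=1,
    )
    model.fit(train[list(spec.predictors)].to_numpy(), labels)
    return model


def predict_table(model: RandomForestClassifier, features: pd.DataFrame,
                  spec: EnsembleSpec) -> np.ndarray:
    cols = list(spec.predictors)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks predictor columns {missing}")
    return model.predict(features[cols].to_numpy())


def predict_year(model: RandomForestClassifier, features: pd.DataFrame,
                 year: int, shape: tuple[int, int],
                 spec: EnsembleSpec) -> np.ndarray:
    """Full-coverage class raster for one year from that year's features."""
    sub = features[features["year"] == year]
    if len(sub) != shape[0] * shape[1]:
        raise ValueError(f"features for year {year} do not cover the "
                         f"{shape} grid")
    labels = predict_table(model, sub, spec)
    out = np.full(shape, -1, dtype=np.int8)
    out[sub["row"].to_numpy(), sub["col"].to_numpy()] = labels
    return out


def predict_annual_maps(model: RandomForestClassifier,
                        features: pd.DataFrame, shape: tuple[int, int],
                        spec: EnsembleSpec) -> dict[int, np.ndarray]:
    """One categorical raster per year present in the feature table."""
    return {int(y): predict_year(model, features, int(y), shape, spec)
            for y in np.sort(features["year"].unique())}


__all__ = ["EnsembleSpec", "predict_annual_maps", "predict_table",
           "predict_year", "split_train_test", "train_ensemble"]
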