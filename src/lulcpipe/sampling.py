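"""Stratified pure-pixel training design with spatial thinning.

Training sites are coarse pixels whose entire fine-resolution footprint
holds a single class ("pure pixels"). A 1-km grid keeps at most one site
per square kilometre, and an explicit greedy thinning pass guarantees that
every pair of selected sites is separated by at least three pixel widths
(~694 m centre to centre) — one-per-cell selection alone cannot deliver
that bound, since picks in edge-adjacent cells can sit a single pixel
apart.

Sites are plain DataFrames with columns ``row, col, x, y, label, year``;
coordinates are planar metres with the origin at the scene's upper-left
pixel centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .filtering import PREDICTORS
from .scheme import PIXEL_SIZE_M
from .synthetic import TruthSchedule


@dataclass(frozen=True)
class SamplingConfig:
    coarse_cell: float = 1000.0          # spatial-filter grid, metres
    min_separation: float = 3 * PIXEL_SIZE_M   # 693.9 m
    per_class_cap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation >= self.coarse_cell:
            raise ValueError("min_separation must be < coarse_cell")
        if self.per_class_cap is not None and self.per_class_cap < 0:
            raise ValueError("per_class_cap must be >= 0")


def find_pure_pixels(truth: TruthSchedule, year: int) -> pd.DataFrame:
    """All pixels whose every fine sub-cell shares one class in ``year``.

    Returns a site DataFrame (one row per candidate) with the shared class
    as ``label`` and ``year`` set to the inspection year.
    """
    t = truth.year_index(year)
    s = truth.subgrid_factor
    fine = truth.fine_truth[t]
    r, c = truth.shape
    blocks = fine.reshape(r, s, c, s)
    first = blocks[:, 0, :, 0]
    pure = (blocks == first[:, None, :, None]).all(axis=(1, 3))
    rows, cols = np.nonzero(pure)
    return pd.DataFrame({
        "row": rows, "col": cols,
        "x": cols * truth.pixel_size,
        "y": rows * truth.pixel_size,
        "label": first[rows, cols].astype(np.int8),
        "year": int(year),
    })


def spatial_filter(candidates: pd.DataFrame,
                   config: SamplingConfig | None = None) -> pd.DataFrame:
    """Select at most one candidate per 1-km cell, then thin greedily until
    every pair of survivors is at least ``min_separation`` apart.

    Selection is seeded: one random candidate per occupied coarse cell,
    visited in random order, kept only if no previously kept site lies
    within the separation radius.
    """
    config = config or SamplingConfig()
    if len(candidates) == 0:
        import warnings
        warnings.warn("empty candidate set: no sites selected")
        return candidates.copy()
    rng = np.random.default_rng(config.seed)
    cand = candidates.reset_index(drop=True)
    cell = (np.floor(cand["x"].to_numpy() / config.coarse_cell).astype(np.int64)
            * 2**32
            + np.floor(cand["y"].to_numpy() / config.coarse_cell).astype(np.int64))
    order = rng.permutation(len(cand))
    # first candidate met per cell in the shuffled order = random pick per cell
    shuffled_cells = cell[order]
    _, first_idx = np.unique(shuffled_cells, return_index=True)
    picks = order[np.sort(first_idx)]
    picks = picks[rng.permutation(len(picks))]

    xy = cand[["x", "y"]].to_numpy(float)
    kept: list[int] = []
    kept_xy = np.empty((len(picks), 2))
    for i in picks:
        if kept:
            d2 = ((kept_xy[: len(kept)] - xy[i]) ** 2).sum(axis=1)
            if (d2 < config.min_separation**2).any():
                continue
        kept_xy[len(kept)] = xy[i]
        kept.append(int(i))
    out = cand.iloc[sorted(kept)].reset_index(drop=True)
    if config.per_class_cap is not None:
        parts = []
        for lbl, grp in out.groupby("label", sort=True):
            if len(grp) > config.per_class_cap:
                take = rng.choice(len(grp), size=config.per_class_cap,
                                  replace=False)
                grp = grp.iloc[np.sort(take)]
            parts.append(grp)
        out = pd.concat(parts, ignore_index=True)
    return out


def build_training_table(sites: pd.DataFrame,
                         features: pd.DataFrame) -> pd.DataFrame:
    """Join each labeled site with its interpretation-year feature row.

    Result: one row per site, ``label`` plus the seven predictors. Duplicate
    sites and sites without a matching feature row are rejected.
    """
    key = ["row", "col", "year"]
    if sites.duplicated(subset=key).any():
        dup = sites[sites.duplicated(subset=key)].iloc[0]
        raise ValueError(f"duplicate site at row={dup['row']} "
                         f"col={dup['col']} year={dup['year']}")
    merged = sites.merge(features[key + PREDICTORS], on=key, how="left",
                         validate="one_to_one")
    missing = merged[PREDICTORS].isna().any(axis=1)
    if missing.any():
        bad = merged[missing].iloc[0]
        raise ValueError(f"no feature row for site row={bad['row']} "
                         f"col={bad['col']} year={bad['year']}")
    return merged[["row", "col", "year", "label"] + PREDICTORS]


def downsample_majority(table: pd.DataFrame, target_class: int,
                        target_n: int, seed: int = 0) -> pd.DataFrame:
    """Uniformly subsample ``target_class`` rows to ``target_n`` without
    replacement; all other classes pass through untouched."""
    is_target = table["label"] == target_class
    n_avail = int(is_target.sum())
    if target_n > n_avail:
        raise ValueError(f"requested {target_n} rows of class {target_class} "
                         f"but only {n_avail} available")
    rng = np.random.default_rng(seed)
    target_idx = table.index[is_target].to_numpy()
    keep = rng.choice(target_idx, size=target_n, replace=False)
    keep_mask = ~is_target
    keep_mask[keep] = True
    return table[keep_mask].reset_index(drop=True)


def class_counts(table: pd.DataFrame) -> pd.Series:
    return table["label"].value_counts().sort_index()


__all__ = ["SamplingConfig", "build_training_table", "class_counts",
           "downsample_majority", "find_pure_pixels", "spatial_filter"]
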