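"""Temporal split of woody vegetation into forest and secondary vegetation.

Mature forest and shrubby secondary growth are spectrally inseparable in
coarse vegetation-index imagery, but their histories differ: natural
succession back to mature forest takes far longer than the mapped period,
so any woody pixel with a non-woody (farm-like) interlude earlier in the
sequence must be secondary growth. The split is a running-prefix rule —
a pixel is *forest* in year t only if it was woody in every year from the
start of the sequence through t, and *secondary* if woody in t but
non-woody at some earlier year. The first year of the sequence seeds the
history and is consumed, never emitted: a 15-year input yields 14 refined
maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import FOREST, SECONDARY, WOODY
from .synthetic import NOT_WOODY, TruthSchedule


@dataclass
class RefinedMaps:
    """Post-split annual maps.

    ``maps[year]`` is a categorical raster over
    {forest, secondary, wetland, grassland, crop, palm, settlement, water,
    bare}; the woody class never appears. ``woody_history`` packs the
    per-year woody/non-woody record of the *input* series as a bitmask
    (bit k = woody in input year k) for audit.
    """

    maps: dict[int, np.ndarray]
    woody_history: np.ndarray
    input_years: tuple[int, ...]

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.maps))


def split_woody(annual_maps: dict[int, np.ndarray]) -> RefinedMaps:
    """Apply the temporal forest/secondary rule to a series of annual maps.

    Output years are the input years minus the first. Non-woody labels pass
    through unchanged.
    """
    years = sorted(annual_maps)
    if len(years) < 2:
        raise ValueError("woody split needs an initial sequence of at least "
                         "two annual maps")
    shape = annual_maps[years[0]].shape
    for y in years:
        if annual_maps[y].shape != shape:
            raise ValueError(f"map for year {y} has inconsistent extent")

    ever_nonwoody = annual_maps[years[0]] != WOODY
    history = np.zeros(shape, dtype=np.uint32)
    history |= (annual_maps[years[0]] == WOODY).astype(np.uint32)
    refined: dict[int, np.ndarray] = {}
    for k, y in enumerate(years[1:], start=1):
        cur = annual_maps[y]
        woody_now = cur == WOODY
        history |= woody_now.astype(np.uint32) << np.uint32(k)
        out = cur.copy()
        out[woody_now & ~ever_nonwoody] = FOREST
        out[woody_now & ever_nonwoody] = SECONDARY
        refined[y] = out
        ever_nonwoody |= ~woody_now
    return RefinedMaps(maps=refined, woody_history=history,
                       input_years=tuple(years))


def refine_truth(truth: TruthSchedule) -> RefinedMaps:
    """Split applied to the truth's own pixel-level maps (noise-free
    reference for validation)."""
    maps = {int(y): truth.pixel_truth[i]
            for i, y in enumerate(truth.years)}
    return split_woody(maps)


def validate_secondary(refined: RefinedMaps, truth: TruthSchedule,
                       n_sample: int, seed: int = 0) -> dict:
    """Score pixels mapped as secondary vegetation against the truth's
    woody-continuity record.

    A sampled (year, pixel) is correct iff the truth also shows woody cover
    that year with a non-woody interlude since the sequence start. When
    ``n_sample`` exceeds the mapped-secondary population a full census is
    used and flagged. Returns per-year percent agreement plus the pooled
    value (``None`` when no secondary pixels exist).
    """
    rng = np.random.default_rng(seed)
    y0 = refined.input_years[0]
    per_year: dict[int, float] = {}
    n_total = n_correct = 0
    pool: list[tuple[int, int, int]] = []
    for y in refined.years:
        rr, cc = np.nonzero(refined.maps[y] == SECONDARY)
        pool.extend((y, int(a), int(b)) for a, b in zip(rr, cc))
    census = n_sample >= len(pool)
    if not pool:
        return {"per_year": {}, "pooled_percent": None, "n_scored": 0,
                "census": True}
    if census:
        chosen = pool
    else:
        idx = rng.choice(len(pool), size=n_sample, replace=False)
        chosen = [pool[i] for i in idx]
    by_year: dict[int, list[bool]] = {}
    run_start_cache: dict[int, np.ndarray] = {}
    for y, r, c in chosen:
        if y not in run_start_cache:
            run_start_cache[y] = truth.woody_run_start(y)
        rs = run_start_cache[y][r, c]
        truly_secondary = rs != NOT_WOODY and rs > y0
        by_year.setdefault(y, []).append(truly_secondary)
    for y, oks in sorted(by_year.items()):
        per_year[y] = 100.0 * float(np.mean(oks))
        n_total += len(oks)
        n_correct += int(np.sum(oks))
    return {
        "per_year": per_year,
        "pooled_percent": 100.0 * n_correct / n_total,
        "n_scored": n_total,
        "census": census,
    }


__all__ = ["RefinedMaps", "refine_truth", "split_woody", "validate_secondary"]
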