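"""Area time series, trend correlations and transition accounting.

Areas are pixel counts scaled by the nominal pixel area (0.0535 km^2 for a
231.3 m grid). Trends are Pearson correlations of class area against
calendar year within an epoch, with a seeded permutation p-value alongside
the classical t-based one — permutation inference keeps the test
distribution-free while retaining the familiar R statistic. Transition
matrices are exact paired-pixel tallies between a base-year and an
end-year map; deforestation drivers aggregate forest/secondary losses to
grassland, crop, palm and settlement, and reforestation aggregates
grassland/crop/palm conversions to secondary vegetation. Bare ground is
counted for area conservation but excluded from trend and transition
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import (
    DRIVER_CLASSES, PIXEL_AREA_KM2, REFORESTATION_SOURCES, SECONDARY,
    WOODY_REFINED, DEFAULT_SCHEME, ClassScheme,
)
from .splitting import RefinedMaps

_ALL_CODES = tuple(range(10))  # 8 base classes + forest + secondary


def class_area_series(refined: RefinedMaps,
                      region_mask: np.ndarray | None = None,
                      region: str = "all",
                      pixel_area_km2: float = PIXEL_AREA_KM2,
                      scheme: ClassScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Tidy per-region/class/year area table (km^2).

    All classes present in the maps are tallied (including bare, needed for
    conservation checks); downstream trend/transition summaries drop bare.
    """
    some_map = refined.maps[refined.years[0]]
    if region_mask is None:
        region_mask = np.ones(some_map.shape, dtype=bool)
    if region_mask.shape != some_map.shape:
        raise ValueError("region mask not co-registered with maps")
    if not region_mask.any():
        raise ValueError("empty region")
    names = scheme.names
    rows = []
    for y in refined.years:
        vals = refined.maps[y][region_mask]
        counts = np.bincount(vals, minlength=max(_ALL_CODES) + 1)
        for code in _ALL_CODES:
            rows.append({
                "region": region, "year": int(y), "code": code,
                "class": names.get(code, str(code)),
                "n_pixels": int(counts[code]),
                "area_km2": counts[code] * pixel_area_km2,
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendResult:
    region: str
    class_name: str
    period: tuple[int, int]
    r: float
    p_permutation: float
    p_t: float
    n_years: int

    @property
    def direction(self) -> str:
        if np.isnan(self.r) or self.p_permutation > 0.05:
            return "none"
        return "increase" if self.r > 0 else "decrease"


def trend_correlation(series: pd.DataFrame, period: tuple[int, int],
                      class_name: str, region: str = "all",
                      n_permutations: int = 10_000,
                      seed: int = 0) -> TrendResult:
    """Pearson R of area vs. year within ``period`` (inclusive), with a
    seeded permutation p-value (and the classical t-based p alongside).

    A positive R means the class gained area over the epoch. Zero-variance
    series have no defined correlation and are reported as no-trend
    (R = NaN, p = 1).
    """
    sel = series[(series["region"] == region)
                 & (series["class"] == class_name)
                 & series["year"].between(*period)]
    sel = sel.sort_values("year")
    years = sel["year"].to_numpy(float)
    areas = sel["area_km2"].to_numpy(float)
    if len(years) < 3:
        raise ValueError("trend needs at least 3 years in the period")
    if np.ptp(areas) == 0 or np.ptp(years) == 0:
        return TrendResult(region, class_name, period, float("nan"),
                           1.0, 1.0, len(years))
    r, p_t = stats.pearsonr(years, areas)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        rp = np.corrcoef(years, rng.permutation(areas))[0, 1]
        if abs(rp) >= abs(r) - 1e-12:
            hits += 1
    p_perm = (hits + 1) / (n_permutations + 1)
    return TrendResult(region, class_name, period, float(r),
                       float(p_perm), float(p_t), len(years))


@dataclass
class TransitionAccount:
    """Class-by-class area transition tally between two annual maps."""

    base_year: int
    end_year: int
    matrix: pd.DataFrame          # rows = base-year class, cols = end-year
    region: str = "all"

    @property
    def total_area(self) -> float:
        return float(self.matrix.to_numpy().sum())

    def driver_summary(self) -> pd.DataFrame:
        """Deforestation: forest/secondary replaced by a farm-like cover."""
        from .scheme import DEFAULT_SCHEME
        names = DEFAULT_SCHEME.names
        rows = []
        total = 0.0
        for drv in DRIVER_CLASSES:
            area = float(sum(self.matrix.loc[names[src], names[drv]]
                             for src in WOODY_REFINED
                             if names[src] in self.matrix.index))
            rows.append({"driver": names[drv], "area_km2": area})
            total += area
        df = pd.DataFrame(rows)
        df["percent"] = 100.0 * df["area_km2"] / total if total > 0 else 0.0
        return df

    def reforestation_summary(self) -> pd.DataFrame:
        """Farm-like covers at base converted to secondary vegetation."""
        from .scheme import DEFAULT_SCHEME
        names = DEFAULT_SCHEME.names
        rows = []
        total = 0.0
        for src in REFORESTATION_SOURCES:
            if names[src] in self.matrix.index:
                area = float(self.matrix.loc[names[src], names[SECONDARY]])
            else:
                area = 0.0
            rows.append({"source": names[src], "area_km2": area})
            total += area
        df = pd.DataFrame(rows)
        df["percent"] = 100.0 * df["area_km2"] / total if total > 0 else 0.0
        return df

    @property
    def net_deforestation_km2(self) -> float:
        return float(self.driver_summary()["area_km2"].sum())

    @property
    def net_reforestation_km2(self) -> float:
        return float(self.reforestation_summary()["area_km2"].sum())


def transition_matrix(map_base: np.ndarray, map_end: np.ndarray,
                      region_mask: np.ndarray | None = None,
                      base_year: int = 0, end_year: int = 0,
                      region: str = "all",
                      pixel_area_km2: float = PIXEL_AREA_KM2,
                      scheme: ClassScheme = DEFAULT_SCHEME
                      ) -> TransitionAccount:
    """Exact paired-pixel transition tally between two categorical maps.

    Cell (i, j) holds the area labeled i in the base map and j in the end
    map; the grand total therefore equals the region area exactly (integer
    pixel counting). Both maps must share extent and class scheme.
    """
    if map_base.shape != map_end.shape:
        raise ValueError("maps do not share an extent")
    if region_mask is None:
        region_mask = np.ones(map_base.shape, dtype=bool)
    b = map_base[region_mask].astype(np.int64)
    e = map_end[region_mask].astype(np.int64)
    k = max(_ALL_CODES) + 1
    if (b < 0).any() or (b >= k).any() or (e < 0).any() or (e >= k).any():
        raise ValueError("map labels outside the class scheme")
    counts = np.bincount(b * k + e, minlength=k * k).reshape(k, k)
    names = scheme.names
    labels = [names[i] for i in _ALL_CODES]
    mat = pd.DataFrame(counts * pixel_area_km2, index=labels,
                       columns=labels)
    return TransitionAccount(base_year=base_year, end_year=end_year,
                             matrix=mat, region=region)


def percent_point_change(cover_pct_start: float,
                         cover_pct_end: float) -> float:
    """Signed percentage-point difference between two cover fractions."""
    for v in (cover_pct_start, cover_pct_end):
        if not 0.0 <= v <= 100.0:
            raise ValueError("cover percentages must be in [0, 100]")
    return cover_pct_end - cover_pct_start


def epoch_trends(series: pd.DataFrame, periods: tuple[tuple[int, int], ...],
                 region: str = "all", seed: int = 0,
                 n_permutations: int = 10_000,
                 scheme: ClassScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Trend table for every non-bare class over each epoch."""
    rows = []
    classes = [c for c in series["class"].unique()
               if c not in scheme.excluded_from_change]
    for period in periods:
        for i, cls in enumerate(sorted(classes)):
            tr = trend_correlation(series, period, cls, region=region,
                                   n_permutations=n_permutations,
                                   seed=seed + i)
            rows.append({"region": region, "class": cls,
                         "period": f"{period[0]}-{period[1]}",
                         "r": tr.r, "p_permutation": tr.p_permutation,
                         "p_t": tr.p_t, "direction": tr.direction})
    return pd.DataFrame(rows)


__all__ = ["TransitionAccount", "TrendResult", "class_area_series",
           "epoch_trends", "percent_point_change", "transition_matrix",
           "trend_correlation"]
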