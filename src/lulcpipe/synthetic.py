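"""Synthetic landscape generator with known truth.

Emulates the statistical structure the downstream mapping pipeline assumes:

* a spatially coherent categorical landscape (patch mosaic, not i.i.d. noise)
  on a fine sub-pixel grid, with prescribed per-class annual transition
  probabilities applied independently per fine cell;
* per-pixel 16-day composite series (23 per year) for five spectral
  variables (red, NIR, MIR, NDVI, EVI) built from class-specific seasonal
  signatures plus AR(1) noise and additive cloud-spike contamination;
* elevation and slope ancillary rasters whose class tendencies mirror the
  study region (wetlands near sea level, woody cover on higher, steeper
  ground);
* an imperfect "visual interpretation" label source with a configurable
  error rate.

Everything is driven by a single integer seed; identical configurations
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .scheme import (
    BARE, COMPOSITES_PER_YEAR, CROP, DEFAULT_SCHEME, GRASSLAND, PALM,
    PIXEL_SIZE_M, SETTLEMENT, VARIABLES, WATER, WETLAND, WOODY, ClassScheme,
)

#: ``woody_since`` value for pixels that are not woody in the last year.
NOT_WOODY = -1

# stage offsets so each generator stage has an independent, reproducible stream
_STAGE_TRUTH, _STAGE_STACK, _STAGE_ANCILLARY, _STAGE_INTERPRET = range(4)


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


_DEFAULT_PROPORTIONS: dict[int, float] = {
    WOODY: 0.60, WETLAND: 0.06, GRASSLAND: 0.12, CROP: 0.06,
    PALM: 0.05, SETTLEMENT: 0.03, WATER: 0.05, BARE: 0.03,
}

# deforestation pressure on woody cover plus farm abandonment back to woody,
# the two processes the change analysis is meant to recover
_DEFAULT_TRANSITIONS: dict[tuple[int, int], float] = {
    (WOODY, GRASSLAND): 0.010,
    (WOODY, CROP): 0.003,
    (WOODY, PALM): 0.002,
    (WOODY, SETTLEMENT): 0.001,
    (GRASSLAND, WOODY): 0.020,
    (CROP, WOODY): 0.010,
    (PALM, WOODY): 0.005,
}


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    Defaults describe a moderately cloudy tropical mosaic dominated by woody
    cover, with slow deforestation into grassland/crops and faster farm
    abandonment back to woody vegetation.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    pixel_size: float = PIXEL_SIZE_M
    subgrid_factor: int = 3
    year_start: int = 2001
    year_end: int = 2015
    composites_per_year: int = COMPOSITES_PER_YEAR
    class_proportions: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    transition_rates: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(_DEFAULT_TRANSITIONS))
    cloud_prob: float = 0.10
    noise_sd: float = 0.03
    ar1_rho: float = 0.30
    label_error_rate: float = 0.05
    patch_density: float = 0.004  # patch seeds per fine cell
    min_transition_patch: int = 1  # 1 disables post-transition smoothing
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composites_per_year != COMPOSITES_PER_YEAR:
            raise ValueError("composites_per_year is fixed at 23")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.subgrid_factor < 3:
            raise ValueError("subgrid_factor must be >= 3")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        sums: dict[int, float] = {}
        for (i, j), r in self.transition_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"transition rate {(i, j)} outside [0, 1]")
            sums[i] = sums.get(i, 0.0) + r
        for i, s in sums.items():
            if s > 1.0 + 1e-12:
                raise ValueError(
                    f"outgoing transition rates from class {i} sum to {s} > 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1


@dataclass
class SpectralSignature:
    """Per-class seasonal spectra for the five variables.

    ``params[class][variable] = (mean, amplitude, phase)``; the noise-free
    value at composite ``p`` (1..23) is
    ``mean + amplitude * sin(2*pi*(p-1)/23 + phase)``.

    ``cloud_effect`` is the additive bias applied to a contaminated
    composite: indices and NIR are depressed, red is raised.
    """

    params: Mapping[int, Mapping[str, tuple[float, float, float]]]
    cloud_effect: Mapping[str, float]
    min_separation_sd: float = 2.0

    def validate(self, noise_sd: float) -> None:
        """Require every class pair to differ by > ``min_separation_sd`` times
        ``noise_sd`` in at least one variable's mean level."""
        classes = sorted(self.params)
        thr = self.min_separation_sd * noise_sd
        for a in classes:
            for b in classes:
                if b <= a:
                    continue
                gaps = [abs(self.params[a][v][0] - self.params[b][v][0])
                        for v in VARIABLES]
                if max(gaps) <= thr:
                    raise ValueError(
                        f"classes {a} and {b} are spectrally inseparable: "
                        f"max mean gap {max(gaps):.3f} <= {thr:.3f}")
        for v in ("ndvi", "evi"):
            for c in classes:
                if not -1.0 <= self.params[c][v][0] <= 1.0:
                    raise ValueError(f"{v} mean for class {c} outside [-1, 1]")

    def curve(self, cls: int, var: str,
              periods: np.ndarray) -> np.ndarray:
        mean, amp, phase = self.params[cls][var]
        return mean + amp * np.sin(2 * np.pi * (periods - 1) / 23.0 + phase)


def default_signature(noise_sd: float = 0.03) -> SpectralSignature:
    """Built-in signature set; validated for >= 2-sigma mean separation."""
    p = {
        #        red              nir              mir              ndvi             evi
        WOODY: {"red": (0.04, 0.010, 0.0), "nir": (0.35, 0.02, 0.0),
                "mir": (0.12, 0.010, 0.0), "ndvi": (0.85, 0.04, 0.0),
                "evi": (0.50, 0.05, 0.0)},
        WETLAND: {"red": (0.06, 0.010, 0.5), "nir": (0.25, 0.03, 0.5),
                  "mir": (0.08, 0.015, 0.5), "ndvi": (0.55, 0.08, 0.5),
                  "evi": (0.32, 0.06, 0.5)},
        GRASSLAND: {"red": (0.09, 0.02, 1.6), "nir": (0.30, 0.04, 1.6),
                    "mir": (0.22, 0.03, 1.6), "ndvi": (0.60, 0.12, 1.6),
                    "evi": (0.35, 0.10, 1.6)},
        CROP: {"red": (0.11, 0.03, 3.1), "nir": (0.32, 0.05, 3.1),
               "mir": (0.25, 0.04, 3.1), "ndvi": (0.50, 0.20, 3.1),
               "evi": (0.30, 0.15, 3.1)},
        PALM: {"red": (0.05, 0.010, 0.0), "nir": (0.38, 0.02, 0.0),
               "mir": (0.20, 0.015, 0.0), "ndvi": (0.80, 0.03, 0.0),
               "evi": (0.55, 0.04, 0.0)},
        SETTLEMENT: {"red": (0.18, 0.010, 0.0), "nir": (0.24, 0.01, 0.0),
                     "mir": (0.30, 0.010, 0.0), "ndvi": (0.25, 0.03, 0.0),
                     "evi": (0.15, 0.02, 0.0)},
        WATER: {"red": (0.03, 0.005, 0.0), "nir": (0.04, 0.005, 0.0),
                "mir": (0.02, 0.005, 0.0), "ndvi": (-0.10, 0.03, 0.0),
                "evi": (-0.05, 0.02, 0.0)},
        BARE: {"red": (0.22, 0.010, 0.0), "nir": (0.28, 0.01, 0.0),
               "mir": (0.35, 0.010, 0.0), "ndvi": (0.15, 0.03, 0.0),
               "evi": (0.08, 0.02, 0.0)},
    }
    cloud = {"red": +0.25, "nir": -0.15, "mir": -0.08,
             "ndvi": -0.40, "evi": -0.35}
    sig = SpectralSignature(params=p, cloud_effect=cloud)
    sig.validate(noise_sd)
    return sig


@dataclass
class TruthSchedule:
    """Known truth for one scene.

    ``fine_truth`` holds the class of every fine sub-pixel cell per year;
    ``pixel_truth`` its majority aggregation to the 231.3 m grid (ties broken
    toward the lowest class code). ``woody_since`` is the first year of the
    uninterrupted woody run ending at the last year, per pixel, or
    ``NOT_WOODY`` if the pixel is non-woody in the last year — both judged
    at pixel level.
    """

    years: np.ndarray                  # (Y,)
    fine_truth: np.ndarray             # (Y, R*s, C*s) int8
    pixel_truth: np.ndarray            # (Y, R, C) int8
    woody_since: np.ndarray            # (R, C) int32
    patch_id: np.ndarray               # (R*s, C*s) int32
    change_log: pd.DataFrame           # year, from_code, to_code, n_cells
    subgrid_factor: int
    pixel_size: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixel_truth.shape[1:]

    def year_index(self, year: int) -> int:
        idx = int(np.searchsorted(self.years, year))
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in schedule")
        return idx

    def woody_run_start(self, year: int) -> np.ndarray:
        """First year of the uninterrupted woody run ending at ``year``
        (``NOT_WOODY`` where the pixel is non-woody that year)."""
        t = self.year_index(year)
        woody = self.pixel_truth[: t + 1] == WOODY
        out = np.full(self.shape, NOT_WOODY, dtype=np.int32)
        run_start = np.full(self.shape, self.years[0], dtype=np.int32)
        for k in range(t + 1):
            run_start[~woody[k]] = self.years[min(k + 1, t)]
        out[woody[t]] = run_start[woody[t]]
        return out


def _grow_patches(config: SceneConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Multi-source patch mosaic: seed cells drawn by class proportion, every
    fine cell assigned to its nearest seed (simultaneous uniform growth)."""
    fr = config.grid_rows * config.subgrid_factor
    fc = config.grid_cols * config.subgrid_factor
    n_cells = fr * fc
    n_patches = max(len(config.class_proportions),
                    int(round(config.patch_density * n_cells)))
    idx = rng.choice(n_cells, size=n_patches, replace=False)
    seeds_rc = np.column_stack(np.unravel_index(idx, (fr, fc)))
    classes = np.array(sorted(config.class_proportions))
    probs = np.array([config.class_proportions[c] for c in classes], float)
    probs = probs / probs.sum()
    seed_class = rng.choice(classes, size=n_patches, p=probs)
    # jitter breaks distance ties deterministically under the seeded stream
    jitter = rng.uniform(-0.25, 0.25, size=seeds_rc.shape)
    tree = cKDTree(seeds_rc + jitter)
    rr, cc = np.meshgrid(np.arange(fr), np.arange(fc), indexing="ij")
    _, owner = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    patch_id = owner.reshape(fr, fc).astype(np.int32)
    return patch_id, seed_class[patch_id].astype(np.int8)


def _majority_pool(fine: np.ndarray, s: int, n_classes: int) -> np.ndarray:
    """Majority class per s-by-s block; ties go to the lowest class code."""
    fr, fc = fine.shape
    r, c = fr // s, fc // s
    blocks = fine.reshape(r, s, c, s)
    counts = np.stack([(blocks == k).sum(axis=(1, 3))
                       for k in range(n_classes)])
    return counts.argmax(axis=0).astype(np.int8)


def _apply_transitions(prev: np.ndarray, rates: dict[tuple[int, int], float],
                       rng: np.random.Generator,
                       min_patch: int) -> np.ndarray:
    """One annual step: independent per-cell transitions by class, optionally
    followed by removal of changed clusters smaller than ``min_patch``."""
    new = prev.copy()
    u = rng.random(prev.shape)
    by_source: dict[int, list[tuple[int, float]]] = {}
    for (i, j), r in sorted(rates.items()):
        if r > 0:
            by_source.setdefault(i, []).append((j, r))
    for i, outs in by_source.items():
        mask = prev == i
        cum = 0.0
        for j, r in outs:
            sel = mask & (u >= cum) & (u < cum + r)
            new[sel] = j
            cum += r
    if min_patch > 1:
        changed = new != prev
        lab, n = ndimage.label(changed)
        if n:
            sizes = np.bincount(lab.ravel())
            small = sizes < min_patch
            small[0] = False
            revert = small[lab]
            new[revert] = prev[revert]
    return new


def generate_truth(config: SceneConfig,
                   scheme: ClassScheme = DEFAULT_SCHEME) -> TruthSchedule:
    """Build the annual truth rasters for a scene.

    Year 0 is a patch mosaic; each later year applies ``transition_rates``
    independently per fine cell. The per-pair changed-cell counts of every
    step are logged, and the pixel-level woody-continuity record is
    maintained alongside.
    """
    rng = _rng(config.seed, _STAGE_TRUTH)
    patch_id, fine0 = _grow_patches(config, rng)
    n_years = config.n_years
    n_classes = scheme.n_classes
    fine = np.empty((n_years,) + fine0.shape, dtype=np.int8)
    fine[0] = fine0
    log_rows = []
    for t in range(1, n_years):
        fine[t] = _apply_transitions(fine[t - 1], config.transition_rates,
                                     rng, config.min_transition_patch)
        changed = fine[t] != fine[t - 1]
        if changed.any():
            pairs = (fine[t - 1][changed].astype(np.int64) * n_classes
                     + fine[t][changed])
            counts = np.bincount(pairs, minlength=n_classes * n_classes)
            for p in np.nonzero(counts)[0]:
                log_rows.append({"year": int(config.years[t]),
                                 "from_code": int(p // n_classes),
                                 "to_code": int(p % n_classes),
                                 "n_cells": int(counts[p])})
    change_log = pd.DataFrame(
        log_rows, columns=["year", "from_code", "to_code", "n_cells"])

    pixel = np.stack([_majority_pool(fine[t], config.subgrid_factor,
                                     n_classes) for t in range(n_years)])

    woody = pixel == WOODY
    woody_since = np.full(pixel.shape[1:], NOT_WOODY, dtype=np.int32)
    run_start = np.full(pixel.shape[1:], config.year_start, dtype=np.int32)
    for t in range(n_years):
        broke = ~woody[t]
        run_start[broke] = config.years[min(t + 1, n_years - 1)]
    woody_since[woody[-1]] = run_start[woody[-1]]

    return TruthSchedule(years=config.years, fine_truth=fine,
                         pixel_truth=pixel, woody_since=woody_since,
                         patch_id=patch_id, change_log=change_log,
                         subgrid_factor=config.subgrid_factor,
                         pixel_size=config.pixel_size)


@dataclass
class VIStack:
    """Per-pixel composite series for the five spectral variables.

    ``values[var]`` has shape ``(n_composites, rows, cols)`` with
    ``n_composites = 23 * n_years``; ``year_of``/``period_of`` give the
    composite calendar. ``contamination`` marks cloud-polluted composites
    (synthetic runs only; shared across variables, as one cloudy composite
    pollutes every band of that pixel).
    """

    values: dict[str, np.ndarray]
    year_of: np.ndarray            # (T,) calendar year of each composite
    period_of: np.ndarray          # (T,) 16-day period 1..23
    pixel_size: float
    contamination: np.ndarray | None = None  # (T, R, C) bool

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.values.values()))
        return first.shape[1:]

    @property
    def n_layers(self) -> int:
        return len(self.year_of)

    @property
    def years(self) -> np.ndarray:
        return np.unique(self.year_of)

    def validate(self) -> None:
        t = self.n_layers
        if t % COMPOSITES_PER_YEAR != 0:
            raise ValueError("layer count must be a multiple of 23")
        for var, arr in self.values.items():
            if arr.shape[0] != t:
                raise ValueError(f"variable {var} has {arr.shape[0]} layers, "
                                 f"expected {t}")


def _ar1_noise(shape: tuple[int, ...], rho: float, sd: float,
               rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series along axis 0 with marginal std ``sd``."""
    z = rng.standard_normal(shape)
    out = np.empty(shape)
    out[0] = z[0] * sd
    innov_sd = sd * np.sqrt(1.0 - rho * rho)
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + innov_sd * z[t]
    return out


def synthesize_stack(truth: TruthSchedule, sig: SpectralSignature,
                     config: SceneConfig) -> VIStack:
    """Render the composite stack from truth classes and signatures.

    value(t) = class seasonal curve + AR(1) noise (+ cloud_effect where the
    composite is contaminated). Indices are clipped to [-1, 1] and
    reflectances to [0, 1] only when noise or clouds push them outside.
    """
    if truth.pixel_truth.shape[1:] != (config.grid_rows, config.grid_cols):
        raise ValueError("truth extent does not match config")
    rng = _rng(config.seed, _STAGE_STACK)
    n_years = len(truth.years)
    t_total = n_years * COMPOSITES_PER_YEAR
    year_of = np.repeat(truth.years, COMPOSITES_PER_YEAR)
    period_of = np.tile(np.arange(1, COMPOSITES_PER_YEAR + 1), n_years)

    contamination = rng.random((t_total,) + truth.shape) < config.cloud_prob

    periods = np.arange(1, COMPOSITES_PER_YEAR + 1, dtype=float)
    classes = sorted(sig.params)
    values: dict[str, np.ndarray] = {}
    for var in VARIABLES:
        curves = {c: sig.curve(c, var, periods) for c in classes}
        arr = np.empty((t_total,) + truth.shape, dtype=np.float64)
        for ti in range(n_years):
            cls_map = truth.pixel_truth[ti]
            year_curve = np.zeros((COMPOSITES_PER_YEAR,) + truth.shape)
            for c in classes:
                m = cls_map == c
                if m.any():
                    year_curve[:, m] = curves[c][:, None]
            sl = slice(ti * COMPOSITES_PER_YEAR, (ti + 1) * COMPOSITES_PER_YEAR)
            arr[sl] = year_curve
        if config.noise_sd > 0:
            arr += _ar1_noise(arr.shape, config.ar1_rho, config.noise_sd, rng)
        arr[contamination] += sig.cloud_effect[var]
        lo, hi = (-1.0, 1.0) if var in ("ndvi", "evi") else (0.0, 1.0)
        np.clip(arr, lo, hi, out=arr)
        values[var] = arr.astype(np.float32)

    stack = VIStack(values=values, year_of=year_of, period_of=period_of,
                    pixel_size=config.pixel_size, contamination=contamination)
    stack.validate()
    return stack


_ELEVATION_OFFSET = {
    WATER: 0.0, WETLAND: 2.0, SETTLEMENT: 30.0, PALM: 40.0,
    CROP: 50.0, GRASSLAND: 60.0, BARE: 80.0, WOODY: 250.0,
}


def slope_from_elevation(elevation: np.ndarray,
                         pixel_size: float) -> np.ndarray:
    """Terrain slope in degrees via central finite differences (one-sided at
    edges), the standard rise-over-run scheme on a regular grid."""
    gy, gx = np.gradient(elevation.astype(float), pixel_size)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def generate_ancillary(truth: TruthSchedule,
                       config: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Elevation (m) and slope (degrees) rasters at pixel resolution.

    Elevation is a smooth random field plus class-dependent offsets (year-0
    classes): wetlands/water sit near sea level, woody cover on markedly
    higher ground, so terrain correlates with class as in the study region.
    """
    rng = _rng(config.seed, _STAGE_ANCILLARY)
    shape = truth.shape
    rough = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=6.0)
    sd = rough.std()
    rough = rough / sd * 40.0 if sd > 0 else rough
    offsets = np.zeros(shape)
    cls0 = truth.pixel_truth[0]
    for c, off in _ELEVATION_OFFSET.items():
        offsets[cls0 == c] = off
    offsets = ndimage.gaussian_filter(offsets, sigma=2.0)
    elevation = rough + offsets
    slope = slope_from_elevation(elevation, config.pixel_size)
    return elevation, slope


def interpret_labels(truth: TruthSchedule, sites: pd.DataFrame,
                     label_error_rate: float, seed: int | None = None,
                     scheme: ClassScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Simulated visual interpretation of high-resolution imagery.

    Each site receives its pixel-level true class for its interpretation
    year, flipped to a uniformly random *other* class with probability
    ``label_error_rate``. Returns a copy of ``sites`` with a ``label``
    column.
    """
    if not 0.0 <= label_error_rate <= 1.0:
        raise ValueError("label_error_rate must be in [0, 1]")
    rows, cols = truth.shape
    r = sites["row"].to_numpy()
    c = sites["col"].to_numpy()
    if (r < 0).any() or (r >= rows).any() or (c < 0).any() or (c >= cols).any():
        raise IndexError("site outside scene extent")
    rng = _rng(truth_seed_or(seed), _STAGE_INTERPRET)
    years = sites["year"].to_numpy()
    labels = np.empty(len(sites), dtype=np.int8)
    for y in np.unique(years):
        m = years == y
        labels[m] = truth.pixel_truth[truth.year_index(int(y))][r[m], c[m]]
    flip = rng.random(len(sites)) < label_error_rate
    if flip.any():
        n_cls = scheme.n_classes
        # uniform over the n-1 wrong labels
        shift = rng.integers(1, n_cls, size=int(flip.sum()))
        labels[flip] = (labels[flip] + shift) % n_cls
    out = sites.copy()
    out["label"] = labels
    return out


def truth_seed_or(seed: int | None) -> int:
    return 0 if seed is None else int(seed)


__all__ = [
    "SceneConfig", "SpectralSignature", "TruthSchedule", "VIStack",
    "NOT_WOODY", "default_signature", "generate_truth", "synthesize_stack",
    "generate_ancillary", "slope_from_elevation", "interpret_labels",
]
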