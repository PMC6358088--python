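"""Gaussian-weighted temporal cleaning of composite series.

Cloud-polluted vegetation-index series are cleaned one year-cycle at a time:
each 23-composite year is smoothed with a normalized discrete Gaussian
kernel (window 5, sigma 1 composite, reflected edges), composites whose
residual against the smoothed curve is large relative to a robust spread
estimate are flagged as outliers and replaced by the smoothed estimate, and
the smooth/flag/replace cycle is repeated for a configurable number of
passes. Unflagged composites are returned bit-identical. Annual means of the
cleaned series, together with elevation and slope, form the classifier's
seven predictors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .scheme import COMPOSITES_PER_YEAR, VARIABLES
from .synthetic import VIStack

#: 1/Phi^{-1}(3/4): scales the median absolute deviation to a normal sigma.
MAD_TO_SIGMA = 1.4826022185056018


@dataclass(frozen=True)
class FilterConfig:
    """Temporal-filter parameters.

    window
        Kernel length in composites; odd, default 5.
    kernel_sigma
        Gaussian sigma in composites, default 1.0.
    outlier_k
        Flag threshold in robust standard deviations (MAD-based), default 2.5.
    min_resid
        Absolute residual floor (variable units) below which a composite is
        never flagged, default 0.03. The smoother attenuates a seasonal
        curve by a few percent of its amplitude, so purely systematic
        residuals stay below ~0.02 for the strongest seasonal classes; the
        floor keeps those from being mistaken for outliers on low-noise
        series while every cloud bias (>= 0.08) remains well above it.
    passes
        Number of smooth/flag/replace iterations, default 2.
    """

    window: int = 5
    kernel_sigma: float = 1.0
    outlier_k: float = 2.5
    min_resid: float = 0.03
    passes: int = 2

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.kernel_sigma <= 0:
            raise ValueError("kernel_sigma must be positive")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")

    @property
    def kernel(self) -> np.ndarray:
        """Normalized discrete Gaussian weights over the window."""
        half = self.window // 2
        lags = np.arange(-half, half + 1, dtype=float)
        w = np.exp(-0.5 * (lags / self.kernel_sigma) ** 2)
        return w / w.sum()


def gaussian_smooth(series: np.ndarray, config: FilterConfig | None = None,
                    axis: int = -1) -> np.ndarray:
    """Kernel-weighted moving average along ``axis`` with reflected edges."""
    config = config or FilterConfig()
    series = np.asarray(series, dtype=float)
    if not np.isfinite(series).all():
        raise ValueError("series contains non-finite values")
    if config.window > series.shape[axis]:
        raise ValueError("window longer than series")
    return ndimage.correlate1d(series, config.kernel, axis=axis,
                               mode="reflect")


def replace_outliers(series: np.ndarray, config: FilterConfig | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Clean one year-cycle (or an array of them along the last axis).

    A composite is flagged iff |raw - smoothed| exceeds ``outlier_k`` robust
    standard deviations of that cycle's residuals (MAD x 1.4826); flagged
    values are replaced by the smoothed estimate. The smooth/flag/replace
    cycle runs for ``passes`` iterations with flags re-derived against the
    *raw* series each time, so composites whose first-pass residual was
    inflated only by a neighbouring spike are released once that spike has
    been replaced in the smoothing reference. An all-identical cycle has
    zero MAD and is returned untouched. Returns ``(cleaned, flags)`` where
    unflagged entries of ``cleaned`` are the raw values verbatim.
    """
    config = config or FilterConfig()
    raw = np.asarray(series, dtype=float)
    working = raw.copy()
    flags = np.zeros(raw.shape, dtype=bool)
    kernel = config.kernel
    for _ in range(config.passes):
        smoothed = gaussian_smooth(working, config, axis=-1)
        resid = raw - smoothed
        med = np.median(resid, axis=-1, keepdims=True)
        mad = np.median(np.abs(resid - med), axis=-1, keepdims=True)
        sigma = MAD_TO_SIGMA * mad
        thr = np.maximum(config.outlier_k * sigma, config.min_resid)
        flags = (np.abs(resid) > thr) & (sigma > 0)
        # Gaussian-weighted estimate from unflagged composites only: the
        # kernel is renormalized over the clean neighbours so a flagged
        # spike cannot contaminate its own replacement value
        good = ~flags
        num = ndimage.correlate1d(np.where(good, raw, 0.0), kernel,
                                  axis=-1, mode="reflect")
        den = ndimage.correlate1d(good.astype(float), kernel, axis=-1,
                                  mode="reflect")
        est = np.where(den > 1e-12, num / np.maximum(den, 1e-12), smoothed)
        working = np.where(flags, est, raw)
    return working, flags


def filter_stack(stack: VIStack, config: FilterConfig | None = None
                 ) -> tuple[VIStack, dict[str, np.ndarray]]:
    """Clean every pixel, variable and year-cycle of a stack.

    Year cycles are independent: no information crosses the 23-composite
    year boundary. Returns the cleaned stack (same shape and calendar) and
    the per-variable outlier flags.
    """
    config = config or FilterConfig()
    stack.validate()
    t, (r, c) = stack.n_layers, stack.shape
    n_years = t // COMPOSITES_PER_YEAR
    values: dict[str, np.ndarray] = {}
    all_flags: dict[str, np.ndarray] = {}
    for var, arr in stack.values.items():
        # (T, R, C) -> (years, R, C, 23): each row is one pixel's year-cycle
        cyc = (arr.reshape(n_years, COMPOSITES_PER_YEAR, r, c)
               .transpose(0, 2, 3, 1))
        cleaned, flags = replace_outliers(cyc, config)
        back = cleaned.transpose(0, 3, 1, 2).reshape(t, r, c)
        fback = flags.transpose(0, 3, 1, 2).reshape(t, r, c)
        lo, hi = (-1.0, 1.0) if var in ("ndvi", "evi") else (0.0, 1.0)
        np.clip(back, lo, hi, out=back)
        values[var] = back.astype(arr.dtype)
        all_flags[var] = fback
    out = VIStack(values=values, year_of=stack.year_of,
                  period_of=stack.period_of, pixel_size=stack.pixel_size,
                  contamination=stack.contamination)
    return out, all_flags


def consensus_flags(flags: dict[str, np.ndarray],
                    min_votes: int = 3) -> np.ndarray:
    """Combine per-variable outlier flags into one contamination verdict.

    Cloud pollution hits every band of a composite at once, so a composite
    is called contaminated when at least ``min_votes`` of the five
    variables flag it — consensus suppresses single-band noise flags
    without losing genuinely cloudy composites.
    """
    votes = sum(f.astype(np.int8) for f in flags.values())
    return votes >= min_votes


def annual_means(stack: VIStack, elevation: np.ndarray,
                 slope: np.ndarray) -> pd.DataFrame:
    """Reduce a (cleaned) stack to the classifier's feature table.

    One row per pixel-year with the annual mean of each spectral variable
    plus elevation and slope replicated across years — seven predictors.
    """
    stack.validate()
    r, c = stack.shape
    if elevation is None or slope is None:
        raise ValueError("elevation and slope rasters are required")
    if elevation.shape != (r, c) or slope.shape != (r, c):
        raise ValueError("ancillary rasters not co-registered with stack")
    years = stack.years
    n_years = len(years)
    rows_idx, cols_idx = np.meshgrid(np.arange(r), np.arange(c),
                                     indexing="ij")
    frames = []
    for yi, year in enumerate(years):
        sel = stack.year_of == year
        d = {
            "row": rows_idx.ravel(), "col": cols_idx.ravel(),
            "year": np.full(r * c, int(year)),
        }
        for var in stack.variables:
            d[var] = stack.values[var][sel].mean(axis=0,
                                                 dtype=np.float64).ravel()
        d["elevation"] = elevation.ravel().astype(float)
        d["slope"] = slope.ravel().astype(float)
        frames.append(pd.DataFrame(d))
    table = pd.concat(frames, ignore_index=True)
    if table[PREDICTORS].isna().any().any():
        raise ValueError("feature table contains missing values")
    return table


#: Column names of the seven predictors, in canonical order.
PREDICTORS = list(VARIABLES) + ["elevation", "slope"]

__all__ = ["FilterConfig", "MAD_TO_SIGMA", "PREDICTORS", "annual_means",
           "consensus_flags", "filter_stack", "gaussian_smooth",
           "replace_outliers"]
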