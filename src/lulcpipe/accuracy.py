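"""Confusion-matrix accuracy assessment.

Overall accuracy, Cohen's kappa with the poor/good/excellent banding used
throughout the pipeline, and per-class omission (miss rate against the
reference marginal) and commission (false-alarm rate against the predicted
marginal) errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scheme import DEFAULT_SCHEME, ClassScheme

#: Kappa agreement bands; the boundary K = 0.75 is assigned to "good" and
#: 0.4 to "good" (closed lower boundary) — configurable via kappa_category.
KAPPA_BANDS = ((0.4, "poor"), (0.75, "good"))


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of reference (rows) against predicted (columns)."""

    counts: pd.DataFrame

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        m = self.counts.to_numpy()
        return float(np.trace(m) / m.sum())

    @property
    def kappa(self) -> float:
        """Chance-corrected agreement K = (po - pe) / (1 - pe)."""
        m = self.counts.to_numpy(float)
        n = m.sum()
        po = np.trace(m) / n
        pe = float((m.sum(axis=1) / n) @ (m.sum(axis=0) / n))
        if pe == 1.0:
            return 1.0 if po == 1.0 else 0.0
        return float((po - pe) / (1.0 - pe))

    def omission(self) -> pd.Series:
        """Per-class misses / reference total (producer's error)."""
        m = self.counts.to_numpy(float)
        ref = m.sum(axis=1)
        with np.errstate(invalid="ignore"):
            rates = np.where(ref > 0, 1.0 - np.diag(m) / ref, np.nan)
        return pd.Series(rates, index=self.counts.index, name="omission")

    def commission(self) -> pd.Series:
        """Per-class false alarms / predicted total (user's error)."""
        m = self.counts.to_numpy(float)
        pred = m.sum(axis=0)
        with np.errstate(invalid="ignore"):
            rates = np.where(pred > 0, 1.0 - np.diag(m) / pred, np.nan)
        return pd.Series(rates, index=self.counts.columns, name="commission")

    def to_report(self) -> pd.DataFrame:
        """Matrix with marginal totals plus omission/commission margins,
        mirroring a standard published confusion-matrix layout."""
        rep = self.counts.copy().astype(float)
        rep["ref_total"] = rep.sum(axis=1)
        rep["omission"] = self.omission()
        bottom = pd.DataFrame(
            [self.counts.sum(axis=0), self.commission()],
            index=["pred_total", "commission"])
        return pd.concat([rep, bottom])


def confusion(reference, predicted,
              scheme: ClassScheme = DEFAULT_SCHEME,
              labels: list[int] | None = None) -> ConfusionMatrix:
    """Cross-tabulate two equal-length label sequences over one scheme."""
    ref = np.asarray(reference).ravel()
    pred = np.asarray(predicted).ravel()
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted differ in length")
    valid = set(scheme.codes.values())
    observed = set(np.unique(ref)) | set(np.unique(pred))
    if not observed <= valid:
        raise ValueError(f"labels {sorted(observed - valid)} outside scheme")
    if labels is None:
        labels = sorted(observed)
    k = len(labels)
    pos = {lbl: i for i, lbl in enumerate(labels)}
    idx = np.array([pos[v] for v in ref]) * k \
        + np.array([pos[v] for v in pred])
    counts = np.bincount(idx, minlength=k * k).reshape(k, k)
    names = [scheme.names[c] for c in labels]
    return ConfusionMatrix(pd.DataFrame(counts, index=names, columns=names))


def kappa_category(k: float,
                   bands: tuple[tuple[float, str], ...] = KAPPA_BANDS
                   ) -> str:
    """Band label for a kappa value: poor (< 0.4), good (0.4..0.75,
    boundaries inclusive), excellent (> 0.75)."""
    if not -1.0 <= k <= 1.0:
        raise ValueError("kappa outside [-1, 1]")
    if k < bands[0][0]:
        return "poor"
    if k <= bands[1][0]:
        return "good"
    return "excellent"


def interpretation_agreement(labels_a, labels_b,
                             scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
    """Kappa and overall accuracy between two label sources for the same
    sites (e.g. a synthetic interpreter scored against truth)."""
    cm = confusion(labels_a, labels_b, scheme=scheme)
    return {"kappa": cm.kappa, "accuracy": cm.accuracy, "n": cm.n,
            "category": kappa_category(max(-1.0, min(1.0, cm.kappa)))}


def kappa_summary(kappas: list[float]) -> dict:
    """Mean and standard deviation of per-year kappas."""
    arr = np.asarray(kappas, float)
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
            "n_years": len(arr)}


__all__ = ["ConfusionMatrix", "KAPPA_BANDS", "confusion",
           "interpretation_agreement", "kappa_category", "kappa_summary"]
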