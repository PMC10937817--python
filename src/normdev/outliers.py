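"""Outlier flags, total outlier counts, prevalence maps and STS status.

A region is an *outlier* for a subject when its deviation z-score falls
strictly below a negative threshold (default -1.96, the lower 2.5% tail
of the standard normal).  Only negative deviations are flagged: the
analysis targets neurodegeneration-related cortical thinning.  The
*total outlier count* (TOC) per subject is the number of flagged
regions, between 0 and 148.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import STS_LEFT, STS_RIGHT, region_mask

DEFAULT_THRESHOLD = -1.96

try:
    from sklearn.base import BaseEstimator, TransformerMixin
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore
        pass

    class TransformerMixin:  # type: ignore
        def fit_transform(self, X, y=None, **kw):
            return self.fit(X, **kw).transform(X)


class OutlierThresholder(BaseEstimator, TransformerMixin):
    """Stateless transformer: z-score matrix -> binary outlier flags.

    ``threshold`` must be negative; a score exactly equal to the
    threshold is *not* an outlier (strict inequality).
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD):
        self.threshold = threshold

    def fit(self, Z=None, y=None):
        if not self.threshold < 0:
            raise ValueError(
                f"threshold must be negative (lower-tail), got {self.threshold}")
        return self

    def transform(self, Z: pd.DataFrame) -> pd.DataFrame:
        self.fit()
        values = np.asarray(Z, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("z-scores must be finite")
        flags = (values < self.threshold).astype(np.int8)
        if isinstance(Z, pd.DataFrame):
            return pd.DataFrame(flags, index=Z.index, columns=Z.columns)
        return pd.DataFrame(flags)


def flag_outliers(z: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Binary outlier flags: 1 where z < threshold (strict), else 0."""
    return OutlierThresholder(threshold).transform(z)


def _check_binary(o) -> np.ndarray:
    arr = np.asarray(o)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("outlier matrix must be binary (0/1)")
    return arr.astype(np.int64)


def total_outlier_count(o: pd.DataFrame) -> pd.Series:
    """Per-subject number of outlier regions (0..n_regions)."""
    arr = _check_binary(o)
    counts = arr.sum(axis=1)
    index = o.index if isinstance(o, pd.DataFrame) else None
    return pd.Series(counts, index=index, name="total_outlier_count")


def outlier_prevalence(o: pd.DataFrame) -> pd.DataFrame:
    """Per-region outlier prevalence, % of subjects, ranked descending.

    Returns a DataFrame indexed by region with columns ``prevalence_pct``
    and ``rank`` (1 = most prevalent); row order follows the input
    column order so it can be joined back onto the atlas.
    """
    arr = _check_binary(o)
    if arr.shape[0] < 1:
        raise ValueError("prevalence needs at least one subject")
    pct = 100.0 * arr.mean(axis=0)
    cols = o.columns if isinstance(o, pd.DataFrame) else pd.RangeIndex(arr.shape[1])
    out = pd.DataFrame({"prevalence_pct": pct}, index=pd.Index(cols, name="region"))
    order = np.argsort(-pct, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    out["rank"] = ranks
    return out


def sts_status(o: pd.DataFrame, atlas: pd.DataFrame) -> pd.Series:
    """Superior-temporal-sulcus outlier status per subject.

    ``bilateral`` if both hemispheres' STS are flagged, ``unilateral``
    if exactly one, ``none`` otherwise.
    """
    arr = _check_binary(o)
    names = list(o.columns)
    try:
        li, ri = names.index(STS_LEFT), names.index(STS_RIGHT)
    except ValueError as exc:
        raise KeyError(f"outlier matrix lacks STS columns: {exc}")
    both = arr[:, li] + arr[:, ri]
    labels = np.where(both == 2, "bilateral", np.where(both == 1, "unilateral", "none"))
    return pd.Series(labels, index=o.index, name="sts_status")


def lobe_prevalence_summary(o: pd.DataFrame, atlas: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of regional prevalence within temporal vs extratemporal."""
    prev = outlier_prevalence(o)["prevalence_pct"].to_numpy()
    rows = []
    for lobe in ("temporal", "extratemporal"):
        mask = region_mask(atlas, lobe_group=lobe)
        vals = prev[mask]
        rows.append({"lobe_group": lobe, "n_regions": int(mask.sum()),
                     "mean_prevalence_pct": float(vals.mean()),
                     "sd_prevalence_pct": float(vals.std(ddof=1))})
    return pd.DataFrame(rows).set_index("lobe_group")


@dataclass
class OutlierSummary:
    """Bundle of per-subject and per-region outlier statistics."""

    total_outlier_count: pd.Series
    prevalence: pd.DataFrame
    sts_status: pd.Series
    lobe_summary: pd.DataFrame


def summarize_outliers(o: pd.DataFrame, atlas: pd.DataFrame) -> OutlierSummary:
    return OutlierSummary(
        total_outlier_count=total_outlier_count(o),
        prevalence=outlier_prevalence(o),
        sts_status=sts_status(o, atlas),
        lobe_summary=lobe_prevalence_summary(o, atlas),
    )
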