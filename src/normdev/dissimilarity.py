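"""Hamming-distance heterogeneity of binary outlier patterns.

The Hamming distance between two subjects is the number of regions at
which their outlier flags disagree (raw counts over 148 regions, not
normalised — group medians are then on the same count scale as total
outlier counts).  Intragroup heterogeneity is summarised by each
subject's median distance to same-group peers; groups are compared by
regressing those per-subject medians on group membership, optionally
with a seeded label-permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .stats import StatResult


def hamming_matrix(o: pd.DataFrame) -> pd.DataFrame:
    """Subjects x subjects matrix of discordant-flag counts."""
    arr = np.asarray(o)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("outlier matrix must be binary (0/1)")
    if arr.shape[0] < 2:
        raise ValueError("need at least two subjects")
    d = squareform(pdist(arr.astype(bool), metric="hamming")) * arr.shape[1]
    d = np.rint(d).astype(np.int64)
    idx = o.index if isinstance(o, pd.DataFrame) else None
    return pd.DataFrame(d, index=idx, columns=idx)


@dataclass
class DissimilaritySummary:
    group: str
    n: int
    subject_medians: pd.Series
    median: float
    iqr: float
    off_diagonal: np.ndarray = field(repr=False, default=None)


def _subject_medians(H: np.ndarray) -> np.ndarray:
    n = H.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return np.array([np.median(H[i][mask[i]]) for i in range(n)])


def group_dissimilarity(H: pd.DataFrame, groups: pd.Series) -> dict[str, DissimilaritySummary]:
    """Per-group heterogeneity summaries from a Hamming matrix.

    For every subject: the median distance to other members of the same
    group; per group: the median and IQR of those per-subject medians,
    plus the pooled off-diagonal distance distribution.  Singleton
    groups are skipped with a warning.
    """
    import warnings

    Hv = np.asarray(H)
    labels_arr = np.asarray(groups)
    out: dict[str, DissimilaritySummary] = {}
    for g in pd.unique(labels_arr):
        pos = np.flatnonzero(labels_arr == g)
        if len(pos) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 members; skipped")
            continue
        sub = Hv[np.ix_(pos, pos)]
        med = _subject_medians(sub)
        q25, q75 = np.percentile(med, [25, 75])
        tri = sub[np.triu_indices_from(sub, k=1)]
        out[str(g)] = DissimilaritySummary(
            group=str(g), n=len(pos),
            subject_medians=pd.Series(med, index=H.index[pos]),
            median=float(np.median(med)), iqr=float(q75 - q25),
            off_diagonal=tri,
        )
    return out


def _median_anova_f(Hv: np.ndarray, codes: np.ndarray, k: int):
    """One-way ANOVA F over per-subject within-group median distances.

    Equivalent to regressing the per-subject medians on group dummies;
    returns (F, group mean medians, per-subject medians) or (nan, ...)
    when degenerate.
    """
    n = len(codes)
    med = np.empty(n)
    means = np.empty(k)
    for g in range(k):
        pos = np.flatnonzero(codes == g)
        sub = Hv[np.ix_(pos, pos)]
        m = sub.shape[0]
        mask = ~np.eye(m, dtype=bool)
        vals = sub[mask].reshape(m, m - 1)
        med[pos] = np.median(vals, axis=1)
        means[g] = med[pos].mean()
    grand = med.mean()
    ssb = sum(np.sum(codes == g) * (means[g] - grand) ** 2 for g in range(k))
    ssw = sum(((med[codes == g] - means[g]) ** 2).sum() for g in range(k))
    df1, df2 = k - 1, n - k
    if ssw <= 0 or df2 < 1:
        return float("nan"), means, med
    return float((ssb / df1) / (ssw / df2)), means, med


def compare_group_dissimilarity(
    H: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> StatResult:
    """Test group differences in per-subject median Hamming distance.

    The per-subject median distance to same-group peers is regressed on
    group membership (equivalently, a one-way ANOVA over the medians);
    the coefficient (difference of group means, first contrast) and F
    statistic are reported.  Because the pairwise distances entering the
    medians are mutually dependent, the parametric F distribution is
    strongly anti-conservative here; the reported ``p`` therefore comes
    from a seeded label-permutation null (default 1000 permutations),
    with the parametric p retained in ``extra["p_parametric"]``.  Set
    ``n_permutations=0`` to report the parametric p instead.
    """
    import scipy.stats as sps

    Hv = np.asarray(H, dtype=float)
    labels_arr = np.asarray(groups)
    levels, codes = np.unique(labels_arr, return_inverse=True)
    sizes = np.bincount(codes, minlength=len(levels))
    keep_levels = [i for i in range(len(levels)) if sizes[i] >= 2]
    if len(keep_levels) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    if len(keep_levels) < len(levels):
        import warnings
        dropped = [str(levels[i]) for i in range(len(levels)) if i not in keep_levels]
        warnings.warn(f"singleton group(s) skipped: {dropped}")
        sel = np.isin(codes, keep_levels)
        Hv = Hv[np.ix_(sel, sel)]
        labels_arr = labels_arr[sel]
        levels, codes = np.unique(labels_arr, return_inverse=True)
        sizes = np.bincount(codes)
    k, n = len(levels), len(codes)
    f_obs, means, _ = _median_anova_f(Hv, codes, k)
    df = (k - 1, n - k)
    if not np.isfinite(f_obs):
        return StatResult(name="median_hamming_regression", effect=float("nan"),
                          statistic=float("nan"), stat_name="F", df=df,
                          p=float("nan"), group_sizes=tuple(int(s) for s in sizes),
                          extra={"estimable": False})
    p_param = float(sps.f.sf(f_obs, *df))
    extra = {"groups": [str(l) for l in levels],
             "group_mean_medians": means.tolist(), "p_parametric": p_param}
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            f_p, _, _ = _median_anova_f(Hv, rng.permutation(codes), k)
            if np.isfinite(f_p) and f_p >= f_obs:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        extra["n_permutations"] = n_permutations
    else:
        p = p_param
    return StatResult(
        name="median_hamming_regression",
        effect=float(means[1] - means[0]),
        statistic=f_obs, stat_name="F", df=df, p=float(p),
        group_sizes=tuple(int(s) for s in sizes),
        extra=extra,
    )
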