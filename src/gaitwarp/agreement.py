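"""Method-comparison statistics: Bland-Altman agreement, Pearson correlation,
one-sample t-tests with Bonferroni correction, and trial-level summaries.

Differences are taken markerless minus reference, so a positive bias means
the markerless system overestimates the angle.  The 95% limits of agreement
are bias +/- 1.96 x SD of the differences with the sample (n-1) SD, the
convention for agreement studies.

Frame-level pairs within a trial are treated as independent observations, as
is common in concurrent-validity studies; no repeated-measures correction is
applied (a known inferential caveat, see the package methods note).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "LOA_MULTIPLIER",
    "AgreementStats",
    "bland_altman",
    "pearson",
    "one_sample_t",
    "bonferroni",
    "summarize_trials",
]

#: Normal quantile for 95% limits of agreement.
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between two measurement systems for one signal.

    ``bias`` is the mean of (a - b) differences in degrees; ``loa_low`` and
    ``loa_high`` satisfy bias -/+ 1.96 x sd_diff exactly.  ``r`` is NaN when
    the correlation is undefined (a constant coordinate).
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r: float
    t_stat: float
    p_value: float
    df: int
    significant: bool
    alpha: float

    def as_dict(self) -> dict:
        return asdict(self)


def bland_altman(pairs: np.ndarray | Sequence, alpha: float = 0.05 / 6
                 ) -> AgreementStats:
    """Agreement statistics for paired (markerless, reference) samples.

    Parameters
    ----------
    pairs
        (n, 2) array of matched samples (a, b); differences are d = a - b.
    alpha
        Significance threshold for the one-sample t-test of zero bias
        (default: Bonferroni-corrected 0.05/6 for three joints x two sides).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if arr.shape[0] < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    a, b = arr[:, 0], arr[:, 1]
    d = a - b
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    r = pearson(arr) if n >= 3 else float("nan")
    if sd > 0:
        t_stat, p_value, df = one_sample_t(d, 0.0)
    else:
        # zero spread: bias is exactly the constant difference
        t_stat = math.inf if bias != 0 else 0.0
        p_value = 0.0 if bias != 0 else 1.0
        df = n - 1
    return AgreementStats(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        r=r,
        t_stat=float(t_stat),
        p_value=float(p_value),
        df=int(df),
        significant=bool(p_value < alpha),
        alpha=alpha,
    )


def pearson(pairs: np.ndarray | Sequence) -> float:
    """Product-moment correlation of paired samples.

    Returns NaN (the flagged undefined value) when either coordinate has
    zero variance, rather than raising or fabricating a number.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    if arr.shape[0] < 3:
        raise ValueError("Pearson correlation requires at least 3 pairs")
    a, b = arr[:, 0], arr[:, 1]
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(sst.pearsonr(a, b).statistic)


def one_sample_t(values: np.ndarray | Sequence, mu0: float = 0.0
                 ) -> tuple[float, float, int]:
    """Two-tailed one-sample t-test of mean(values) against ``mu0``.

    Returns ``(t, p, df)`` with t = (mean - mu0) / (sd / sqrt(n)), df = n-1.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("t-test requires at least 2 values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("degenerate input: zero standard deviation")
    res = sst.ttest_1samp(x, popmean=mu0)
    return float(res.statistic), float(res.pvalue), int(res.df)


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold alpha / m."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def summarize_trials(records: Iterable[Mapping]) -> pd.DataFrame:
    """Aggregate per-trial similarity scores into a joint x side table.

    Each record needs ``joint``, ``side`` and either a ``similarity`` score
    or ``excluded=True`` with an ``exclusion_reason``.  Rows are emitted for
    every joint/side cell with data, plus pooled "both" rows per joint and an
    "all" block, with mean +/- SD of the similarity scores, pair-weighted by
    construction (pooled cells concatenate their member samples).  Empty
    cells are absent from the table, not reported as zero.
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no trial records to summarise")
    for col, default in (("excluded", False), ("exclusion_reason", "")):
        if col not in df:
            df[col] = default
        else:
            df[col] = df[col].map(lambda v: default if pd.isna(v) else v)
    if "similarity" not in df:
        raise ValueError("records carry no similarity scores")

    kept = df[~df["excluded"].astype(bool)]
    rows = []

    def cell(joint: str, side: str, sub: pd.DataFrame, n_excluded: int):
        if sub.empty:
            return
        vals = sub["similarity"].to_numpy(dtype=float)
        rows.append({
            "joint": joint,
            "side": side,
            "n": int(vals.size),
            "mean_similarity": float(np.mean(vals)),
            "sd_similarity": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
            "n_excluded": int(n_excluded),
        })

    joints = list(dict.fromkeys(df["joint"]))
    for joint in joints:
        jk = kept[kept["joint"] == joint]
        jx = df[(df["joint"] == joint) & df["excluded"].astype(bool)]
        for side in list(dict.fromkeys(df.loc[df["joint"] == joint, "side"])):
            cell(joint, side, jk[jk["side"] == side],
                 (jx["side"] == side).sum())
        cell(joint, "both", jk, len(jx))
    for side in list(dict.fromkeys(df["side"])):
        cell("all", side, kept[kept["side"] == side],
             (df["excluded"].astype(bool) & (df["side"] == side)).sum())
    cell("all", "both", kept, df["excluded"].astype(bool).sum())
    return pd.DataFrame(rows)
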