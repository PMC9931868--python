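"""Group statistics: Welch's t-test and Pearson correlation of tumor TACs.

Welch's unequal-variance t is the default two-sample test because the cohort
sizes differ (n = 3-6 per tracer/timepoint); no multiple-testing correction
is applied (each contrast is judged at alpha = 0.05 on its own).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class GroupComparison:
    """Two-sample comparison summary."""

    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    significant: bool

    def stars(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return "ns"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("label_a", "label_b", "mean_a", "mean_b", "sd_a", "sd_b",
                 "n_a", "n_b", "t", "df", "p", "significant")}


def welch_t(a, b, label_a: str = "a", label_b: str = "b",
            equal_var: bool = False) -> GroupComparison:
    """Welch's two-sided t-test (pooled Student's t when equal_var=True)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate: identical constants -> no evidence; different -> certain
        if a.mean() == b.mean():
            t, p, df = 0.0, 1.0, float(a.size + b.size - 2)
        else:
            t, p, df = np.inf if a.mean() > b.mean() else -np.inf, 0.0, \
                float(a.size + b.size - 2)
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return GroupComparison(
        label_a=label_a, label_b=label_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)), sd_b=float(np.sqrt(vb)),
        n_a=int(a.size), n_b=int(b.size),
        t=t, df=df, p=p, significant=bool(p <= ALPHA))


def pearson_matrix(curves) -> np.ndarray:
    """Pairwise Pearson r between equal-length TACs (diagonal = 1)."""
    vals = np.vstack([np.asarray(c.values, float) for c in curves])
    if np.any(vals.std(axis=1) == 0):
        raise ValueError("every curve needs non-zero variance")
    return np.corrcoef(vals)
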