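"""Cohort aggregation and paired significance testing.

Comparisons between two networks evaluated on the same cases use the
two-sided paired t-test on per-case differences, with the conventional
significance tiers: ``ns`` (p >= 0.05), ``*`` (p < 0.05), ``**``
(p < 0.01), ``***`` (p < 0.001).  No multiple-testing correction is
applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError

__all__ = ["PairedComparison", "paired_t_test", "significance_tier",
           "aggregate"]

_TIERS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_tier(p: float) -> str:
    for cut, tier in _TIERS:
        if p < cut:
            return tier
    return "ns"


@dataclass(frozen=True)
class PairedComparison:
    metric_name: str
    values_a: tuple
    values_b: tuple
    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    significance_tier: str

    def to_dict(self) -> dict:
        return {"metric": self.metric_name, "t": self.t_statistic,
                "df": self.degrees_of_freedom, "p": self.p_value,
                "tier": self.significance_tier}


def paired_t_test(a, b, metric_name: str = "") -> PairedComparison:
    """Two-sided paired t-test on per-case differences a_i - b_i."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("paired samples must be 1-D and of equal length")
    if len(a) < 2:
        raise ConfigError("need at least 2 paired observations")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise ConfigError("degenerate test: zero-variance differences")
    res = sps.ttest_rel(a, b)
    t, p = float(res.statistic), float(res.pvalue)
    return PairedComparison(metric_name, tuple(a), tuple(b), t, len(a) - 1,
                            p, significance_tier(p))


def aggregate(reports) -> pd.DataFrame:
    """Cohort mean and sample SD (n-1) per metric.

    Dice fractions are reported in percent, MHD in mm.  For a single case
    the SD is reported as 0 with ``sd_defined = False``.
    """
    reports = list(reports)
    if not reports:
        raise ConfigError("no reports to aggregate")
    df = pd.DataFrame([r.to_dict() for r in reports])
    for col in ("dsc_whole", "dsc_boundary_1px", "dsc_boundary_2px"):
        df[col] *= 100.0
    n = len(df)
    out = pd.DataFrame({
        "mean": df.mean(),
        "sd": df.std(ddof=1) if n > 1 else 0.0 * df.mean(),
    })
    out["n"] = n
    out["sd_defined"] = n > 1
    out.index.name = "metric"
    return out
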