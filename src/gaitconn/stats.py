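"""One-way ANOVA across task conditions with Tukey HSD post hoc tests.

Per metric and gait phase (or time window), the per-epoch metric values of
the three conditions are compared by a classic one-way analysis of
variance; pairwise differences are then probed with Tukey's honestly
significant difference test.  P-values are reported per comparison and
are NOT corrected across metrics or phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats


@dataclass
class GroupSamples:
    """Per-condition metric samples for one (metric, phase/window) cell."""

    groups: dict[str, np.ndarray]
    metric: str = ""
    phase: str = ""

    def __post_init__(self) -> None:
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        for name, vals in self.groups.items():
            if vals.ndim != 1 or len(vals) < 2:
                raise ValueError(f"group {name!r} needs at least 2 observations")


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    metric: str = ""
    phase: str = ""


def anova_oneway(samples: GroupSamples) -> AnovaResult:
    """Classic between/within mean-square ratio, p from the F distribution.

    Degenerate input (zero within-group variance with equal means) yields
    F = 0 with a warning rather than NaN.
    """
    arrays = list(samples.groups.values())
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    if n_total <= k:
        raise ValueError("total sample size must exceed the number of groups")
    df_b, df_w = k - 1, n_total - k
    grand = np.concatenate(arrays).mean()
    ss_b = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_w == 0 and ss_b == 0:
        warnings.warn("all observations identical; F defined as 0")
        return AnovaResult(0.0, df_b, df_w, 1.0, samples.metric, samples.phase)
    F, p = sstats.f_oneway(*arrays)
    return AnovaResult(float(F), df_b, df_w, float(p), samples.metric, samples.phase)


def posthoc_pairwise(samples: GroupSamples) -> pd.DataFrame:
    """Tukey HSD p-values for every group pair (3 rows for 3 groups)."""
    names = list(samples.groups.keys())
    if len(names) < 3:
        raise ValueError("post hoc comparisons need at least 3 groups")
    res = sstats.tukey_hsd(*samples.groups.values())
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            rows.append(
                {
                    "metric": samples.metric,
                    "phase": samples.phase,
                    "group_a": names[a],
                    "group_b": names[b],
                    "p": float(res.pvalue[a, b]),
                }
            )
    return pd.DataFrame(rows)


def metric_anova_table(per_epoch: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """ANOVA + post hoc per (metric, phase) cell.

    ``per_epoch[metric][phase]`` maps condition → per-epoch values; the
    output mirrors the figures' significance reporting, with a star at
    P < 0.05 and a reminder that p-values are uncorrected.
    """
    rows = []
    for metric, by_phase in per_epoch.items():
        for phase, groups in by_phase.items():
            gs = GroupSamples(groups, metric=metric, phase=phase)
            res = anova_oneway(gs)
            row = {
                "metric": metric,
                "phase": phase,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
                "significant": "*" if res.p < 0.05 else "",
                "corrected": "none",
            }
            if len(groups) >= 3:
                ph = posthoc_pairwise(gs)
                for _, r in ph.iterrows():
                    row[f"p_{r['group_a']}_{r['group_b']}"] = r["p"]
            rows.append(row)
    return pd.DataFrame(rows)
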