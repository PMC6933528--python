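"""Statistical layer for perturbation sweeps.

One-way ANOVA across weight conditions per metric, followed by Tukey HSD
post-hoc comparisons of every condition against the control, with
significance flagged at p < 0.05.  The Tukey step uses the Tukey-Kramer
standard error, so unbalanced groups (e.g. replicates lost to integration
failures) are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "TukeyComparison", "one_way_anova", "tukey_hsd", "stats_frame"]

ALPHA = 0.05


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class TukeyComparison:
    group: str
    control: str
    mean_difference: float  # group mean - control mean
    p_adjusted: float
    significant: bool


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for label, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1 or len(arr) < 2:
            raise ValueError(f"group {label!r} must hold at least 2 values")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"group {label!r} contains non-finite values")
        out[str(label)] = arr
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within with df (k-1, N-k).

    Degenerate input (zero variance everywhere) is flagged with an error
    rather than returning 0/0.
    """
    data = _validate_groups(groups)
    arrays = list(data.values())
    n_total = sum(len(a) for a in arrays)
    k = len(arrays)
    grand = np.concatenate(arrays)
    if np.ptp(grand) == 0.0:
        raise ValueError("all values identical: ANOVA is undefined (zero total variance)")
    ssw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    if ssw == 0.0:
        raise ValueError("zero within-group variance in every group: F is unbounded")
    F, p = sps.f_oneway(*arrays)
    return AnovaResult(
        F=float(F),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p),
        group_means={lbl: float(a.mean()) for lbl, a in data.items()},
        group_sems={lbl: float(sps.sem(a)) for lbl, a in data.items()},
        group_ns={lbl: len(a) for lbl, a in data.items()},
    )


def tukey_hsd(
    groups: Mapping[str, Sequence[float]],
    control_label: str,
    alpha: float = ALPHA,
) -> list[TukeyComparison]:
    """Tukey (Tukey-Kramer for unbalanced groups) comparisons vs the control.

    The adjusted p-value for a pair is the survival function of the
    studentized range distribution with k groups and N-k error df at

        q = |mean_i - mean_c| / sqrt(MSW/2 * (1/n_i + 1/n_c)).
    """
    data = _validate_groups(groups)
    if control_label not in data:
        raise KeyError(f"control label {control_label!r} not among groups")
    arrays = list(data.values())
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    df_within = n_total - k
    msw = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays) / df_within
    control = data[control_label]
    out = []
    for label, a in data.items():
        if label == control_label:
            continue
        diff = float(a.mean() - control.mean())
        if msw == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / len(a) + 1.0 / len(control)))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_within))
        p_adj = min(1.0, max(0.0, p_adj))
        out.append(
            TukeyComparison(
                group=label,
                control=control_label,
                mean_difference=diff,
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return out


def stats_frame(
    metric: str,
    anova: AnovaResult,
    comparisons: list[TukeyComparison],
) -> pd.DataFrame:
    """CSV-ready summary: the omnibus row followed by per-comparison rows.

    ``significant`` is False ("NS") when the comparison does not reach the
    alpha = 0.05 criterion.
    """
    rows = [
        {
            "metric": metric,
            "comparison": "omnibus",
            "estimate": np.nan,
            "F": anova.F,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "p": anova.p_value,
            "significant": anova.significant,
        }
    ]
    for c in comparisons:
        rows.append(
            {
                "metric": metric,
                "comparison": f"{c.group} vs {c.control}",
                "estimate": c.mean_difference,
                "F": np.nan,
                "df_between": np.nan,
                "df_within": np.nan,
                "p": c.p_adjusted,
                "significant": c.significant,
            }
        )
    return pd.DataFrame(rows)
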