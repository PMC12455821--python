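"""Group comparison of isoform proportions with BH false-discovery control.

For a two-group sample design, each retained isoform's per-sample
within-gene proportions are compared with a two-sided Welch (unequal
variance) t-test; p-values are Benjamini-Hochberg adjusted across the
isoforms of the gene and called significant at q <= 0.05. Welch is used
rather than the pooled-variance test because group sizes and variances are
rarely balanced across conditions; proportions are tested untransformed by
default, with an optional logit transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupTestResult:
    isoform_id: str
    group_means: dict[str, float]
    t_stat: float | None
    p_value: float | None
    q_value: float | None
    significant: bool
    testable: bool = True


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Welch t statistic and p-value.

    Both groups constant and equal -> (0, 1) by convention. Fewer than two
    observations in either group raises (the caller flags untestable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return math.inf if np.mean(x) > np.mean(y) else -math.inf, 0.0
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return [float(v) for v in q]


def group_proportion_test(
    proportions: pd.DataFrame,
    group_map: Mapping[str, str],
    alpha: float = 0.05,
    logit: bool = False,
) -> list[GroupTestResult]:
    """Welch test per isoform on per-sample proportions, BH across isoforms.

    ``proportions`` is isoform x sample; ``group_map`` maps every sample to
    one of exactly two groups. Isoforms that cannot be tested (too few
    samples, or zero variance with equal means handled by convention) are
    reported with testable=False and excluded from the BH family.
    """
    missing = [s for s in proportions.columns if s not in group_map]
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")
    groups = sorted(set(group_map[s] for s in proportions.columns))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    ga = [s for s in proportions.columns if group_map[s] == groups[0]]
    gb = [s for s in proportions.columns if group_map[s] == groups[1]]

    vals = proportions if not logit else np.log(
        proportions.clip(lower=1e-9, upper=1 - 1e-9)
        / (1 - proportions.clip(lower=1e-9, upper=1 - 1e-9))
    )
    results: list[GroupTestResult] = []
    for iso in proportions.index:
        means = {
            groups[0]: float(proportions.loc[iso, ga].mean()),
            groups[1]: float(proportions.loc[iso, gb].mean()),
        }
        try:
            t, p = welch_t(vals.loc[iso, ga], vals.loc[iso, gb])
            results.append(GroupTestResult(iso, means, t, p, None, False, True))
        except ValueError:
            results.append(GroupTestResult(iso, means, None, None, None, False, False))
    testable = [r for r in results if r.testable]
    qs = bh_adjust([r.p_value for r in testable])
    for r, q in zip(testable, qs):
        r.q_value = q
        r.significant = q <= alpha
    return results


def results_frame(results: Sequence[GroupTestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"isoform_id": r.isoform_id, "t": r.t_stat, "p": r.p_value,
               "q": r.q_value, "significant": r.significant, "testable": r.testable}
        for g, m in r.group_means.items():
            row[f"mean_{g}"] = m
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "GroupTestResult",
    "bh_adjust",
    "group_proportion_test",
    "results_frame",
    "welch_t",
]
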