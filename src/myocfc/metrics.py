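"""Per-colony CFC metrics and group-level statistics.

From the calibrated nuclei and the MHC+ regions of one colony image:

    total nuclei      N   = sum of all nuclear quantities
    stain-negative    S   = quantities of nuclei outside any MHC+ cytoplasm
    coefficient of differentiation
                      D_f = 1 - S / N
    fusion index      U_i = (sum of nuclei within MHC+ cells of > 2 nuclei) / N

Both are frequencies on [0, 1]; D_f measures differentiation (nuclei within
MHC+ cytoplasm) and U_i terminal differentiation (nuclei that have gone
through a definitive fusion event). U_i sums the unrounded quantities of
MULTI-classified regions, so U_i <= D_f always holds.

Group summaries report the mean with a two-sided 95% Student-t confidence
interval; unpaired two-group comparisons use Welch's t-test.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import List, Sequence

import numpy as np
from scipy import stats

from .calibration import NucleusRecord
from .mhc_mapping import FiberClass, MhcRegion

logger = logging.getLogger("myocfc")


class MetricName(Enum):
    TOTAL = "total_nuclei"
    DF = "df"
    UI = "ui"


@dataclass(frozen=True)
class ColonyMetrics:
    """Proliferation and differentiation metrics for one colony image."""

    image_id: str
    total_nuclei: float
    stain_negative_nuclei: float
    mhc_positive_nuclei: float
    df: float
    ui: float
    mono_count: int
    bi_count: int
    multi_count: int
    anucleate_count: int


@dataclass(frozen=True)
class GroupSummary:
    metric: MetricName
    n: int
    mean: float
    ci_lower: float
    ci_upper: float
    values: tuple


@dataclass(frozen=True)
class GroupComparison:
    metric: MetricName
    mean_difference: float  # mean(a) - mean(b)
    ci_lower: float
    ci_upper: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def compute_colony_metrics(
    nuclei: Sequence[NucleusRecord],
    mhc: Sequence[MhcRegion],
    image_id: str,
) -> ColonyMetrics:
    """Evaluate one colony after nucleus-to-MHC assignment.

    A zero-nucleus image gets D_f = U_i = 0 with a logged warning, so batch
    CSVs stay rectangular.
    """
    total = float(sum(n.nuclear_quantity for n in nuclei))
    stain_negative = float(
        sum(n.nuclear_quantity for n in nuclei if n.assigned_mhc_label is None)
    )
    mhc_positive = total - stain_negative
    multi_sum = float(
        sum(r.nuclei_total for r in mhc if r.fiber_class is FiberClass.MULTI)
    )
    if total > 0:
        df = 1.0 - stain_negative / total
        # ui <= df holds mathematically (MULTI regions hold a subset of the
        # MHC+ quantities); min() guards the one-ulp summation-order case
        ui = min(multi_sum / total, df)
    else:
        logger.warning("%s: no nuclei detected; D_f and U_i set to 0", image_id)
        df = 0.0
        ui = 0.0
    counts = {cls: 0 for cls in FiberClass}
    for region in mhc:
        counts[region.fiber_class] += 1
    return ColonyMetrics(
        image_id=image_id,
        total_nuclei=total,
        stain_negative_nuclei=stain_negative,
        mhc_positive_nuclei=mhc_positive,
        df=df,
        ui=ui,
        mono_count=counts[FiberClass.MONO],
        bi_count=counts[FiberClass.BI],
        multi_count=counts[FiberClass.MULTI],
        anucleate_count=counts[FiberClass.ANUCLEATE],
    )


def _metric_values(colonies: Sequence[ColonyMetrics], metric: MetricName) -> np.ndarray:
    attr = {"total_nuclei": "total_nuclei", "df": "df", "ui": "ui"}[metric.value]
    return np.asarray([getattr(c, attr) for c in colonies], dtype=np.float64)


def summarize_group(
    colonies: Sequence[ColonyMetrics], metric: MetricName
) -> GroupSummary:
    """Mean and two-sided 95% Student-t CI (n-1 degrees of freedom)."""
    if len(colonies) == 0:
        raise ValueError("cannot summarize an empty group")
    values = _metric_values(colonies, metric)
    n = len(values)
    mean = float(values.mean())
    if n == 1:
        logger.warning("group of size 1: confidence interval degenerate at the mean")
        return GroupSummary(metric, n, mean, mean, mean, tuple(values))
    sd = float(values.std(ddof=1))
    halfwidth = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return GroupSummary(
        metric, n, mean, mean - halfwidth, mean + halfwidth, tuple(values)
    )


def compare_groups(
    a: Sequence[ColonyMetrics],
    b: Sequence[ColonyMetrics],
    metric: MetricName,
) -> GroupComparison:
    """Welch two-sample t-test on a per-colony metric (unpaired, two-sided).

    Reports the difference of means (a - b) with its 95% CI on Welch's
    degrees of freedom.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 colonies for a comparison")
    xa = _metric_values(a, metric)
    xb = _metric_values(b, metric)
    na, nb = len(xa), len(xb)
    diff = float(xa.mean() - xb.mean())
    va = float(xa.var(ddof=1))
    vb = float(xb.var(ddof=1))
    se2 = va / na + vb / nb
    if se2 == 0.0:
        # zero variance in both groups: identical-constant groups compare
        # as no difference (p = 1) or a certain difference (p = 0)
        t_stat = 0.0 if diff == 0.0 else math.inf * math.copysign(1.0, diff)
        dof = float(na + nb - 2)
        p = 1.0 if diff == 0.0 else 0.0
        return GroupComparison(metric, diff, diff, diff, t_stat, dof, p)
    se = math.sqrt(se2)
    t_stat = diff / se
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * stats.t.sf(abs(t_stat), dof))
    halfwidth = float(stats.t.ppf(0.975, dof)) * se
    return GroupComparison(
        metric, diff, diff - halfwidth, diff + halfwidth, float(t_stat), float(dof), p
    )


def write_group_summary_csv(
    path,
    summaries: Sequence[tuple[str, GroupSummary]],
) -> None:
    """Write group summaries as CSV: metric, group, n, mean, ci_lower, ci_upper."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "group", "n", "mean", "ci_lower", "ci_upper"])
        for group_name, summary in summaries:
            writer.writerow(
                [
                    summary.metric.value,
                    group_name,
                    summary.n,
                    repr(float(summary.mean)),
                    repr(float(summary.ci_lower)),
                    repr(float(summary.ci_upper)),
                ]
            )
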