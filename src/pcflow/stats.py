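"""Cohort validation statistics: phantom accuracy gate, per-system
interpolation-order selection, and the summary statistics (mean +/- SD, RMS,
paired t-test, F-test).

Mean values indicate systematic offsets in a group of studies; RMS values
better reflect the offset magnitude in an individual study.  Aggregates are
computed only over studies that passed the phantom measurement accuracy
check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import CorrectionConfig, InvariantError, StudyRecord
from .flow import roi_mean_velocity

__all__ = [
    "AccuracyCheckResult",
    "OrderSelection",
    "GroupStats",
    "PairedTests",
    "CohortResult",
    "phantom_accuracy_check",
    "select_interpolation_order",
    "group_stats",
    "cohort_summary",
]


@dataclass
class AccuracyCheckResult:
    """Outcome of the phantom measurement accuracy check.

    ``wall_diff`` is the in-vivo minus phantom thorax-wall ROI mean
    velocity, each averaged over all of its own cardiac phases, in the
    flow-positive sign convention.  The study passes iff
    ``|wall_diff| <= threshold`` (inclusive).
    """

    wall_diff: float
    passed: bool
    threshold: float


@dataclass
class OrderSelection:
    """Interpolation order chosen for one system."""

    order: int
    rms_by_order: dict[int, float]
    meets_target: bool


@dataclass
class GroupStats:
    """mean, SD (n-1 denominator) and RMS of one quantity over a group."""

    n: int
    mean: float
    sd: float
    rms: float


@dataclass
class PairedTests:
    """Paired t-tests (signed and absolute pairing) and the two-sided
    variance-ratio F-test between pre- and post-correction offsets.

    Degenerate inputs (zero variance of differences, or < 2 pairs) leave
    the corresponding statistic as NaN — undefined, never fabricated.
    """

    t_signed: float = math.nan
    p_signed: float = math.nan
    t_abs: float = math.nan
    p_abs: float = math.nan
    f_stat: float = math.nan
    p_f: float = math.nan


@dataclass
class CohortResult:
    per_study: pd.DataFrame
    per_system: dict[str, dict] = field(default_factory=dict)
    selected_order: dict[str, OrderSelection] = field(default_factory=dict)
    overall: dict[str, GroupStats] = field(default_factory=dict)
    tests: PairedTests = field(default_factory=PairedTests)
    co_tests: PairedTests = field(default_factory=PairedTests)


def phantom_accuracy_check(
    study: StudyRecord, config: CorrectionConfig
) -> AccuracyCheckResult:
    """Compare the thorax-wall ROI mean velocity between the in-vivo and the
    phantom acquisition; disagreement flags phantom offset instability.

    Raises
    ------
    KeyError
        If the study has no thorax-wall ROI.
    """
    wall = study.roi("thorax_wall")
    sign = study.in_vivo.flow_sign
    v_vivo = sign * roi_mean_velocity(study.in_vivo, wall, "time-averaged")
    v_phantom = sign * roi_mean_velocity(study.phantom, wall, "time-averaged")
    diff = v_vivo - v_phantom
    return AccuracyCheckResult(
        wall_diff=float(diff),
        passed=bool(abs(diff) <= config.gate_threshold),
        threshold=config.gate_threshold,
    )


def select_interpolation_order(
    v_post_by_order: dict[int, np.ndarray],
    config: CorrectionConfig,
) -> OrderSelection:
    """Choose the interpolation order for one system.

    The lowest order whose per-system RMS residual offset is below the
    performance target (``gate_threshold``) wins, because higher orders are
    more sensitive to artifacts and noise.  If no order meets the target,
    the RMS-minimizing order is returned flagged ``meets_target=False``.

    Raises
    ------
    InvariantError
        If any order has no passed studies.
    """
    rms_by_order: dict[int, float] = {}
    for order in sorted(v_post_by_order):
        values = np.asarray(v_post_by_order[order], dtype=float)
        if values.size == 0:
            raise InvariantError(f"no passed studies available for order {order}")
        rms_by_order[order] = float(np.sqrt(np.mean(values**2)))
    for order, rms in rms_by_order.items():
        if rms < config.gate_threshold:
            return OrderSelection(order=order, rms_by_order=rms_by_order, meets_target=True)
    best = min(rms_by_order, key=lambda o: (rms_by_order[o], o))
    return OrderSelection(order=best, rms_by_order=rms_by_order, meets_target=False)


def group_stats(values: np.ndarray) -> GroupStats:
    """mean, sample SD and RMS; satisfies rms^2 = mean^2 + (n-1)/n * sd^2."""
    values = np.asarray(values, dtype=float)
    n = values.size
    mean = float(values.mean()) if n else math.nan
    sd = float(values.std(ddof=1)) if n > 1 else math.nan
    rms = float(np.sqrt(np.mean(values**2))) if n else math.nan
    return GroupStats(n=n, mean=mean, sd=sd, rms=rms)


def _paired_tests(pre: np.ndarray, post: np.ndarray) -> PairedTests:
    out = PairedTests()
    if pre.size < 2:
        return out
    d_signed = pre - post
    if np.std(d_signed, ddof=1) > 0:
        t = sps.ttest_rel(pre, post)
        out.t_signed, out.p_signed = float(t.statistic), float(t.pvalue)
    d_abs = np.abs(pre) - np.abs(post)
    if np.std(d_abs, ddof=1) > 0:
        t = sps.ttest_rel(np.abs(pre), np.abs(post))
        out.t_abs, out.p_abs = float(t.statistic), float(t.pvalue)
    var_pre = float(np.var(pre, ddof=1))
    var_post = float(np.var(post, ddof=1))
    if var_pre > 0 and var_post > 0:
        f = var_pre / var_post
        dof = pre.size - 1
        p_one = sps.f.sf(f, dof, dof) if f >= 1 else sps.f.cdf(f, dof, dof)
        out.f_stat, out.p_f = float(f), float(min(1.0, 2.0 * p_one))
    return out


def cohort_summary(per_study: pd.DataFrame, config: CorrectionConfig) -> CohortResult:
    """Summarize a cohort of assessed studies.

    Parameters
    ----------
    per_study : DataFrame
        One row per study with columns ``subject_id``, ``system_id``,
        ``vessel``, ``passed``, ``wall_diff``, ``v_pre``, ``v_post@k`` and
        ``co_error_post@k`` for each fitted order k, and ``co_error_pre``.

    Returns
    -------
    CohortResult with per-system order selection, per-system and overall
    mean/SD/RMS of the offsets and CO errors at the selected order, and the
    paired t / F tests on the passed studies.

    Raises
    ------
    InvariantError
        If fewer than 2 studies passed the accuracy check overall.
    """
    orders = sorted(
        int(c.split("@")[1]) for c in per_study.columns if c.startswith("v_post@")
    )
    if not orders:
        raise InvariantError("per-study table has no v_post@<order> columns")
    passed = per_study[per_study["passed"]]
    if len(passed) < 2:
        raise InvariantError(f"need >= 2 passed studies, got {len(passed)}")

    result = CohortResult(per_study=per_study.copy())

    selected_col = np.empty(len(per_study), dtype=float)
    selected_col[:] = np.nan
    co_selected_col = selected_col.copy()
    order_col = np.zeros(len(per_study), dtype=int)

    for system_id, group in passed.groupby("system_id"):
        sel = select_interpolation_order(
            {k: group[f"v_post@{k}"].to_numpy() for k in orders}, config
        )
        result.selected_order[str(system_id)] = sel
        idx = per_study["system_id"] == system_id
        selected_col[idx.to_numpy()] = per_study.loc[idx, f"v_post@{sel.order}"]
        co_selected_col[idx.to_numpy()] = per_study.loc[idx, f"co_error_post@{sel.order}"]
        order_col[idx.to_numpy()] = sel.order

        g = group
        result.per_system[str(system_id)] = {
            "n": len(g),
            "selected_order": sel.order,
            "meets_target": sel.meets_target,
            "rms_by_order": sel.rms_by_order,
            "v_pre": group_stats(g["v_pre"].to_numpy()),
            "v_post": group_stats(g[f"v_post@{sel.order}"].to_numpy()),
            "co_error_pre": group_stats(g["co_error_pre"].to_numpy()),
            "co_error_post": group_stats(g[f"co_error_post@{sel.order}"].to_numpy()),
        }

    result.per_study["v_post_selected"] = selected_col
    result.per_study["co_error_post_selected"] = co_selected_col
    result.per_study["selected_order"] = order_col

    passed_sel = result.per_study[result.per_study["passed"]]
    v_pre = passed_sel["v_pre"].to_numpy(dtype=float)
    v_post = passed_sel["v_post_selected"].to_numpy(dtype=float)
    co_pre = passed_sel["co_error_pre"].to_numpy(dtype=float)
    co_post = passed_sel["co_error_post_selected"].to_numpy(dtype=float)

    result.overall = {
        "v_pre": group_stats(v_pre),
        "v_post": group_stats(v_post),
        "co_error_pre": group_stats(co_pre),
        "co_error_post": group_stats(co_post),
    }
    result.tests = _paired_tests(v_pre, v_post)
    result.co_tests = _paired_tests(co_pre, co_post)
    return result
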