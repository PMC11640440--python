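"""Paired pre/post deviation computation and cohort-level trend evaluation.

Conventions
-----------
* Differences are ``post - pre``, so decreases are negative.
* The relative difference is ``100 * (post - pre) / pre`` in percent, with
  the zero rule: if either value is exactly zero the relative difference is
  set to exactly 0 (features absent in one condition never reach this stage;
  they are excluded during pairing).
* Cohort trends are summarized per feature by macro-averaging per-patient
  relative differences (each patient weighted equally) and by a two-sided
  dependent t-test on the raw pre/post feature scores.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

PAIRED_COLUMNS = ("patient_id", "structure", "metric", "pre", "post")
DEVIATION_COLUMNS = ("patient_id", "structure", "metric", "pre", "post", "abs_diff", "rel_diff_pct", "flags")
EVALUATION_COLUMNS = ("structure", "metric", "n", "mean_rel_diff_pct", "t", "df", "p", "significance", "flags")

SIG_HIGH = "p<0.01"
SIG_LOW = "p<0.05"
SIG_NONE = "ns"

FLAG_ZERO_RULE = "zero_rule"
FLAG_INSUFFICIENT_N = "insufficient_n"
FLAG_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class TTestResult:
    """Dependent paired t-test outcome with edge-case flagging."""

    t: float
    df: int
    p: float
    flag: str = ""


def pair_features(pre_table: pd.DataFrame, post_table: pd.DataFrame) -> pd.DataFrame:
    """Inner-join one patient's pre and post feature tables on (structure, metric).

    Features present in only one condition are dropped (and logged): only
    pairwise-existing features enter the deviation analysis.
    """
    pre_ids = set(pre_table["patient_id"].unique())
    post_ids = set(post_table["patient_id"].unique())
    if len(pre_ids) > 1 or len(post_ids) > 1:
        raise InputError(f"pair_features expects single-patient tables, got {pre_ids} vs {post_ids}")
    if pre_ids and post_ids and pre_ids != post_ids:
        raise InputError(f"patient id mismatch between conditions: {pre_ids} vs {post_ids}")

    key = ["structure", "metric"]
    merged = pre_table.merge(post_table, on=key, how="outer", suffixes=("_pre", "_post"), indicator=True)
    dropped = merged[merged["_merge"] != "both"]
    if len(dropped):
        pid = (pre_ids | post_ids or {"?"}).pop()
        for _, row in dropped.iterrows():
            side = "post" if row["_merge"] == "left_only" else "pre"
            logger.info(
                "patient %s: feature %s/%s missing in %s condition; excluded from pairing",
                pid, row["structure"], row["metric"], side,
            )
    paired = merged[merged["_merge"] == "both"]
    out = pd.DataFrame(
        {
            "patient_id": paired["patient_id_pre"].values,
            "structure": paired["structure"].values,
            "metric": paired["metric"].values,
            "pre": paired["value_pre"].astype(float).values,
            "post": paired["value_post"].astype(float).values,
        }
    )
    return out.sort_values(["structure", "metric"], kind="stable").reset_index(drop=True)


def absolute_difference(pre_value: float, post_value: float) -> float:
    """Signed change ``post - pre`` in the feature's own units."""
    return post_value - pre_value


def relative_difference_pct(pre_value: float, post_value: float) -> float:
    """Percent change from the pre-condition baseline, with the zero rule.

    Returns exactly 0.0 whenever either value is zero.
    """
    if pre_value == 0 or post_value == 0:
        return 0.0
    return 100.0 * (post_value - pre_value) / pre_value


def compute_deviations(paired: pd.DataFrame) -> pd.DataFrame:
    """Per-feature absolute and relative deviations for one patient's pairs."""
    rows = []
    for row in paired.itertuples(index=False):
        zero = row.pre == 0 or row.post == 0
        rows.append(
            (
                row.patient_id,
                row.structure,
                row.metric,
                row.pre,
                row.post,
                absolute_difference(row.pre, row.post),
                relative_difference_pct(row.pre, row.post),
                FLAG_ZERO_RULE if zero else "",
            )
        )
    return pd.DataFrame.from_records(rows, columns=DEVIATION_COLUMNS)


def macro_average(values: Iterable[float]) -> float:
    """Arithmetic mean over per-patient relative differences (equal weights)."""
    arr = np.asarray([v for v in values if math.isfinite(v)], dtype=float)
    if arr.size == 0:
        raise InputError("macro_average of an empty value list")
    return float(arr.mean())


def paired_t_test(pre_vec: Sequence[float], post_vec: Sequence[float]) -> TTestResult:
    """Classical dependent-samples t-test on differences ``post - pre``.

    t = mean(d) * sqrt(n) / sd(d) with the sample standard deviation
    (n - 1 denominator); two-sided p from the t distribution with n - 1
    degrees of freedom.

    Edge cases: n < 2 gives (t=0, p=1) flagged ``insufficient_n``;
    zero-variance differences give p=0 (flagged ``degenerate``) when the mean
    difference is nonzero, and (t=0, p=1) when it is zero.
    """
    pre = np.asarray(pre_vec, dtype=float)
    post = np.asarray(post_vec, dtype=float)
    if pre.shape != post.shape:
        raise InputError(f"paired vectors differ in length: {pre.shape} vs {post.shape}")
    n = pre.size
    if n < 2:
        return TTestResult(t=0.0, df=max(n - 1, 0), p=1.0, flag=FLAG_INSUFFICIENT_N)
    d = post - pre
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.copysign(math.inf, mean), df=df, p=0.0, flag=FLAG_DEGENERATE)
    t = mean * math.sqrt(n) / sd
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, flag="")


def significance_class(p: float) -> str:
    if p < 0.01:
        return SIG_HIGH
    if p < 0.05:
        return SIG_LOW
    return SIG_NONE


def evaluate_cohort(deviations: pd.DataFrame, bonferroni: bool = False) -> pd.DataFrame:
    """Cohort-level evaluation: one row per feature observed in >= 1 patient.

    Macro-averages the relative differences across patients and runs the
    paired t-test on the raw pre/post scores of the patients contributing
    that feature (pairwise-complete analysis).  Significance is classed at
    the 0.05 and 0.01 thresholds; the optional Bonferroni column is
    ``min(1, p * m)`` with m the number of evaluated features.
    """
    if deviations.empty:
        cols = list(EVALUATION_COLUMNS) + (["p_bonferroni"] if bonferroni else [])
        return pd.DataFrame(columns=cols)
    rows = []
    for (structure, metric), grp in deviations.groupby(["structure", "metric"], sort=True):
        rel = grp["rel_diff_pct"].to_numpy(dtype=float)
        rel = rel[np.isfinite(rel)]
        if rel.size == 0:
            logger.info("feature %s/%s: no usable relative differences; skipped", structure, metric)
            continue
        res = paired_t_test(grp["pre"].to_numpy(), grp["post"].to_numpy())
        rows.append(
            (
                structure,
                metric,
                int(len(grp)),
                macro_average(rel),
                res.t,
                res.df,
                res.p,
                significance_class(res.p),
                res.flag,
            )
        )
    table = pd.DataFrame.from_records(rows, columns=EVALUATION_COLUMNS)
    if bonferroni:
        m = len(table)
        table["p_bonferroni"] = np.minimum(1.0, table["p"] * m)
    return table


def write_deviation_csv(deviations: pd.DataFrame, path: os.PathLike | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    deviations.to_csv(path, index=False, float_format="%.6g")


def write_evaluation_csv(evaluation: pd.DataFrame, path: os.PathLike | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    evaluation.to_csv(path, index=False, float_format="%.6g")
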