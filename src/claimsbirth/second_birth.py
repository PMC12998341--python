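"""Washout-window scan for identifying a second childbirth.

Childbirth diagnosis codes recur around a single delivery (prenatal visits
before it, postpartum checks after), so naively looking for a second burst
of codes misreads one birth as two. The remedy is a washout: after the
first birth, ignore all claims for ``k`` months and only then start looking
for the next event. This module scans ``k`` over 2..24 months — bracketing
the typical two-year inter-birth interval — and reports the full metric set
per ``k``, selecting the ``k`` with the highest Youden index (ties broken
toward the smaller washout).

Population and reference: eligible women with at least one linkage birth in
the window. A woman is second-birth positive when she has two or more
qualifying linkage births; by default the reference month is her *second*
birth and the anchor is her *first* (earliest) linkage birth. The detected
second event is dated to the earliest qualifying claim month at or after
``first + k`` — the next distinct event after the washout — and matched
with the same one-month discharge tolerance as the first-birth validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .algorithms import AlgorithmSpec, Condition, _COND_COLS, _eval_vector, annotate_conditions
from .codesets import CodeSets
from .gold import GoldStandard
from .metrics import ConfusionTable, MetricSet, compute_metrics

__all__ = [
    "WashoutResult",
    "WashoutScan",
    "second_birth_gold",
    "detect_second",
    "scan_washout",
]


@dataclass(frozen=True)
class WashoutResult:
    k: int
    table: ConfusionTable
    metrics: MetricSet


@dataclass(frozen=True)
class WashoutScan:
    results: tuple[WashoutResult, ...]
    best_k: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "k": r.k,
                    "tp": r.table.tp,
                    "tn": r.table.tn,
                    "fn": r.table.fn,
                    "fp": r.table.fp,
                    "sensitivity": r.metrics.sensitivity,
                    "specificity": r.metrics.specificity,
                    "ppv": r.metrics.ppv,
                    "npv": r.metrics.npv,
                    "kappa": r.metrics.kappa,
                    "youden": r.metrics.youden,
                    "best": r.k == self.best_k,
                }
            )
        return pd.DataFrame(rows)


def second_birth_gold(
    gold: GoldStandard, reference: str = "second"
) -> pd.DataFrame:
    """Second-birth reference for women with at least one linkage birth.

    Returns a frame indexed by woman_id with ``first_month_idx``,
    ``second_positive`` and ``second_month_idx`` (NaN for single-birth
    women). ``reference`` picks the matched birth for multi-birth women:
    ``'second'`` (default) the second-earliest, ``'latest'`` the most
    recent.
    """
    if reference not in ("second", "latest"):
        raise ValueError(f"unknown reference {reference!r}")
    rows = []
    for wid, months in gold.birth_months.items():
        second = np.nan
        if len(months) >= 2:
            second = months[1] if reference == "second" else months[-1]
        rows.append((wid, months[0], len(months) >= 2, float(second)))
    df = pd.DataFrame(
        rows, columns=["woman_id", "first_month_idx", "second_positive", "second_month_idx"]
    ).set_index("woman_id")
    return df


def _earliest_events(
    claims: pd.DataFrame,
    women: pd.Index,
    first_month: pd.Series,
    spec: AlgorithmSpec,
    cs: CodeSets,
    k: int,
    window: tuple[int, int],
) -> pd.Series:
    """Earliest qualifying event month >= first + k per woman (NaN if none)."""
    cl = claims[claims["woman_id"].isin(women)]
    start, end = window
    cl = cl[(cl["month_idx"] >= start) & (cl["month_idx"] < end)]
    cutoff = first_month.reindex(cl["woman_id"]).to_numpy() + k
    cl = cl[cl["month_idx"].to_numpy() >= cutoff]
    ann = annotate_conditions(cl, cs)

    has: dict[Condition, np.ndarray] = {}
    min_month: dict[Condition, np.ndarray] = {}
    for c in Condition:
        sub = ann[ann[_COND_COLS[c]]]
        agg = sub.groupby("woman_id")["month_idx"].min().reindex(women)
        min_month[c] = agg.to_numpy(dtype=float)
        has[c] = ~np.isnan(min_month[c])

    sat = _eval_vector(spec.expression, has)
    refs = sorted(spec.expression.conditions(), key=lambda c: c.value)
    stacked = np.vstack([min_month[c] for c in refs])
    event = np.min(np.nan_to_num(stacked, nan=np.inf), axis=0)
    event[~sat | ~np.isfinite(event)] = np.nan
    return pd.Series(event, index=women)


def detect_second(
    claims: pd.DataFrame,
    spec: AlgorithmSpec,
    cs: CodeSets,
    first_month: pd.Series,
    k: int,
    window: tuple[int, int],
) -> pd.Series:
    """Detected second-birth month per woman with washout ``k`` (NaN = none)."""
    if not 1 <= k:
        raise ValueError("washout k must be positive")
    return _earliest_events(
        claims, first_month.index, first_month, spec, cs, k, window
    )


def _confusion_second(
    second: pd.DataFrame, events: pd.Series
) -> ConfusionTable:
    pos = second["second_positive"].to_numpy(dtype=bool)
    ref = second["second_month_idx"].to_numpy(dtype=float)
    ev = events.reindex(second.index).to_numpy(dtype=float)
    detected = ~np.isnan(ev)
    matched = detected & pos & ((ref == ev) | (ref == ev - 1))
    tp = int(matched.sum())
    fn = int(pos.sum()) - tp
    fp = int((detected & ~pos).sum())
    tn = int((~pos).sum()) - fp
    return ConfusionTable(tp=tp, tn=tn, fn=fn, fp=fp)


def scan_washout(
    gold: GoldStandard,
    claims: pd.DataFrame,
    spec: AlgorithmSpec,
    cs: CodeSets,
    k_range: range = range(2, 25),
    reference: str = "second",
    ci_method: str = "wald",
) -> WashoutScan:
    """Evaluate one algorithm's second-birth detection for each washout ``k``.

    The population is fixed across ``k`` (women with >=1 linkage birth);
    each ``k`` reuses the standard confusion/metrics path. ``best_k`` is the
    smallest ``k`` attaining the maximal Youden index.
    """
    second = second_birth_gold(gold, reference)
    first = second["first_month_idx"]
    results = []
    for k in k_range:
        ev = _earliest_events(claims, second.index, first, spec, cs, k, gold.window)
        ct = _confusion_second(second, ev)
        results.append(WashoutResult(k=k, table=ct, metrics=compute_metrics(ct, ci_method=ci_method)))
    if not results:
        raise ValueError("empty k_range")
    best = max(results, key=lambda r: (np.nan_to_num(r.metrics.youden, nan=-np.inf), -r.k))
    return WashoutScan(results=tuple(results), best_k=best.k)
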