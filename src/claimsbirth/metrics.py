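"""Month-tolerant matching and validation statistics.

A claims-derived event counts as identifying the reference childbirth when
the reference month equals the algorithm month or the month before it: a
delivery admission is billed in the discharge month, so claims may trail
the birth by one month, but they may not lead it.

Classification is at the woman level:

* reference-positive woman: TP if an event was detected *and* its month
  matches under the tolerance, otherwise FN (a detected-but-mismatched
  positive is a dating failure, not a false positive — the positive and
  negative margins are fixed by the reference, not by the algorithm);
* reference-negative woman: FP if any event was detected, otherwise TN.

From the confusion table: sensitivity, specificity, PPV, NPV with binomial
95% confidence intervals (Wald normal approximation by default, Wilson as
an option), Cohen's kappa ``(p_o - p_e)/(1 - p_e)`` with the two-rater
marginal-product expected agreement, and the Youden index
``sensitivity + specificity - 1``. Report rounding is half-up — percentages
to 1 decimal, kappa/Youden to 2 — internal values are never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .algorithms import AlgorithmSpec
from .gold import GoldStandard

__all__ = [
    "ConfusionTable",
    "MetricSet",
    "months_match",
    "build_confusion",
    "proportion_ci",
    "compute_metrics",
    "report_table",
    "round_half_up",
]

_CI_METHODS = {"wald": "normal", "wilson": "wilson"}


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def months_match(alg_month: int, gold_month: int) -> bool:
    """Tolerance rule: reference month == algorithm month or one before it."""
    return gold_month == alg_month or gold_month == alg_month - 1


@dataclass(frozen=True)
class ConfusionTable:
    """Woman-level TP/TN/FN/FP counts."""

    tp: int
    tn: int
    fn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fn + self.fp

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Validation statistics; proportions in [0,1], NaN where undefined."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float]
    npv_ci: tuple[float, float]
    kappa: float
    youden: float


def build_confusion(gold: GoldStandard, events: pd.Series) -> ConfusionTable:
    """Classify every eligible woman against one algorithm's detections.

    ``events`` holds the detected month index (NaN = not detected) and must
    be indexed by woman_id; ids outside the eligible population are a
    referential error, and women missing from ``events`` count as not
    detected.
    """
    pw = gold.per_woman
    extra = events.index.difference(pw.index)
    if len(extra):
        raise KeyError(
            f"events include women absent from the gold standard: {list(extra[:5])}"
        )
    ev = events.reindex(pw.index).to_numpy(dtype=float)
    detected = ~np.isnan(ev)
    pos = pw["gold_positive"].to_numpy(dtype=bool)
    gm = pw["gold_month_idx"].to_numpy(dtype=float)
    matched = detected & pos & ((gm == ev) | (gm == ev - 1))
    tp = int(matched.sum())
    fn = int(pos.sum()) - tp
    fp = int((detected & ~pos).sum())
    tn = int((~pos).sum()) - fp
    return ConfusionTable(tp=tp, tn=tn, fn=fn, fp=fp)


def proportion_ci(
    successes: int, n: int, level: float = 0.95, method: str = "wald"
) -> tuple[float, float]:
    """Binomial CI for a proportion, clipped to [0, 1].

    ``method`` is ``'wald'`` (normal approximation) or ``'wilson'``.
    """
    if method not in _CI_METHODS:
        raise ValueError(f"unknown CI method {method!r}")
    if n == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method=_CI_METHODS[method])
    return (float(min(max(lo, 0.0), 1.0)), float(min(max(hi, 0.0), 1.0)))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(
    ct: ConfusionTable, ci_level: float = 0.95, ci_method: str = "wald"
) -> MetricSet:
    """All validation statistics for one confusion table.

    Metrics whose denominator is zero come back NaN (with NaN CIs) rather
    than raising: an algorithm that fires for nobody simply has no PPV.
    """
    sens = _ratio(ct.tp, ct.tp + ct.fn)
    spec = _ratio(ct.tn, ct.tn + ct.fp)
    ppv = _ratio(ct.tp, ct.tp + ct.fp)
    npv = _ratio(ct.tn, ct.tn + ct.fn)

    n = ct.n
    if n > 0:
        p_o = (ct.tp + ct.tn) / n
        # expected agreement from the two classifications' margins
        p_e = (
            (ct.tp + ct.fp) * (ct.tp + ct.fn) + (ct.fn + ct.tn) * (ct.fp + ct.tn)
        ) / (n * n)
        kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    else:
        kappa = float("nan")
    youden = sens + spec - 1

    def ci(k: int, d: int) -> tuple[float, float]:
        if d == 0:
            return (float("nan"), float("nan"))
        return proportion_ci(k, d, ci_level, ci_method)

    return MetricSet(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=ci(ct.tp, ct.tp + ct.fn),
        specificity_ci=ci(ct.tn, ct.tn + ct.fp),
        ppv_ci=ci(ct.tp, ct.tp + ct.fp),
        npv_ci=ci(ct.tn, ct.tn + ct.fn),
        kappa=kappa,
        youden=youden,
    )


def report_table(
    gold: GoldStandard,
    events: pd.DataFrame,
    specs: Iterable[AlgorithmSpec],
    ci_level: float = 0.95,
    ci_method: str = "wald",
) -> pd.DataFrame:
    """One validation row per algorithm (counts, metrics and CIs).

    ``events`` is the frame from :func:`claimsbirth.algorithms.detect_events`
    (one column per algorithm id). Percentages are reported half-up at one
    decimal, kappa/Youden at two, mirroring the usual presentation of such
    validation tables.
    """
    rows = []
    for spec in specs:
        ct = build_confusion(gold, events[spec.id])
        m = compute_metrics(ct, ci_level, ci_method)
        rows.append(
            {
                "algorithm_id": spec.id,
                "definition": spec.label,
                "tp": ct.tp,
                "tn": ct.tn,
                "fn": ct.fn,
                "fp": ct.fp,
                "sens": round_half_up(m.sensitivity * 100, 1),
                "sens_lo": round_half_up(m.sensitivity_ci[0] * 100, 1),
                "sens_hi": round_half_up(m.sensitivity_ci[1] * 100, 1),
                "spec": round_half_up(m.specificity * 100, 1),
                "spec_lo": round_half_up(m.specificity_ci[0] * 100, 1),
                "spec_hi": round_half_up(m.specificity_ci[1] * 100, 1),
                "ppv": round_half_up(m.ppv * 100, 1),
                "ppv_lo": round_half_up(m.ppv_ci[0] * 100, 1),
                "ppv_hi": round_half_up(m.ppv_ci[1] * 100, 1),
                "npv": round_half_up(m.npv * 100, 1),
                "npv_lo": round_half_up(m.npv_ci[0] * 100, 1),
                "npv_hi": round_half_up(m.npv_ci[1] * 100, 1),
                "kappa": round_half_up(m.kappa, 2),
                "youden": round_half_up(m.youden, 2),
            }
        )
    return pd.DataFrame(rows)


def format_metrics(ct: ConfusionTable, m: MetricSet) -> str:
    """Human-readable metric block (used by the CLI)."""
    def pct(v, ci):
        if math.isnan(v):
            return "undefined"
        return (
            f"{round_half_up(v * 100, 1):.1f}% "
            f"(95% CI {round_half_up(ci[0] * 100, 1):.1f}-{round_half_up(ci[1] * 100, 1):.1f})"
        )

    lines = [
        f"TP={ct.tp} TN={ct.tn} FN={ct.fn} FP={ct.fp} (n={ct.n})",
        f"sensitivity: {pct(m.sensitivity, m.sensitivity_ci)}",
        f"specificity: {pct(m.specificity, m.specificity_ci)}",
        f"PPV:         {pct(m.ppv, m.ppv_ci)}",
        f"NPV:         {pct(m.npv, m.npv_ci)}",
        f"kappa:       {round_half_up(m.kappa, 2):.2f}",
        f"Youden:      {round_half_up(m.youden, 2):.2f}",
    ]
    return "\n".join(lines)
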