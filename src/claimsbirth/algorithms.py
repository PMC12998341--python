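"""Boolean phenotyping algorithms over claims code sets.

Six primitive conditions are evaluated per woman from her claim lines:

========== ==========================================================
symbol     meaning
========== ==========================================================
A          childbirth diagnosis code without a suspected flag
A_susp     childbirth diagnosis code, suspected flag permitted
           (superset of A: flagged *and* unflagged lines qualify)
A_pre      as A, on the preterm-excluded diagnosis set
A_pre_susp as A_susp, on the preterm-excluded diagnosis set
B          childbirth procedure code
C          childbirth medication code
========== ==========================================================

A phenotyping algorithm is an AND/OR combination of these conditions. The
built-in roster has 32 algorithms: 18 over {A, A_susp, B, C} and the 14
preterm-excluded counterparts of those that reference a diagnosis condition.

Detection semantics: by default a condition holds if the woman has at least
one qualifying claim line anywhere in the observation window ("anytime"
mode — claim lines for one delivery routinely land in different billing
months, so same-month co-occurrence is not required). When an algorithm
fires, the event is dated to the latest month carrying any qualifying line
of any referenced, satisfied condition; discharge billing means that month
may trail the actual birth month by one, which the validation tolerance
(:func:`claimsbirth.metrics.months_match`) absorbs. A stricter "same-month"
mode requiring all AND-ed conditions within one billing month is available
for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .codesets import CodeSets, normalize_icd10

__all__ = [
    "Condition",
    "Expr",
    "Cond",
    "And",
    "Or",
    "AlgorithmSpec",
    "builtin_algorithms",
    "annotate_conditions",
    "condition_months",
    "detect_event",
    "detect_events",
]


class Condition(Enum):
    A = "A"
    A_SUSP = "A_susp"
    A_PRE = "A_pre"
    A_PRE_SUSP = "A_pre_susp"
    B = "B"
    C = "C"

    @property
    def label(self) -> str:
        return {
            Condition.A: "[A]",
            Condition.A_SUSP: "[A+susp]",
            Condition.A_PRE: "[A(pre(-))]",
            Condition.A_PRE_SUSP: "[A(pre(-))+susp]",
            Condition.B: "[B]",
            Condition.C: "[C]",
        }[self]


# -- expression trees -------------------------------------------------------


class Expr:
    """Monotone Boolean expression over conditions (AND/OR only)."""

    def evaluate(self, truth: Mapping[Condition, bool]) -> bool:
        raise NotImplementedError

    def conditions(self) -> frozenset[Condition]:
        raise NotImplementedError

    def label(self) -> str:
        raise NotImplementedError

    def substitute(self, mapping: Mapping[Condition, Condition]) -> "Expr":
        raise NotImplementedError


@dataclass(frozen=True)
class Cond(Expr):
    condition: Condition

    def evaluate(self, truth):
        return bool(truth[self.condition])

    def conditions(self):
        return frozenset({self.condition})

    def label(self):
        return self.condition.label

    def substitute(self, mapping):
        return Cond(mapping.get(self.condition, self.condition))


@dataclass(frozen=True)
class And(Expr):
    terms: tuple[Expr, ...]

    def __init__(self, *terms: Expr):
        object.__setattr__(self, "terms", tuple(terms))

    def evaluate(self, truth):
        return all(t.evaluate(truth) for t in self.terms)

    def conditions(self):
        return frozenset().union(*(t.conditions() for t in self.terms))

    def label(self):
        return " and ".join(t.label() for t in self.terms)

    def substitute(self, mapping):
        return And(*(t.substitute(mapping) for t in self.terms))


@dataclass(frozen=True)
class Or(Expr):
    terms: tuple[Expr, ...]

    def __init__(self, *terms: Expr):
        object.__setattr__(self, "terms", tuple(terms))

    def evaluate(self, truth):
        return any(t.evaluate(truth) for t in self.terms)

    def conditions(self):
        return frozenset().union(*(t.conditions() for t in self.terms))

    def label(self):
        return " or ".join(t.label() for t in self.terms)

    def substitute(self, mapping):
        return Or(*(t.substitute(mapping) for t in self.terms))


@dataclass(frozen=True)
class AlgorithmSpec:
    """One phenotyping algorithm: a stable id plus a Boolean expression."""

    id: int
    expression: Expr

    @property
    def label(self) -> str:
        return self.expression.label()


def builtin_algorithms() -> list[AlgorithmSpec]:
    """The 32-algorithm roster.

    Algorithms 1-18 combine [A+susp]/[A]/[B]/[C]; 19-32 are the 14 of those
    referencing a diagnosis condition with the diagnosis set replaced by its
    preterm-excluded variant (the four diagnosis-free combinations are not
    duplicated).
    """
    a, s, b, c = (
        Cond(Condition.A),
        Cond(Condition.A_SUSP),
        Cond(Condition.B),
        Cond(Condition.C),
    )
    base: list[Expr] = [
        s,                  # 1  [A+susp]
        b,                  # 2  [B]
        c,                  # 3  [C]
        And(s, b),          # 4
        Or(s, b),           # 5
        And(s, c),          # 6
        Or(s, c),           # 7
        And(b, c),          # 8
        Or(b, c),           # 9
        And(s, b, c),       # 10
        Or(s, b, c),        # 11
        a,                  # 12 [A]
        And(a, b),          # 13
        Or(a, b),           # 14
        And(a, c),          # 15
        Or(a, c),           # 16
        And(a, b, c),       # 17
        Or(a, b, c),        # 18
    ]
    specs = [AlgorithmSpec(i + 1, e) for i, e in enumerate(base)]
    preterm_map = {
        Condition.A: Condition.A_PRE,
        Condition.A_SUSP: Condition.A_PRE_SUSP,
    }
    next_id = 19
    for e in base:
        refs = e.conditions()
        if refs & {Condition.A, Condition.A_SUSP}:
            specs.append(AlgorithmSpec(next_id, e.substitute(preterm_map)))
            next_id += 1
    assert len(specs) == 32
    return specs


# -- condition evaluation ---------------------------------------------------

_COND_COLS = {c: f"cond_{c.value}" for c in Condition}


def annotate_conditions(claims: pd.DataFrame, cs: CodeSets) -> pd.DataFrame:
    """Add one boolean column per condition marking qualifying claim lines."""
    out = claims.copy()
    is_dx = (claims["domain"] == "diagnosis").to_numpy()
    cats = claims["code"].map(lambda c: normalize_icd10(str(c)))
    in_dx = cats.isin(cs.diagnosis).to_numpy() & is_dx
    in_dx_pre = in_dx & ~cats.isin(cs.preterm_exclusion).to_numpy()
    unflagged = ~claims["suspected"].to_numpy(dtype=bool)
    out[_COND_COLS[Condition.A_SUSP]] = in_dx
    out[_COND_COLS[Condition.A]] = in_dx & unflagged
    out[_COND_COLS[Condition.A_PRE_SUSP]] = in_dx_pre
    out[_COND_COLS[Condition.A_PRE]] = in_dx_pre & unflagged
    out[_COND_COLS[Condition.B]] = (claims["domain"] == "procedure").to_numpy() & claims[
        "code"
    ].isin(cs.procedure).to_numpy()
    out[_COND_COLS[Condition.C]] = (claims["domain"] == "medication").to_numpy() & claims[
        "code"
    ].isin(cs.medication).to_numpy()
    return out


def condition_months(
    claims: pd.DataFrame, cond: Condition, cs: CodeSets
) -> set[int]:
    """Months in which one woman's claims carry a qualifying line for ``cond``."""
    if claims["woman_id"].nunique() > 1:
        raise ValueError("condition_months expects claims for a single woman")
    ann = annotate_conditions(claims, cs)
    return set(ann.loc[ann[_COND_COLS[cond]], "month_idx"].astype(int))


def _restrict_window(claims: pd.DataFrame, window: tuple[int, int] | None) -> pd.DataFrame:
    if window is None:
        return claims
    start, end = window
    return claims[(claims["month_idx"] >= start) & (claims["month_idx"] < end)]


def detect_events(
    claims: pd.DataFrame,
    women: Iterable[str],
    specs: Iterable[AlgorithmSpec],
    cs: CodeSets,
    window: tuple[int, int] | None = None,
    and_mode: str = "anytime",
) -> pd.DataFrame:
    """Evaluate algorithms for every woman; return detected event months.

    Returns a DataFrame indexed by ``woman_id`` (exactly the ``women``
    given, detections or not) with one float column per algorithm id: the
    claims-derived childbirth month index, NaN where the algorithm does not
    fire.

    ``and_mode='anytime'`` (default) treats each condition as satisfied by a
    qualifying line anywhere in the window; ``'same-month'`` requires the
    whole expression to hold within a single billing month, dating the event
    to the latest such month.
    """
    if and_mode not in ("anytime", "same-month"):
        raise ValueError(f"unknown and_mode {and_mode!r}")
    specs = list(specs)
    index = pd.Index(list(women), name="woman_id")
    cl = _restrict_window(claims, window)
    cl = cl[cl["woman_id"].isin(index)]
    ann = annotate_conditions(cl, cs)

    out = pd.DataFrame(index=index)
    if and_mode == "same-month":
        per_month = ann.groupby(["woman_id", "month_idx"])[list(_COND_COLS.values())].any()
        truth_cols = {c: per_month[_COND_COLS[c]].to_numpy() for c in Condition}
        for spec in specs:
            sat = _eval_vector(spec.expression, truth_cols)
            months = per_month.index.get_level_values("month_idx").to_numpy()
            wids = per_month.index.get_level_values("woman_id")
            hit = pd.Series(months[sat], index=wids[sat]).groupby(level=0).max()
            out[spec.id] = hit.reindex(index).astype(float)
        return out

    has: dict[Condition, np.ndarray] = {}
    max_month: dict[Condition, np.ndarray] = {}
    for c in Condition:
        sub = ann[ann[_COND_COLS[c]]]
        agg = sub.groupby("woman_id")["month_idx"].max().reindex(index)
        max_month[c] = agg.to_numpy(dtype=float)
        has[c] = ~np.isnan(max_month[c])

    for spec in specs:
        sat = _eval_vector(spec.expression, has)
        refs = sorted(spec.expression.conditions(), key=lambda c: c.value)
        stacked = np.vstack([max_month[c] for c in refs])
        event = np.max(np.nan_to_num(stacked, nan=-np.inf), axis=0)
        event[~sat | ~np.isfinite(event)] = np.nan
        out[spec.id] = event
    return out


def _eval_vector(expr: Expr, truth: Mapping[Condition, np.ndarray]) -> np.ndarray:
    if isinstance(expr, Cond):
        return np.asarray(truth[expr.condition], dtype=bool)
    if isinstance(expr, And):
        acc = _eval_vector(expr.terms[0], truth)
        for t in expr.terms[1:]:
            acc = acc & _eval_vector(t, truth)
        return acc
    if isinstance(expr, Or):
        acc = _eval_vector(expr.terms[0], truth)
        for t in expr.terms[1:]:
            acc = acc | _eval_vector(t, truth)
        return acc
    raise TypeError(f"unknown expression node {expr!r}")


def detect_event(
    claims: pd.DataFrame,
    spec: AlgorithmSpec,
    cs: CodeSets,
    window: tuple[int, int] | None = None,
    and_mode: str = "anytime",
) -> int | None:
    """Single-woman convenience wrapper around :func:`detect_events`.

    Returns the detected event month index, or ``None``.
    """
    if claims.empty:
        return None
    wids = claims["woman_id"].unique()
    if len(wids) > 1:
        raise ValueError("detect_event expects claims for a single woman")
    res = detect_events(claims, wids, [spec], cs, window, and_mode)
    v = res[spec.id].iloc[0]
    return None if pd.isna(v) else int(v)
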