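"""Independent brute-force oracles used to cross-check the vectorized paths.

Everything here is deliberately naive: per-record Python loops, explicit
condition definitions re-derived from first principles, no shared code with
the package's detection/confusion implementations beyond the public domain
types. Keep it slow and obvious.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from claimsbirth.algorithms import AlgorithmSpec, And, Cond, Condition, Or


def record_qualifies(row, cond: Condition, cs) -> bool:
    """Does one claim line qualify for a condition? Re-derived rule-by-rule."""
    code = str(row["code"]).strip().upper().replace(".", "")
    cat = code[:3]
    cat_ok = len(cat) == 3 and cat[0].isalpha() and cat[1:].isdigit()
    if cond is Condition.B:
        return row["domain"] == "procedure" and row["code"] in cs.procedure
    if cond is Condition.C:
        return row["domain"] == "medication" and row["code"] in cs.medication
    if row["domain"] != "diagnosis" or not cat_ok:
        return False
    in_full = cat in cs.diagnosis
    in_pre = in_full and cat not in cs.preterm_exclusion
    flagged = bool(row["suspected"])
    if cond is Condition.A:
        return in_full and not flagged
    if cond is Condition.A_SUSP:
        return in_full
    if cond is Condition.A_PRE:
        return in_pre and not flagged
    if cond is Condition.A_PRE_SUSP:
        return in_pre
    raise AssertionError(cond)


def brute_condition_months(claims: pd.DataFrame, cond: Condition, cs) -> set[int]:
    months = set()
    for _, row in claims.iterrows():
        if record_qualifies(row, cond, cs):
            months.add(int(row["month_idx"]))
    return months


def _eval(expr, truth):
    if isinstance(expr, Cond):
        return truth[expr.condition]
    if isinstance(expr, And):
        return all(_eval(t, truth) for t in expr.terms)
    if isinstance(expr, Or):
        return any(_eval(t, truth) for t in expr.terms)
    raise AssertionError(expr)


def brute_detect(
    claims: pd.DataFrame,
    spec: AlgorithmSpec,
    cs,
    window: tuple[int, int] | None = None,
) -> int | None:
    """Latest-month detection for one woman, by full enumeration."""
    if window is not None:
        claims = claims[
            (claims["month_idx"] >= window[0]) & (claims["month_idx"] < window[1])
        ]
    month_sets = {c: brute_condition_months(claims, c, cs) for c in Condition}
    truth = {c: bool(month_sets[c]) for c in Condition}
    if not _eval(spec.expression, truth):
        return None
    pool = set()
    for c in spec.expression.conditions():
        pool |= month_sets[c]
    return max(pool)


def brute_confusion(gold_rows, events: dict) -> tuple[int, int, int, int]:
    """Per-woman if/else classification.

    ``gold_rows``: iterable of (woman_id, gold_positive, gold_month_or_None);
    ``events``: woman_id -> detected month or None.
    """
    tp = tn = fn = fp = 0
    for wid, positive, gm in gold_rows:
        ev = events.get(wid)
        if positive:
            if ev is not None and (gm == ev or gm == ev - 1):
                tp += 1
            else:
                fn += 1
        else:
            if ev is not None:
                fp += 1
            else:
                tn += 1
    return tp, tn, fn, fp


def random_claims_fixture(rng: np.random.Generator, cs, max_records: int = 10) -> pd.DataFrame:
    """Random single-woman claims with a mix of qualifying and junk lines."""
    n = int(rng.integers(0, max_records + 1))
    diag = sorted(cs.diagnosis)
    junk_dx = ["O20", "O10", "Z99", "A00", "bogus", "O8", ""]
    proc = sorted(cs.procedure) + ["PROC_UNRELATED"]
    med = sorted(cs.medication) + ["MED_UNRELATED"]
    rows = []
    for _ in range(n):
        domain = ("diagnosis", "procedure", "medication")[rng.integers(0, 3)]
        if domain == "diagnosis":
            pool = diag + junk_dx
            code = pool[rng.integers(0, len(pool))]
            suspected = bool(rng.integers(0, 2))
        elif domain == "procedure":
            code = proc[rng.integers(0, len(proc))]
            suspected = False
        else:
            code = med[rng.integers(0, len(med))]
            suspected = False
        rows.append(
            {
                "woman_id": "W0",
                "month_idx": int(rng.integers(24170, 24190)),
                "domain": domain,
                "code": code,
                "suspected": suspected,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["woman_id", "month_idx", "domain", "code", "suspected"]
        ).astype({"month_idx": int, "suspected": bool})
    return pd.DataFrame(rows)
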