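"""Linkage-based gold standard for childbirth month.

Insurer-maintained family registries let a child be linked to an insured
mother through a parent-child identifier, assigned only for live births.
The child's birth year and month then serve as the reference ("gold
standard") childbirth event against which claims-derived events are judged.

Two restrictions define the validation cohort:

* only women whose husband can be identified in the family information are
  kept — otherwise a child may be registered under the father's insurance
  and the mother's linkage silently missing, which would misclassify real
  deliveries as false positives;
* a linked birth qualifies only if the mother was aged 15-49 in completed
  years in the child's birth month. Women whose every linked birth fails
  the age filter remain in the cohort as gold-negatives, flagged
  ``age_ineligible``.

Women with several qualifying births contribute only the most recent one
(``gold_month``); the full qualifying history is retained for the
second-birth analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import LinkageError
from .months import format_ym

__all__ = ["GoldStandard", "build_gold_standard"]

AGE_MIN = 15
AGE_MAX = 49


@dataclass
class GoldStandard:
    """Per-woman childbirth reference for one observation window.

    ``per_woman`` is indexed by ``woman_id`` over the eligible population and
    carries ``gold_positive`` (bool), ``gold_month_idx`` (float, NaN when
    negative), ``age_ineligible`` (bool) and ``n_births`` (int, qualifying
    births in window). ``birth_months`` maps each gold-positive woman to her
    sorted qualifying birth months.
    """

    per_woman: pd.DataFrame
    birth_months: dict[str, tuple[int, ...]]
    window: tuple[int, int]
    n_ignored_links: int = 0
    n_age_ineligible_women: int = 0
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_eligible(self) -> int:
        return len(self.per_woman)

    @property
    def n_positive(self) -> int:
        return int(self.per_woman["gold_positive"].sum())

    @property
    def n_negative(self) -> int:
        return self.n_eligible - self.n_positive

    @property
    def birth_rate(self) -> float:
        """Fraction of the eligible cohort with a qualifying childbirth."""
        return self.n_positive / self.n_eligible if self.n_eligible else float("nan")


def build_gold_standard(
    population: pd.DataFrame,
    links: pd.DataFrame,
    window: tuple[int, int],
    *,
    require_husband: bool = True,
    age_range: tuple[int, int] = (AGE_MIN, AGE_MAX),
) -> GoldStandard:
    """Build the gold standard from population and parent-child link tables.

    Parameters
    ----------
    population
        As returned by :func:`claimsbirth.io.read_population`.
    links
        As returned by :func:`claimsbirth.io.read_links`.
    window
        Half-open ``[start, end)`` month-index observation window.
    require_husband
        Restrict the cohort to husband-identified women (the default; turn
        off only for sensitivity analyses).
    age_range
        Inclusive maternal age band, in completed years at the child's birth
        month, for a linked birth to qualify.

    Raises
    ------
    LinkageError
        If a link references an unknown mother, or a child's birth precedes
        the mother's own birth month.
    """
    start, end = window
    if end <= start:
        raise ValueError("empty observation window")
    lo, hi = age_range

    cohort = population
    if require_husband:
        cohort = population[population["husband_identified"]]

    unknown = ~links["mother_id"].isin(population.index)
    if unknown.any():
        bad = links.loc[unknown, "mother_id"].iloc[:5].tolist()
        raise LinkageError(f"links reference unknown mother_id values: {bad}")

    lk = links.copy()
    lk["mother_birth"] = population["birth_month_idx"].reindex(lk["mother_id"]).values
    if (lk["child_birth_month_idx"] < lk["mother_birth"]).any():
        row = lk[lk["child_birth_month_idx"] < lk["mother_birth"]].iloc[0]
        raise LinkageError(
            f"child born {format_ym(row['child_birth_month_idx'])} before mother "
            f"{row['mother_id']} ({format_ym(row['mother_birth'])})"
        )

    in_window = (lk["child_birth_month_idx"] >= start) & (lk["child_birth_month_idx"] < end)
    n_ignored = int((~in_window).sum())
    lk = lk[in_window]
    # completed-years age at the child's birth month
    age = (lk["child_birth_month_idx"] - lk["mother_birth"]) // 12
    qualifies = (age >= lo) & (age <= hi)
    in_cohort = lk["mother_id"].isin(cohort.index)

    qual = lk[qualifies & in_cohort]
    grouped = qual.groupby("mother_id")["child_birth_month_idx"]
    gold_month = grouped.max()
    n_births = grouped.size()
    birth_months = {
        wid: tuple(sorted(m)) for wid, m in grouped.apply(list).items()
    }

    # women with in-window links but no age-qualifying birth
    linked_women = set(lk.loc[in_cohort, "mother_id"])
    age_ineligible_women = linked_women - set(gold_month.index)

    per_woman = pd.DataFrame(index=cohort.index.copy())
    per_woman["gold_positive"] = per_woman.index.isin(gold_month.index)
    per_woman["gold_month_idx"] = gold_month.reindex(per_woman.index).astype(float)
    per_woman["age_ineligible"] = per_woman.index.isin(age_ineligible_women)
    per_woman["n_births"] = (
        n_births.reindex(per_woman.index).fillna(0).astype(np.int64)
    )

    counts = {
        "population": len(population),
        "husband_filtered_out": len(population) - len(cohort),
        "links_total": len(links),
        "links_out_of_window": n_ignored,
        "age_ineligible_women": len(age_ineligible_women),
    }
    return GoldStandard(
        per_woman=per_woman,
        birth_months=birth_months,
        window=window,
        n_ignored_links=n_ignored,
        n_age_ineligible_women=len(age_ineligible_women),
        counts=counts,
    )
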