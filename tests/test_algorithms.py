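import numpy as np
import pandas as pd
import pytest

from claimsbirth.algorithms import (
    And,
    Cond,
    Condition,
    Or,
    builtin_algorithms,
    condition_months,
    detect_event,
    detect_events,
)

from _oracles import brute_condition_months, brute_detect, random_claims_fixture
from conftest import make_claims

M = 24245  # arbitrary month index (2020-06)


# -- roster ------------------------------------------------------------------


def test_roster_size_and_ids(specs):
    assert len(specs) == 32
    assert [s.id for s in specs] == list(range(1, 33))


@pytest.mark.parametrize(
    "alg_id, expected",
    [
        (1, Cond(Condition.A_SUSP)),
        (2, Cond(Condition.B)),
        (3, Cond(Condition.C)),
        (10, And(Cond(Condition.A_SUSP), Cond(Condition.B), Cond(Condition.C))),
        (11, Or(Cond(Condition.A_SUSP), Cond(Condition.B), Cond(Condition.C))),
        (12, Cond(Condition.A)),
        (18, Or(Cond(Condition.A), Cond(Condition.B), Cond(Condition.C))),
        (19, Cond(Condition.A_PRE_SUSP)),
        (25, Or(Cond(Condition.A_PRE_SUSP), Cond(Condition.B), Cond(Condition.C))),
        (26, Cond(Condition.A_PRE)),
        (32, Or(Cond(Condition.A_PRE), Cond(Condition.B), Cond(Condition.C))),
    ],
)
def test_builtin_expressions(spec_by_id, alg_id, expected):
    assert spec_by_id[alg_id].expression == expected


def test_preterm_roster_is_the_diagnosis_referencing_subset(specs):
    base = specs[:18]
    preterm = specs[18:]
    assert len(preterm) == 14
    diag_base = [
        s
        for s in base
        if s.expression.conditions() & {Condition.A, Condition.A_SUSP}
    ]
    assert len(diag_base) == 14
    swap = {Condition.A: Condition.A_PRE, Condition.A_SUSP: Condition.A_PRE_SUSP}
    for b, p in zip(diag_base, preterm):
        assert b.expression.substitute(swap) == p.expression
    # the four diagnosis-free combinations are not duplicated
    for s in preterm:
        assert s.expression.conditions() & {Condition.A_PRE, Condition.A_PRE_SUSP}


# -- condition months --------------------------------------------------------


def test_unflagged_diagnosis_qualifies_for_both_A_variants(cs):
    claims = make_claims([("W0", M, "diagnosis", "O80", False)])
    assert condition_months(claims, Condition.A, cs) == {M}
    assert condition_months(claims, Condition.A_SUSP, cs) == {M}


def test_suspected_diagnosis_counts_only_with_flag_permitted(cs):
    claims = make_claims([("W0", M, "diagnosis", "O80", True)])
    assert condition_months(claims, Condition.A, cs) == set()
    assert condition_months(claims, Condition.A_SUSP, cs) == {M}


def test_preterm_code_excluded_from_pre_variants(cs):
    claims = make_claims([("W0", M, "diagnosis", "O60", True)])
    assert condition_months(claims, Condition.A_PRE_SUSP, cs) == set()
    assert condition_months(claims, Condition.A_SUSP, cs) == {M}


def test_domain_must_match_code_set(cs):
    # a procedure-set code on a diagnosis line qualifies for nothing
    claims = make_claims([("W0", M, "diagnosis", "PROC_CAESAREAN", False)])
    for c in Condition:
        assert condition_months(claims, c, cs) == set()


# -- detection ---------------------------------------------------------------


def test_single_procedure_record_detected(cs, spec_by_id):
    claims = make_claims([("W0", M, "procedure", "PROC_CAESAREAN", False)])
    assert detect_event(claims, spec_by_id[2], cs) == M


def test_latest_month_dating(cs, spec_by_id):
    claims = make_claims(
        [
            ("W0", M - 2, "diagnosis", "O80", False),
            ("W0", M, "diagnosis", "O86", False),  # postpartum echo
        ]
    )
    assert detect_event(claims, spec_by_id[1], cs) == M


def test_and_requires_every_condition(cs, spec_by_id):
    claims = make_claims([("W0", M, "diagnosis", "O80", False)])
    assert detect_event(claims, spec_by_id[4], cs) is None  # [A+susp] and [B]


def test_or_dating_uses_all_satisfied_conditions(cs, spec_by_id):
    # OR fires on the procedure alone, but a later diagnosis month dates it
    claims = make_claims(
        [
            ("W0", M, "procedure", "PROC_VACUUM", False),
            ("W0", M + 1, "diagnosis", "O86", False),
        ]
    )
    assert detect_event(claims, spec_by_id[11], cs) == M + 1


def test_window_restriction(cs, spec_by_id):
    claims = make_claims([("W0", M, "procedure", "PROC_VACUUM", False)])
    assert detect_event(claims, spec_by_id[2], cs, window=(M + 1, M + 10)) is None


def test_same_month_mode(cs, spec_by_id):
    spread = make_claims(
        [
            ("W0", M, "diagnosis", "O80", False),
            ("W0", M + 1, "procedure", "PROC_CAESAREAN", False),
        ]
    )
    spec = spec_by_id[4]  # [A+susp] and [B]
    assert detect_event(spread, spec, cs, and_mode="anytime") == M + 1
    assert detect_event(spread, spec, cs, and_mode="same-month") is None
    together = make_claims(
        [
            ("W0", M, "diagnosis", "O80", False),
            ("W0", M, "procedure", "PROC_CAESAREAN", False),
        ]
    )
    assert detect_event(together, spec, cs, and_mode="same-month") == M


def test_detect_events_covers_undetected_women(cs, specs):
    claims = make_claims([("W0", M, "procedure", "PROC_CAESAREAN", False)])
    ev = detect_events(claims, ["W0", "W1"], specs, cs)
    assert ev.loc["W0", 2] == M
    assert np.isnan(ev.loc["W1", 2])
    assert list(ev.index) == ["W0", "W1"]


# -- properties and oracle equivalence --------------------------------------


def test_condition_superset_properties(cs):
    rng = np.random.default_rng(42)
    for _ in range(150):
        claims = random_claims_fixture(rng, cs)
        months = {c: brute_condition_months(claims, c, cs) for c in Condition}
        assert months[Condition.A] <= months[Condition.A_SUSP]
        assert months[Condition.A_PRE] <= months[Condition.A]
        assert months[Condition.A_PRE_SUSP] <= months[Condition.A_SUSP]
        # and the package agrees with the brute-force enumeration
        if len(claims):
            for c in Condition:
                assert condition_months(claims, c, cs) == months[c]


def test_and_detection_implies_or_detection(cs):
    a, b, c = Cond(Condition.A_SUSP), Cond(Condition.B), Cond(Condition.C)
    from claimsbirth.algorithms import AlgorithmSpec

    and_spec = AlgorithmSpec(101, And(a, b, c))
    or_spec = AlgorithmSpec(102, Or(a, b, c))
    rng = np.random.default_rng(3)
    for _ in range(100):
        claims = random_claims_fixture(rng, cs)
        if claims.empty:
            continue
        if detect_event(claims, and_spec, cs) is not None:
            assert detect_event(claims, or_spec, cs) is not None


def test_detection_matches_brute_force(cs, specs):
    rng = np.random.default_rng(11)
    for _ in range(150):
        claims = random_claims_fixture(rng, cs)
        if claims.empty:
            continue
        ev = detect_events(claims, ["W0"], specs, cs)
        for spec in specs:
            expected = brute_detect(claims, spec, cs)
            got = ev.loc["W0", spec.id]
            if expected is None:
                assert np.isnan(got)
            else:
                assert got == expected


def test_preterm_restriction_never_adds_detections(cs, specs):
    # every woman detected by a preterm-excluded algorithm is detected by
    # its full-diagnosis counterpart
    pairs = {19: 1, 20: 4, 21: 5, 22: 6, 23: 7, 24: 10, 25: 11, 26: 12,
             27: 13, 28: 14, 29: 15, 30: 16, 31: 17, 32: 18}
    by_id = {s.id: s for s in specs}
    rng = np.random.default_rng(5)
    for _ in range(100):
        claims = random_claims_fixture(rng, cs)
        if claims.empty:
            continue
        for pre_id, base_id in pairs.items():
            if detect_event(claims, by_id[pre_id], cs) is not None:
                assert detect_event(claims, by_id[base_id], cs) is not None
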