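import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from claimsbirth import (
    ConfusionTable,
    build_confusion,
    build_gold_standard,
    compute_metrics,
    months_match,
    proportion_ci,
    report_table,
)
from claimsbirth.metrics import round_half_up
from claimsbirth.months import month_index as mi

from _oracles import brute_confusion
from conftest import make_links, make_population


@pytest.mark.parametrize(
    "alg, gold, expected",
    [
        ((2020, 6), (2020, 5), True),   # claims lag birth by the discharge month
        ((2020, 5), (2020, 5), True),
        ((2020, 5), (2020, 6), False),  # claims may not lead the birth
        ((2020, 5), (2020, 3), False),
    ],
)
def test_months_match(alg, gold, expected):
    assert months_match(mi(*alg), mi(*gold)) is expected


def _gold_fixture(window, rows, links):
    return build_gold_standard(make_population(rows), make_links(links), window)


def test_build_confusion_single_woman(window):
    gold = _gold_fixture(window, [("W1", mi(1990, 1), True)], [("W1", mi(2020, 5))])
    ev = pd.Series({"W1": float(mi(2020, 5))})
    ct = build_confusion(gold, ev)
    assert (ct.tp, ct.tn, ct.fn, ct.fp) == (1, 0, 0, 0)


def test_detected_but_mismatched_positive_is_fn_not_fp(window):
    gold = _gold_fixture(window, [("W1", mi(1990, 1), True)], [("W1", mi(2020, 5))])
    ev = pd.Series({"W1": float(mi(2020, 8))})  # three months late
    ct = build_confusion(gold, ev)
    assert (ct.tp, ct.tn, ct.fn, ct.fp) == (0, 0, 1, 0)


def test_five_woman_fixture_hand_enumeration(window):
    rows = [(f"W{i}", mi(1990, 1), True) for i in range(1, 6)]
    links = [("W1", mi(2020, 5)), ("W2", mi(2019, 3))]
    gold = _gold_fixture(window, rows, links)
    # W1 matched, W2 undetected, W4 falsely detected
    ev = pd.Series({"W1": float(mi(2020, 5)), "W4": float(mi(2018, 1))})
    ct = build_confusion(gold, ev)
    assert (ct.tp, ct.tn, ct.fn, ct.fp) == (1, 2, 1, 1)
    # the naive per-woman oracle agrees
    gold_rows = [("W1", True, mi(2020, 5)), ("W2", True, mi(2019, 3)),
                 ("W3", False, None), ("W4", False, None), ("W5", False, None)]
    assert brute_confusion(gold_rows, {"W1": mi(2020, 5), "W4": mi(2018, 1)}) == (1, 2, 1, 1)


def test_confusion_rejects_unknown_women(window):
    gold = _gold_fixture(window, [("W1", mi(1990, 1), True)], [])
    with pytest.raises(KeyError):
        build_confusion(gold, pd.Series({"W9": 100.0}))


def test_perfect_table():
    m = compute_metrics(ConfusionTable(50, 50, 0, 0))
    assert m.sensitivity == m.specificity == m.ppv == m.npv == 1.0
    assert m.kappa == 1.0
    assert m.youden == 1.0


def test_highest_ppv_reference_row():
    m = compute_metrics(ConfusionTable(13083, 812797, 24851, 3895))
    assert round_half_up(m.ppv * 100, 1) == 77.1


def test_undefined_metrics_are_nan_not_errors():
    m = compute_metrics(ConfusionTable(0, 10, 0, 0))  # nobody gold-positive
    assert math.isnan(m.sensitivity)
    assert math.isnan(m.ppv)
    assert m.specificity == 1.0
    all_zero = compute_metrics(ConfusionTable(0, 0, 0, 0))
    assert math.isnan(all_zero.kappa)


def test_youden_identity_to_machine_precision():
    rng = np.random.default_rng(0)
    for _ in range(200):
        tp, tn, fn, fp = rng.integers(1, 1000, 4)
        m = compute_metrics(ConfusionTable(int(tp), int(tn), int(fn), int(fp)))
        assert m.youden == m.sensitivity + m.specificity - 1


def test_metrics_agree_with_independent_recomputation():
    # dual route: expand each table to labels and use sklearn's kappa,
    # plus direct ratio formulas, on 1000 random tables
    rng = np.random.default_rng(123)
    for _ in range(1000):
        tp, tn, fn, fp = (int(x) for x in rng.integers(1, 400, 4))
        m = compute_metrics(ConfusionTable(tp, tn, fn, fp))
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.ppv == pytest.approx(tp / (tp + fp))
        assert m.npv == pytest.approx(tn / (tn + fn))
        y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
        y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
        assert m.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred), abs=1e-12)


def test_kappa_near_zero_under_independence():
    rng = np.random.default_rng(99)
    n = 200_000
    gold = rng.random(n) < 0.05
    detected = rng.random(n) < 0.07  # independent of gold
    tp = int((gold & detected).sum())
    fn = int((gold & ~detected).sum())
    fp = int((~gold & detected).sum())
    tn = int((~gold & ~detected).sum())
    m = compute_metrics(ConfusionTable(tp, tn, fn, fp))
    assert abs(m.kappa) < 0.01


def test_wald_ci_formula_and_clipping():
    lo, hi = proportion_ci(25361, 37934)
    p = 25361 / 37934
    h = 1.959963984540054 * math.sqrt(p * (1 - p) / 37934)
    assert lo == pytest.approx(p - h)
    assert hi == pytest.approx(p + h)
    assert proportion_ci(0, 100)[0] == 0.0  # clipped at zero
    assert proportion_ci(100, 100)[1] == 1.0
    wlo, whi = proportion_ci(50, 100, method="wilson")
    assert 0.39 < wlo < 0.41 and 0.59 < whi < 0.61
    with pytest.raises(ValueError):
        proportion_ci(1, 10, method="bogus")


def test_report_table_shape_and_marginals(window, cs, specs):
    from claimsbirth import SynthConfig, detect_events, generate

    cfg = SynthConfig(n_women=3000, seed=2)
    ds = generate(cfg)
    gold = build_gold_standard(ds.population, ds.links, cfg.window)
    ev = detect_events(ds.claims, gold.per_woman.index, specs, cs, cfg.window)
    table = report_table(gold, ev, specs)
    assert len(table) == 32
    assert (table["tp"] + table["fn"]).nunique() == 1
    assert (table["tn"] + table["fp"]).nunique() == 1
    assert (table["tp"] + table["fn"]).iloc[0] == gold.n_positive

    # nothing detected: every row is (0, N_neg, N_pos, 0)
    empty = ds.claims.iloc[0:0]
    ev0 = detect_events(empty, gold.per_woman.index, specs, cs, cfg.window)
    t0 = report_table(gold, ev0, specs)
    assert (t0["tp"] == 0).all() and (t0["fp"] == 0).all()
    assert (t0["fn"] == gold.n_positive).all()
    assert (t0["tn"] == gold.n_negative).all()
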