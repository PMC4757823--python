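"""Enrichment factor, maxEF, AUC and hit selection."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

from morscreen.errors import DomainError
from morscreen.enrichment_validation import (
    enrichment_factor,
    evaluate_model_ensemble,
    max_enrichment_factor,
    roc_auc,
    round_display,
    select_top_hits,
)
from morscreen.library_io import ActivityRecord, build_screening_result


@pytest.mark.parametrize(
    "tp,n,a,big_n,display",
    [
        (39, 48, 45, 240, 4.3),  # combined agonist pharmacophore ensemble
        (42, 77, 47, 240, 2.8),  # combined antagonist pharmacophore ensemble
        (72, 77, 92, 240, 2.4),  # antagonist ensemble, all actives counted
        (32, 48, 45, 240, 3.6),  # combined agonist shape ensemble
        (39, 54, 47, 240, 3.7),  # combined antagonist shape ensemble
    ],
)
def test_enrichment_factor_reproduces_published_values(tp, n, a, big_n, display):
    assert round_display(enrichment_factor(tp, n, a, big_n)) == display


def test_perfect_hitlist_reaches_the_ceiling():
    assert enrichment_factor(10, 10, 45, 240) == pytest.approx(240 / 45)


@pytest.mark.parametrize(
    "args",
    [(1, 0, 5, 10), (0, 1, 0, 10), (5, 4, 5, 10), (6, 10, 5, 10), (1, 1, 11, 10)],
)
def test_enrichment_factor_domain_errors(args):
    with pytest.raises(DomainError):
        enrichment_factor(*args)


@given(
    tp=st.integers(0, 50), n=st.integers(1, 100),
    a=st.integers(1, 100), big_n=st.integers(1, 500),
)
def test_ef_algebraic_identity_with_rationals(tp, n, a, big_n):
    """EF * (A/N) == TP/n exactly, checked in exact rational arithmetic."""
    if not (a <= big_n and n <= big_n and tp <= min(n, a)):
        return
    ef = Fraction(tp, n) / Fraction(a, big_n)
    assert ef * Fraction(a, big_n) == Fraction(tp, n)
    assert enrichment_factor(tp, n, a, big_n) == pytest.approx(float(ef), rel=1e-12)
    assert float(ef) <= big_n / a + 1e-12


@pytest.mark.parametrize(
    "a,big_n,display",
    [(45, 240, 5.3), (47, 240, 5.1), (240, 240, 1.0)],
)
def test_max_enrichment_ceiling(a, big_n, display):
    assert round_display(max_enrichment_factor(a, big_n)) == display


def test_max_enrichment_with_fixed_hitlist_size():
    # n below A: every hit can be active, ceiling is N/A scaled by min(n,A)/n = 1
    assert max_enrichment_factor(45, 240, n=10) == pytest.approx(240 / 45)
    # n above A: at most A true positives
    assert max_enrichment_factor(45, 240, n=90) == pytest.approx((45 / 90) * (240 / 45))
    with pytest.raises(DomainError):
        max_enrichment_factor(0, 240)


def _brute_force_auc(scores, flags):
    """Concordant-pair count with half-credit ties (independent oracle)."""
    pos = [s for s, f in zip(scores, flags) if f]
    neg = [s for s, f in zip(scores, flags) if not f]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_known_cases():
    # one concordant pair of two: (3 > 2) yes, (1 > 2) no
    assert roc_auc([3, 2, 1], [True, False, True]) == pytest.approx(0.5)
    # one concordant + one tied pair: (1 + 0.5) / 2
    assert roc_auc([3, 2, 2], [True, False, True]) == pytest.approx(0.75)
    assert roc_auc([5, 4, 1, 0], [True, True, False, False]) == 1.0
    assert roc_auc([1, 1, 1, 1], [True, False, True, False]) == 0.5


def test_auc_matches_brute_force_and_sklearn(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(20):
        n = int(rng.integers(4, 21))
        scores = rng.integers(0, 6, size=n).astype(float)  # many ties
        flags = rng.random(n) < 0.5
        if flags.all() or not flags.any():
            continue
        ours = roc_auc(scores, flags)
        assert ours == pytest.approx(_brute_force_auc(scores, flags), abs=1e-12)
        assert ours == pytest.approx(roc_auc_score(flags, scores), abs=1e-12)


def test_auc_complement_without_ties(rng):
    scores = rng.permutation(12).astype(float)
    flags = np.array([True] * 5 + [False] * 7)
    assert roc_auc(scores, flags) + roc_auc(-scores, flags) == pytest.approx(1.0)


def test_auc_single_class_rejected():
    with pytest.raises(DomainError):
        roc_auc([1.0, 2.0], [True, True])


def _result(scores, flags, method="pharm", target_class=None):
    ids = list(scores)
    return build_screening_result(
        method, scores, flags, {i: None for i in ids}, {}, target_class=target_class
    )


def _annot(labels):
    out = {}
    for cid, label in labels.items():
        out[cid] = ActivityRecord(cid, class_label=label)
    return out


def test_evaluate_ensemble_counts_and_recovery():
    scores = {"a1": 0.9, "a2": 0.8, "b1": 0.7, "i1": 0.0, "i2": 0.0}
    flags = {"a1": True, "a2": True, "b1": True, "i1": False, "i2": False}
    labels = {"a1": "agonist", "a2": "agonist", "b1": "antagonist",
              "i1": "inactive", "i2": "inactive"}
    vm = evaluate_model_ensemble(_result(scores, flags), _annot(labels), ["agonist"])
    assert (vm.TP, vm.n, vm.A, vm.N) == (2, 3, 2, 5)
    assert vm.EF == pytest.approx((2 / 3) / (2 / 5))
    assert vm.per_class_recovery == {"agonist": 1.0, "antagonist": 1.0, "inactive": 0.0}
    # counting both active classes changes TP and A
    vm2 = evaluate_model_ensemble(_result(scores, flags), _annot(labels),
                                  ["agonist", "antagonist"])
    assert (vm2.TP, vm2.A) == (3, 3)
    assert vm2.auc == 1.0  # all actives scored above all inactives


def test_evaluate_ensemble_requires_annotations_and_hits():
    scores = {"a": 1.0, "b": 0.0}
    flags = {"a": True, "b": False}
    with pytest.raises(DomainError, match="unannotated"):
        evaluate_model_ensemble(_result(scores, flags), {}, ["agonist"])
    annot = _annot({"a": "agonist", "b": "inactive"})
    with pytest.raises(DomainError):  # empty hitlist -> EF undefined
        evaluate_model_ensemble(
            _result(scores, {"a": False, "b": False}), annot, ["agonist"]
        )


def test_select_top_hits_and_shortfall():
    ag = _result(
        {f"c{i}": 1.0 - i / 10 for i in range(6)},
        {f"c{i}": True for i in range(6)},
        method="pharm", target_class="agonist",
    )
    ant = _result({"x": 0.9, "y": 0.1}, {"x": True, "y": False},
                  method="pharm", target_class="antagonist")
    sel = select_top_hits([ag, ant], {"agonist": 4, "antagonist": 2})
    assert sel.ids("pharm", "agonist") == ("c0", "c1", "c2", "c3")
    assert not sel.shortfall("pharm", "agonist")
    assert sel.ids("pharm", "antagonist") == ("x",)
    assert sel.shortfall("pharm", "antagonist")
    empty = select_top_hits([ag], {"agonist": 0})
    assert empty.ids("pharm", "agonist") == ()
    with pytest.raises(DomainError):
        select_top_hits([ag], {"agonist": -1})


def test_display_rounding_half_away_from_zero():
    assert round_display(4.35) == 4.4
    assert round_display(2.25) == 2.3
    assert round_display(5.333) == 5.3
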