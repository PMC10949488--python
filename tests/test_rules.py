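"""Subrule evaluation, rule combination, score aggregation, classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phagescore.rules import (
    And,
    Clause,
    Or,
    RuleConfigError,
    RuleSpec,
    ScoreConfig,
    SubruleSpec,
    ViralRuleClassifier,
    aggregate_score,
    apply_rule,
    default_config,
    default_rules,
    dump_config,
    evaluate_subrule,
    load_config,
    rule_contributions,
)

from conftest import make_row, make_table


def test_absent_feature_fails_condition():
    sub = SubruleSpec(
        "dvf_confident",
        And((Clause("dvf_score", ">=", 0.9), Clause("dvf_pvalue", "<", 0.05))),
        1.0,
        "confident",
    )
    assert evaluate_subrule(make_row(), sub) == 0.0


def test_high_confidence_negative_scores_minus_three():
    row = make_row(
        cv_viral_genes=0, cv_host_genes=8, kj_classified=True, kj_is_viral=False
    )
    tnv_cellular = default_rules()["tnv"].subrules[0]
    assert evaluate_subrule(row, tnv_cellular) == -3.0


def test_default_tier_magnitudes():
    """Low confidence = ±0.5, confident = ±1, highly-confident-negative = −3."""
    for rule in default_rules().values():
        for sub in rule.subrules:
            mag = {"low_confidence": 0.5, "confident": 1.0,
                   "high_confidence_negative": 3.0}[sub.tier]
            assert abs(sub.score) == mag


def test_two_feature_condition_matches_enumerated_truth_table():
    """Exhaustive oracle: AND over (dvf_score >= 0.9, dvf_pvalue < 0.05)
    across present/absent x satisfying/non-satisfying combinations."""
    cond = And((Clause("dvf_score", ">=", 0.9), Clause("dvf_pvalue", "<", 0.05)))
    score_vals = {np.nan: None, 0.95: True, 0.5: False}
    pval_vals = {np.nan: None, 0.01: True, 0.5: False}
    for s, p in itertools.product(score_vals, pval_vals):
        row = make_row(dvf_score=s, dvf_pvalue=p)
        expected = bool(score_vals[s]) and bool(pval_vals[p])
        assert cond.evaluate(row) is expected, (s, p)
        # vectorised path agrees with the scalar path
        table = make_table({"x": {"dvf_score": s, "dvf_pvalue": p}})
        assert bool(cond.mask(table).iloc[0]) is expected


def test_unknown_feature_rejected_at_config_time():
    with pytest.raises(RuleConfigError, match="no_such_feature"):
        Clause("no_such_feature", ">=", 1)


class TestApplyRule:
    def test_no_match_gives_zero(self):
        assert apply_rule(make_row(), default_rules()["vs2"]) == 0.0

    def test_max_positive_takes_best_confidence(self):
        # both the +1 hallmark subrule and the +0.5 low subrule match
        row = make_row(vs2_score=0.7, vs2_hallmark=2)
        assert apply_rule(row, default_rules()["vs2"]) == 1.0

    def test_sum_accumulates_negative_evidence(self):
        rule = RuleSpec(
            "tnv",
            (
                SubruleSpec("a", Clause("cv_host_genes", ">=", 2), -1.0, "confident"),
                SubruleSpec("b", Clause("kj_is_viral", "==", False), -3.0,
                            "high_confidence_negative"),
            ),
            "sum",
        )
        row = make_row(cv_host_genes=5, kj_is_viral=False)
        assert apply_rule(row, rule) == -4.0


class TestAggregate:
    def test_score_one_is_viral_inclusive(self):
        row = make_row(vs2_score=0.95)
        res = aggregate_score(row, default_config(), ["vs2", "tnv"], "s")
        assert res.viral_score == 1.0
        assert res.predicted_viral

    def test_two_halves_reach_threshold_but_one_does_not(self):
        row = make_row(dvf_score=0.8, dvf_pvalue=0.01, vs_category=3)
        both = aggregate_score(row, default_config(), ["dvf", "vs"])
        assert both.viral_score == 1.0 and both.predicted_viral
        alone = aggregate_score(row, default_config(), ["dvf"])
        assert alone.viral_score == 0.5 and not alone.predicted_viral

    def test_tuning_removal_outweighs_two_confident_calls(self):
        row = make_row(
            vs2_score=0.95, vb_quality="high",
            kj_classified=True, kj_is_viral=False, cv_viral_genes=0,
        )
        res = aggregate_score(row, default_config(), ["vs2", "vb", "tnv"])
        assert res.viral_score == -1.0
        assert not res.predicted_viral

    def test_empty_active_rules_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            aggregate_score(make_row(), default_config(), [])


# -- property tests ----------------------------------------------------------

maybe = lambda strat: st.one_of(st.just(np.nan), strat)  # noqa: E731

row_strategy = st.fixed_dictionaries(
    {
        "vs2_score": maybe(st.floats(0, 1)),
        "vs2_hallmark": maybe(st.integers(0, 10).map(float)),
        "vb_quality": st.sampled_from(["high", "medium", "low", "none"]),
        "vs_category": maybe(st.integers(1, 6).map(float)),
        "dvf_score": maybe(st.floats(0, 1)),
        "dvf_pvalue": maybe(st.floats(0, 1)),
        "cv_viral_genes": maybe(st.integers(0, 30).map(float)),
        "cv_host_genes": maybe(st.integers(0, 30).map(float)),
        "cv_completeness": maybe(st.floats(0, 100)),
        "cv_quality": st.sampled_from(
            [None, "complete", "high", "medium", "low", "not_determined"]
        ),
        "kj_classified": st.booleans(),
        "kj_is_viral": st.sampled_from([None, True, False]),
    }
)

rule_subset = st.sets(
    st.sampled_from(["vs2", "vb", "vs", "dvf", "tna", "tnv"]), min_size=1
)


@settings(max_examples=200, derandomize=True)
@given(features=row_strategy, active=rule_subset)
def test_aggregate_is_additive_over_rules(features, active):
    row = make_row(**features)
    config = default_config()
    res = aggregate_score(row, config, sorted(active))
    assert res.viral_score == pytest.approx(
        sum(apply_rule(row, config.rules[r]) for r in sorted(active))
    )
    assert res.viral_score == pytest.approx(sum(res.contributions.values()))
    assert res.predicted_viral == (res.viral_score >= config.viral_threshold)


@settings(max_examples=200, derandomize=True)
@given(features=row_strategy, active=rule_subset)
def test_tuning_rules_are_monotone(features, active):
    """Adding tna never lowers a score; adding tnv never raises it."""
    row = make_row(**features)
    config = default_config()
    base = aggregate_score(row, config, sorted(active)).viral_score
    with_tna = aggregate_score(row, config, sorted(active | {"tna"})).viral_score
    with_tnv = aggregate_score(row, config, sorted(active | {"tnv"})).viral_score
    assert with_tna >= base - 1e-12 or "tna" in active
    assert with_tnv <= base + 1e-12 or "tnv" in active
    if "tna" in active:
        assert with_tna == pytest.approx(base)
    if "tnv" in active:
        assert with_tnv == pytest.approx(base)


@settings(max_examples=200, derandomize=True)
@given(features=row_strategy)
def test_low_confidence_toggle_changes_score_by_halves(features):
    row = make_row(**features)
    active = ["vs2", "vb", "vs", "dvf", "tna", "tnv"]
    with_low = aggregate_score(row, default_config(), active).viral_score
    without = aggregate_score(
        row, default_config(include_low_confidence=False), active
    ).viral_score
    delta = with_low - without
    assert abs(delta / 0.5 - round(delta / 0.5)) < 1e-9


@settings(max_examples=100, derandomize=True)
@given(features=st.lists(row_strategy, min_size=1, max_size=8))
def test_vectorised_contributions_match_rowwise(features):
    table = make_table({f"s{i}": f for i, f in enumerate(features)})
    config = default_config()
    contrib = rule_contributions(table, config)
    for i, f in enumerate(features):
        row = make_row(**f)
        for rid, rule in config.rules.items():
            assert contrib.at[f"s{i}", rid] == pytest.approx(apply_rule(row, rule))


# -- config validation and round-trip ---------------------------------------


def test_rule_needs_two_subrules():
    with pytest.raises(RuleConfigError, match=">= 2"):
        RuleSpec("vs2", (default_rules()["vs2"].subrules[0],), "max_positive")


def test_tna_must_be_positive_tnv_negative():
    pos = SubruleSpec("p", Clause("kj_is_viral", "==", True), 0.5, "low_confidence")
    neg = SubruleSpec("n", Clause("cv_host_genes", ">=", 2), -1.0, "confident")
    with pytest.raises(RuleConfigError, match="tna"):
        RuleSpec("tna", (pos, neg), "sum")
    with pytest.raises(RuleConfigError, match="tnv"):
        RuleSpec("tnv", (neg, pos), "sum")


def test_config_yaml_round_trip(tmp_path):
    path = tmp_path / "rules.yaml"
    dump_config(default_config(), path)
    loaded = load_config(path)
    assert set(loaded.rules) == set(default_rules())
    # behavior-identical on a probe row
    row = make_row(vs2_score=0.95, vs2_hallmark=3, vb_quality="low",
                   cv_host_genes=4, cv_viral_genes=0,
                   kj_classified=True, kj_is_viral=False)
    for rid in loaded.rules:
        assert apply_rule(row, loaded.rules[rid]) == apply_rule(
            row, default_rules()[rid]
        )


# -- sklearn estimator surface ----------------------------------------------


class TestViralRuleClassifier:
    def test_params_round_trip_through_clone(self):
        from sklearn.base import clone

        clf = ViralRuleClassifier(active_rules=("vs2", "tnv"), threshold=2.0)
        cloned = clone(clf)
        assert cloned.get_params()["threshold"] == 2.0
        assert cloned.get_params()["active_rules"] == ("vs2", "tnv")

    def test_predict_matches_aggregate(self):
        table = make_table(
            {
                "v": {"vs2_score": 0.95, "vs2_hallmark": 3},
                "n": {"kj_classified": True, "kj_is_viral": False,
                      "cv_viral_genes": 0.0, "cv_host_genes": 6.0},
            }
        )
        clf = ViralRuleClassifier().fit(table)
        preds = clf.predict(table)
        config = default_config()
        for sid, pred in zip(table.index, preds):
            expected = aggregate_score(
                dict(table.loc[sid]), config, clf.active_rules_
            ).predicted_viral
            assert pred == expected

    def test_threshold_is_monotone_in_score(self):
        table = make_table(
            {
                "a": {"dvf_score": 0.8, "dvf_pvalue": 0.01},  # 0.5
                "b": {"vs2_score": 0.95},  # 1.0
                "c": {"vs2_score": 0.95, "vb_quality": "high"},  # 2.0
            }
        )
        clf = ViralRuleClassifier().fit(table)
        scores = clf.decision_function(table)
        preds = clf.predict(table)
        order = scores.sort_values().index
        sorted_preds = [bool(preds[list(table.index).index(s)]) for s in order]
        assert sorted_preds == sorted(sorted_preds)  # False before True

    def test_unfitted_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            ViralRuleClassifier().predict(make_table({"a": {}}))

    def test_unknown_active_rule_rejected_at_fit(self):
        with pytest.raises(ValueError, match="bogus"):
            ViralRuleClassifier(active_rules=("bogus",)).fit()
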