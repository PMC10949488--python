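"""Rule-based viral scoring.

Each sequence receives a *viral score*: the sum, over the active rules, of
that rule's contribution.  A rule is a named bundle of *subrules*; a subrule
is a declarative condition over feature-table columns together with a score
contribution whose magnitude encodes confidence:

* low-confidence evidence contributes ``±0.5``,
* confident evidence contributes ``±1``,
* a highly confident non-viral signal contributes ``−3``.

Four rules wrap a single tool's output (``vs2``, ``vb``, ``vs``, ``dvf``);
two *tuning* rules aggregate cross-tool evidence: tuning addition (``tna``)
raises the score on distinctly viral features (CheckV completeness, Kaiju
viral taxonomy, VirSorter2 hallmark genes), tuning removal (``tnv``) lowers
it on distinctly non-viral features (cellular taxonomy with no viral genes,
host-gene excess, no tool signal at all).

Sequences with a final score ``>= threshold`` (default 1, inclusive) are
predicted viral.

A comparison whose feature is absent (NaN) evaluates false, so missing tool
output can never satisfy a condition.  Single-tool rules combine their
subrules with ``max_positive`` (one tool contributes its single best
confidence level); tuning rules combine with ``sum`` so independent pieces
of evidence accumulate.

The default subrule set ships as data (:func:`default_rules`) and is fully
overridable from a YAML config (:func:`load_config`); the cutoffs follow the
tool developers' published recommendations and are reconstructions, not an
authoritative transcription of any particular pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin

from .features import FEATURES

RULE_IDS = ("vs2", "vb", "vs", "dvf", "tna", "tnv")

TIERS = ("low_confidence", "confident", "high_confidence_negative")

#: default score magnitude per tier
TIER_SCORES = {"low_confidence": 0.5, "confident": 1.0, "high_confidence_negative": 3.0}


class RuleConfigError(ValueError):
    """Invalid rule configuration (unknown feature, bad operator, bad tier)."""


# ---------------------------------------------------------------------------
# condition mini-language
# ---------------------------------------------------------------------------

_COMPARATORS = {
    "==": lambda s, v: s == v,
    "!=": lambda s, v: (s != v) & s.notna(),
    "<": lambda s, v: s < v,
    "<=": lambda s, v: s <= v,
    ">": lambda s, v: s > v,
    ">=": lambda s, v: s >= v,
    "in": lambda s, v: s.isin(list(v)),
}


@dataclass(frozen=True)
class Clause:
    """``feature <op> value`` over one feature-table column.

    ``op`` is one of ``== != < <= > >= in absent present``; ``absent`` and
    ``present`` take no value.  A comparison on an absent (NaN) feature is
    false; only ``absent`` matches missing values.
    """

    feature: str
    op: str
    value: object = None

    def __post_init__(self) -> None:
        if self.feature not in FEATURES:
            raise RuleConfigError(f"unknown feature {self.feature!r}")
        if self.op not in _COMPARATORS and self.op not in ("absent", "present"):
            raise RuleConfigError(f"unknown comparator {self.op!r}")

    def mask(self, table: pd.DataFrame) -> pd.Series:
        col = table[self.feature]
        if self.op == "absent":
            return col.isna()
        if self.op == "present":
            return col.notna()
        with np.errstate(invalid="ignore"):
            out = _COMPARATORS[self.op](col, self.value)
        return out.fillna(False).astype(bool) & col.notna()

    def evaluate(self, row: Mapping[str, object]) -> bool:
        value = row.get(self.feature) if hasattr(row, "get") else row[self.feature]
        missing = value is None or (isinstance(value, float) and np.isnan(value))
        if self.op == "absent":
            return missing
        if self.op == "present":
            return not missing
        if missing:
            return False
        if self.op == "==":
            return bool(value == self.value)
        if self.op == "!=":
            return bool(value != self.value)
        if self.op == "in":
            return value in list(self.value)
        if self.op == "<":
            return bool(value < self.value)
        if self.op == "<=":
            return bool(value <= self.value)
        if self.op == ">":
            return bool(value > self.value)
        return bool(value >= self.value)


@dataclass(frozen=True)
class And:
    clauses: tuple

    def mask(self, table: pd.DataFrame) -> pd.Series:
        out = pd.Series(True, index=table.index)
        for c in self.clauses:
            out &= c.mask(table)
        return out

    def evaluate(self, row: Mapping[str, object]) -> bool:
        return all(c.evaluate(row) for c in self.clauses)


@dataclass(frozen=True)
class Or:
    clauses: tuple

    def mask(self, table: pd.DataFrame) -> pd.Series:
        out = pd.Series(False, index=table.index)
        for c in self.clauses:
            out |= c.mask(table)
        return out

    def evaluate(self, row: Mapping[str, object]) -> bool:
        return any(c.evaluate(row) for c in self.clauses)


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubruleSpec:
    """One condition -> score-contribution clause within a rule."""

    name: str
    condition: object  # Clause | And | Or
    score: float
    tier: str

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise RuleConfigError(f"unknown tier {self.tier!r} in subrule {self.name}")
        # tier/score consistency is enforced only for the default magnitudes;
        # any other real score is permitted by config.
        mag = abs(self.score)
        if mag in (0.5, 1.0, 3.0):
            expected = TIER_SCORES[self.tier]
            if mag != expected:
                raise RuleConfigError(
                    f"subrule {self.name}: tier {self.tier} implies |score| = "
                    f"{expected}, got {self.score}"
                )
        if self.tier == "high_confidence_negative" and self.score > 0:
            raise RuleConfigError(
                f"subrule {self.name}: high_confidence_negative must be negative"
            )


@dataclass(frozen=True)
class RuleSpec:
    """A named rule: at least two subrules plus a combination mode."""

    rule_id: str
    subrules: tuple
    combine: str  # max_positive | sum

    def __post_init__(self) -> None:
        if len(self.subrules) < 2:
            raise RuleConfigError(f"rule {self.rule_id}: needs >= 2 subrules")
        if self.combine not in ("max_positive", "sum"):
            raise RuleConfigError(f"rule {self.rule_id}: bad combine {self.combine!r}")
        if self.rule_id == "tna" and any(s.score <= 0 for s in self.subrules):
            raise RuleConfigError("tna subrules must all have score > 0")
        if self.rule_id == "tnv" and any(s.score >= 0 for s in self.subrules):
            raise RuleConfigError("tnv subrules must all have score < 0")


@dataclass(frozen=True)
class ScoreConfig:
    """Complete scoring configuration: the six rules plus global knobs."""

    rules: Mapping[str, RuleSpec]
    viral_threshold: float = 1.0
    include_low_confidence: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.viral_threshold):
            raise RuleConfigError("viral_threshold must be finite")

    def effective_rules(self) -> dict[str, RuleSpec]:
        """Rules after the low-confidence toggle is applied."""
        if self.include_low_confidence:
            return dict(self.rules)
        out = {}
        for rid, rule in self.rules.items():
            kept = tuple(s for s in rule.subrules if s.tier != "low_confidence")
            if len(kept) >= 2:
                out[rid] = replace(rule, subrules=kept)
            elif kept:
                # bypass the >=2 invariant check: the rule as configured had
                # >=2 subrules; the toggle merely deactivates a tier
                thinned = replace(rule, subrules=rule.subrules)
                object.__setattr__(thinned, "subrules", kept)
                out[rid] = thinned
        return out


# ---------------------------------------------------------------------------
# default configuration
# ---------------------------------------------------------------------------


def default_rules() -> dict[str, RuleSpec]:
    """The shipped subrule set (developer-recommended cutoffs)."""
    c = Clause
    vs2 = RuleSpec(
        "vs2",
        (
            SubruleSpec("vs2_confident", c("vs2_score", ">=", 0.9), 1.0, "confident"),
            SubruleSpec(
                "vs2_low",
                And((c("vs2_score", ">=", 0.5), c("vs2_score", "<", 0.9))),
                0.5,
                "low_confidence",
            ),
            SubruleSpec(
                "vs2_hallmark",
                And((c("vs2_hallmark", ">=", 1), c("vs2_score", ">=", 0.5))),
                1.0,
                "confident",
            ),
        ),
        "max_positive",
    )
    vb = RuleSpec(
        "vb",
        (
            SubruleSpec(
                "vb_confident", c("vb_quality", "in", ("high", "medium")), 1.0, "confident"
            ),
            SubruleSpec("vb_low", c("vb_quality", "==", "low"), 0.5, "low_confidence"),
        ),
        "max_positive",
    )
    vs = RuleSpec(
        "vs",
        (
            SubruleSpec("vs_confident", c("vs_category", "in", (1, 2)), 1.0, "confident"),
            SubruleSpec("vs_low", c("vs_category", "==", 3), 0.5, "low_confidence"),
        ),
        "max_positive",
    )
    dvf = RuleSpec(
        "dvf",
        (
            SubruleSpec(
                "dvf_confident",
                And((c("dvf_score", ">=", 0.9), c("dvf_pvalue", "<", 0.05))),
                1.0,
                "confident",
            ),
            SubruleSpec(
                "dvf_low",
                And(
                    (
                        c("dvf_score", ">=", 0.7),
                        c("dvf_score", "<", 0.9),
                        c("dvf_pvalue", "<", 0.05),
                    )
                ),
                0.5,
                "low_confidence",
            ),
        ),
        "max_positive",
    )
    tna = RuleSpec(
        "tna",
        (
            SubruleSpec(
                "tna_checkv",
                Or(
                    (
                        c("cv_quality", "in", ("complete", "high", "medium")),
                        c("cv_completeness", ">=", 50),
                    )
                ),
                1.0,
                "confident",
            ),
            SubruleSpec("tna_kaiju", c("kj_is_viral", "==", True), 0.5, "low_confidence"),
            SubruleSpec("tna_hallmark", c("vs2_hallmark", ">=", 2), 1.0, "confident"),
        ),
        "sum",
    )
    tnv = RuleSpec(
        "tnv",
        (
            SubruleSpec(
                "tnv_cellular",
                And(
                    (
                        c("kj_classified", "==", True),
                        c("kj_is_viral", "==", False),
                        c("cv_viral_genes", "==", 0),
                    )
                ),
                -3.0,
                "high_confidence_negative",
            ),
            SubruleSpec(
                "tnv_host_genes",
                And((c("cv_host_genes", ">=", 2), c("cv_viral_genes", "<=", 1))),
                -1.0,
                "confident",
            ),
            SubruleSpec(
                "tnv_no_signal",
                And(
                    (
                        Or((c("vs2_score", "<", 0.5), c("vs2_score", "absent"))),
                        c("vb_quality", "==", "none"),
                        c("vs_category", "absent"),
                    )
                ),
                -0.5,
                "low_confidence",
            ),
        ),
        "sum",
    )
    return {"vs2": vs2, "vb": vb, "vs": vs, "dvf": dvf, "tna": tna, "tnv": tnv}


def default_config(
    viral_threshold: float = 1.0, include_low_confidence: bool = True
) -> ScoreConfig:
    return ScoreConfig(default_rules(), viral_threshold, include_low_confidence)


# ---------------------------------------------------------------------------
# YAML config round-trip
# ---------------------------------------------------------------------------


def _condition_from_obj(obj) -> Clause | And | Or:
    if isinstance(obj, dict):
        if set(obj) == {"all"}:
            return And(tuple(_condition_from_obj(o) for o in obj["all"]))
        if set(obj) == {"any"}:
            return Or(tuple(_condition_from_obj(o) for o in obj["any"]))
        raise RuleConfigError(f"condition dict must have a single 'all' or 'any' key: {obj}")
    if isinstance(obj, (list, tuple)):
        if len(obj) == 2:
            return Clause(obj[0], obj[1])
        if len(obj) == 3:
            value = tuple(obj[2]) if isinstance(obj[2], list) else obj[2]
            return Clause(obj[0], obj[1], value)
    raise RuleConfigError(f"cannot parse condition {obj!r}")


def _condition_to_obj(cond) -> object:
    if isinstance(cond, And):
        return {"all": [_condition_to_obj(c) for c in cond.clauses]}
    if isinstance(cond, Or):
        return {"any": [_condition_to_obj(c) for c in cond.clauses]}
    if cond.op in ("absent", "present"):
        return [cond.feature, cond.op]
    value = list(cond.value) if isinstance(cond.value, tuple) else cond.value
    return [cond.feature, cond.op, value]


def load_config(path: str | Path) -> ScoreConfig:
    """Load a scoring configuration from YAML (see ``dump_config`` schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rules = {}
    for rid, robj in raw["rules"].items():
        subrules = tuple(
            SubruleSpec(
                s["name"],
                _condition_from_obj(s["when"]),
                float(s["score"]),
                s["tier"],
            )
            for s in robj["subrules"]
        )
        default_combine = "sum" if rid in ("tna", "tnv") else "max_positive"
        rules[rid] = RuleSpec(rid, subrules, robj.get("combine", default_combine))
    return ScoreConfig(
        rules,
        float(raw.get("threshold", 1.0)),
        bool(raw.get("include_low_confidence", True)),
    )


def dump_config(config: ScoreConfig, path: str | Path) -> None:
    """Write a configuration to YAML in the schema ``load_config`` reads."""
    raw = {
        "threshold": config.viral_threshold,
        "include_low_confidence": config.include_low_confidence,
        "rules": {
            rid: {
                "combine": rule.combine,
                "subrules": [
                    {
                        "name": s.name,
                        "score": s.score,
                        "tier": s.tier,
                        "when": _condition_to_obj(s.condition),
                    }
                    for s in rule.subrules
                ],
            }
            for rid, rule in config.rules.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate_subrule(row: Mapping[str, object], subrule: SubruleSpec) -> float:
    """The subrule's score if its condition holds on this row, else 0."""
    return subrule.score if subrule.condition.evaluate(row) else 0.0


def apply_rule(row: Mapping[str, object], rule: RuleSpec) -> float:
    """One rule's contribution for one row.

    ``max_positive``: the best matched confidence level (0 if none match);
    ``sum``: all matched subrule scores accumulate.
    """
    matched = [s.score for s in rule.subrules if s.condition.evaluate(row)]
    if not matched:
        return 0.0
    return max(matched) if rule.combine == "max_positive" else sum(matched)


def rule_contributions(table: pd.DataFrame, config: ScoreConfig) -> pd.DataFrame:
    """Vectorised per-rule contributions: one column per rule id."""
    rules = config.effective_rules()
    out = pd.DataFrame(index=table.index)
    for rid, rule in rules.items():
        masks = [(s.condition.mask(table), s.score) for s in rule.subrules]
        if rule.combine == "sum":
            contrib = pd.Series(0.0, index=table.index)
            for mask, score in masks:
                contrib += mask * score
        else:
            stacked = pd.concat(
                [mask.map({True: score, False: np.nan}) for mask, score in masks],
                axis=1,
            )
            contrib = stacked.max(axis=1).fillna(0.0)
        out[rid] = contrib
    return out


@dataclass(frozen=True)
class ViralScoreResult:
    """Per-sequence outcome: rule contributions, total score, prediction."""

    seq_id: str
    contributions: Mapping[str, float]
    viral_score: float
    predicted_viral: bool


def aggregate_score(
    row: Mapping[str, object],
    config: ScoreConfig,
    active_rules: Iterable[str],
    seq_id: str = "",
) -> ViralScoreResult:
    """Viral score for one row: sum of the active rules' contributions."""
    active = list(active_rules)
    if not active:
        raise ValueError("active_rules must be non-empty (63 = non-empty subsets)")
    rules = config.effective_rules()
    unknown = set(active) - set(rules)
    if unknown:
        raise ValueError(f"unknown rule id(s) {sorted(unknown)}")
    contributions = {rid: apply_rule(row, rules[rid]) for rid in active}
    score = sum(contributions.values())
    return ViralScoreResult(
        seq_id, contributions, score, score >= config.viral_threshold
    )


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------


class ViralRuleClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based viral/non-viral classifier over a feature table.

    A scikit-learn-compatible wrapper around the viral-score aggregation:
    ``decision_function`` returns per-sequence viral scores and ``predict``
    thresholds them (``score >= threshold`` -> viral).  No parameters are
    learned from data; ``fit`` validates the configuration.

    Parameters
    ----------
    rules:
        Mapping rule_id -> :class:`RuleSpec`; ``None`` uses the shipped
        defaults.
    active_rules:
        The ruleset to apply (non-empty subset of the configured rule ids);
        ``None`` activates all configured rules.
    threshold:
        Inclusive viral-score cutoff (default 1.0).
    include_low_confidence:
        If False, ``low_confidence`` (±0.5) subrules are removed before
        evaluation.

    Examples
    --------
    >>> clf = ViralRuleClassifier(active_rules=("vs2", "tnv")).fit()
    >>> scores = clf.decision_function(feature_table)   # doctest: +SKIP
    """

    def __init__(
        self,
        rules: Mapping[str, RuleSpec] | None = None,
        active_rules: Sequence[str] | None = None,
        threshold: float = 1.0,
        include_low_confidence: bool = True,
    ):
        self.rules = rules
        self.active_rules = active_rules
        self.threshold = threshold
        self.include_low_confidence = include_low_confidence

    def _config(self) -> ScoreConfig:
        rules = default_rules() if self.rules is None else dict(self.rules)
        return ScoreConfig(rules, self.threshold, self.include_low_confidence)

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "ViralRuleClassifier":
        """Validate the configuration; nothing is estimated from ``X``."""
        config = self._config()
        active = (
            tuple(config.rules) if self.active_rules is None else tuple(self.active_rules)
        )
        if not active:
            raise ValueError("active_rules must be non-empty")
        unknown = set(active) - set(config.rules)
        if unknown:
            raise ValueError(f"unknown rule id(s) {sorted(unknown)}")
        self.config_ = config
        self.active_rules_ = active
        self.classes_ = np.array([False, True])
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "config_"):
            raise RuntimeError("ViralRuleClassifier is not fitted; call fit() first")

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-rule contributions for the active rules (one column each)."""
        self._check_fitted()
        contrib = rule_contributions(X, self.config_)
        return contrib[[r for r in self.active_rules_ if r in contrib.columns]]

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        """Viral score per sequence (sum of active-rule contributions)."""
        return self.transform(X).sum(axis=1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Boolean viral calls: ``viral_score >= threshold``."""
        scores = self.decision_function(X)
        return (scores >= self.config_.viral_threshold).to_numpy()

    def score_table(self, X: pd.DataFrame) -> pd.DataFrame:
        """Long-form results: contributions, viral_score, predicted_viral."""
        contrib = self.transform(X)
        out = contrib.copy()
        out["viral_score"] = contrib.sum(axis=1)
        out["predicted_viral"] = out["viral_score"] >= self.config_.viral_threshold
        return out
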