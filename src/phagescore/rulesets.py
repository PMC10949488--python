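"""Ruleset enumeration, per-ruleset prediction, and prediction overlap.

A *ruleset* is a non-empty subset of the six rules applied jointly; six
rules yield ``2**6 - 1 = 63`` rulesets.  Overlap between two rulesets'
viral calls is the Jaccard index: the intersection (called viral by both)
divided by the union (called viral by at least one).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .rules import RULE_IDS, ScoreConfig, ViralScoreResult, rule_contributions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ruleset:
    """A non-empty, duplicate-free subset of rule ids."""

    rule_ids: tuple

    def __post_init__(self) -> None:
        if not self.rule_ids:
            raise ValueError("a ruleset must contain at least one rule")
        if len(set(self.rule_ids)) != len(self.rule_ids):
            raise ValueError(f"duplicate rule ids in {self.rule_ids}")
        object.__setattr__(self, "rule_ids", tuple(sorted(self.rule_ids)))

    @property
    def label(self) -> str:
        return "+".join(self.rule_ids)

    def __len__(self) -> int:
        return len(self.rule_ids)


def enumerate_rulesets(rule_ids: Iterable[str] = RULE_IDS) -> list[Ruleset]:
    """All non-empty subsets, ordered by size then label (deterministic).

    Six rules give the full complement of 63 rulesets.
    """
    ids = sorted(set(rule_ids))
    if not ids:
        raise ValueError("rule_ids must be non-empty")
    if len(ids) > 16:
        raise ValueError("refusing to enumerate subsets of more than 16 rules")
    out: list[Ruleset] = []
    for k in range(1, len(ids) + 1):
        sized = [Ruleset(tuple(c)) for c in combinations(ids, k)]
        out.extend(sorted(sized, key=lambda r: r.label))
    return out


def predict_ruleset(
    features: pd.DataFrame, config: ScoreConfig, ruleset: Ruleset
) -> dict[str, ViralScoreResult]:
    """Score every sequence under one ruleset."""
    if features.empty:
        raise ValueError("feature table is empty")
    contrib = rule_contributions(features, config)
    active = [r for r in ruleset.rule_ids if r in contrib.columns]
    scores = contrib[active].sum(axis=1)
    out = {}
    for sid in features.index:
        score = float(scores.at[sid])
        out[sid] = ViralScoreResult(
            sid,
            {rid: float(contrib.at[sid, rid]) for rid in active},
            score,
            score >= config.viral_threshold,
        )
    return out


def predictions_table(
    features: pd.DataFrame, config: ScoreConfig, rulesets: Iterable[Ruleset]
) -> pd.DataFrame:
    """Long-format predictions: (ruleset, seq_id, viral_score, predicted_viral).

    Per-rule contributions are computed once and reused across rulesets, so
    scoring all 63 rulesets costs little more than scoring one.
    """
    contrib = rule_contributions(features, config)
    frames = []
    for rs in rulesets:
        active = [r for r in rs.rule_ids if r in contrib.columns]
        scores = contrib[active].sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "ruleset": rs.label,
                    "seq_id": features.index,
                    "viral_score": scores.to_numpy(),
                    "predicted_viral": (scores >= config.viral_threshold).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def overlap(viral_a: set, viral_b: set) -> float:
    """Jaccard overlap of two viral-call sets; both empty is defined as 1.0."""
    a, b = set(viral_a), set(viral_b)
    union = a | b
    if not union:
        logger.info("overlap of two empty prediction sets; defined as 1.0")
        return 1.0
    return len(a & b) / len(union)


def overlap_matrix(
    predictions: Mapping[str, set],
) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise overlap between rulesets' viral-call sets.

    Returns the symmetric, unit-diagonal matrix plus the per-ruleset viral
    counts (the total number of viruses identified by each combination).
    """
    labels = list(predictions)
    if len(labels) < 2:
        raise ValueError("need at least 2 rulesets for an overlap matrix")
    n = len(labels)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = overlap(predictions[labels[i]], predictions[labels[j]])
    matrix = pd.DataFrame(mat, index=labels, columns=labels)
    counts = pd.Series({lab: len(predictions[lab]) for lab in labels}, name="n_viral")
    return matrix, counts


def overlap_summary(matrix: pd.DataFrame, high: float = 0.9, moderate: float = 0.5) -> dict:
    """Headline overlap statistics on an overlap matrix.

    Fraction of off-diagonal pairs above ``moderate`` overlap, and how many
    rulesets are near-identical (>= ``high``) to at least one other ruleset.
    """
    vals = matrix.to_numpy()
    n = vals.shape[0]
    off = vals[~np.eye(n, dtype=bool)]
    near = (vals >= high) & ~np.eye(n, dtype=bool)
    return {
        "fraction_above_moderate": float((off > moderate).mean()),
        "n_rulesets_with_high_overlap": int(near.any(axis=1).sum()),
    }
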