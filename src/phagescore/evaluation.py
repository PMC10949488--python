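"""Benchmark rulesets against ground truth.

Per (ruleset, replicate): confusion counts, precision, recall, and Matthews
correlation coefficient (MCC).  MCC uses all four confusion-matrix cells,

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

making it robust to the strong class imbalance of environmental metagenomes
(roughly one sequence in ten is viral).  Rulesets statistically equivalent
to the best one per metric form the "high MCC" / "high precision" /
"high recall" groups.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rules import ScoreConfig, rule_contributions
from .rulesets import Ruleset

logger = logging.getLogger(__name__)

METRICS = ("mcc", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(predictions: Mapping[str, bool], labels: pd.DataFrame) -> ConfusionCounts:
    """Tally TP/FP/TN/FN for boolean viral calls against a label table."""
    missing = [sid for sid in predictions if sid not in labels.index]
    if missing:
        raise KeyError(f"unlabeled seq_id(s): {sorted(missing)[:10]}")
    tp = fp = tn = fn = 0
    for sid, called in predictions.items():
        truth = bool(labels.at[sid, "is_virus"])
        if called and truth:
            tp += 1
        elif called and not truth:
            fp += 1
        elif not called and truth:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn)


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, mcc) with zero-denominator conventions.

    Precision with no positive calls is 0; MCC with any zero factor in the
    denominator is 0.  Both keep degenerate rulesets finite and comparable.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return precision, recall, mcc


def evaluate_all(
    features_per_replicate: Sequence[pd.DataFrame],
    labels_per_replicate: Sequence[pd.DataFrame],
    config: ScoreConfig,
    rulesets: Iterable[Ruleset],
) -> pd.DataFrame:
    """One metric row per (ruleset, replicate).

    Returns a DataFrame with columns (ruleset, n_rules, replicate, tp, fp,
    tn, fn, precision, recall, mcc, degenerate).  A replicate with zero true
    viruses yields degenerate rows (excluded from grouping downstream).
    """
    if len(features_per_replicate) != len(labels_per_replicate):
        raise ValueError("features and labels must have the same number of replicates")
    if not features_per_replicate:
        raise ValueError("need at least one replicate")
    rulesets = list(rulesets)
    rows = []
    for rep, (features, labels) in enumerate(
        zip(features_per_replicate, labels_per_replicate)
    ):
        degenerate = not labels["is_virus"].any()
        if degenerate:
            warnings.warn(f"replicate {rep} has zero true viruses; rows flagged degenerate")
        contrib = rule_contributions(features, config)
        truth = labels.loc[features.index, "is_virus"].to_numpy(dtype=bool)
        for rs in rulesets:
            active = [r for r in rs.rule_ids if r in contrib.columns]
            called = (contrib[active].sum(axis=1) >= config.viral_threshold).to_numpy()
            tp = int(np.sum(called & truth))
            fp = int(np.sum(called & ~truth))
            fn = int(np.sum(~called & truth))
            tn = int(np.sum(~called & ~truth))
            precision, recall, mcc = metrics(ConfusionCounts(tp, fp, tn, fn))
            rows.append(
                {
                    "ruleset": rs.label,
                    "n_rules": len(rs),
                    "replicate": rep,
                    "tp": tp,
                    "fp": fp,
                    "tn": tn,
                    "fn": fn,
                    "precision": precision,
                    "recall": recall,
                    "mcc": mcc,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def mean_metrics(rows: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-ruleset means across non-degenerate replicates."""
    ok = rows[~rows["degenerate"]]
    return ok.groupby("ruleset", sort=True)[list(METRICS)].mean()


def _paired_pvalue(top: np.ndarray, other: np.ndarray, test: str) -> float:
    """One-sided p-value that ``other`` is lower than ``top`` across replicates."""
    diff = other - top
    if np.allclose(diff, 0):
        return 1.0  # identical metrics: no evidence of a decrease
    if test == "wilcoxon":
        return float(stats.wilcoxon(other, top, alternative="less").pvalue)
    if test == "ttest":
        return float(stats.ttest_rel(other, top, alternative="less").pvalue)
    raise ValueError(f"unknown test {test!r}")


def top_groups(
    rows: pd.DataFrame, alpha: float = 0.05, test: str = "wilcoxon"
) -> pd.DataFrame:
    """Identify rulesets statistically equivalent to the best per metric.

    For each metric the rulesets are ranked by mean across replicates; every
    ruleset is tested (paired, one-sided) for a decrease relative to the top
    one, p-values are Benjamini-Hochberg adjusted across rulesets, and the
    "high" group contains the top ruleset plus all with p_adj >= alpha.

    With a single replicate (or degenerate data) the grouping falls back to
    rank only: each metric's top ruleset alone forms the high group.

    Returns a long DataFrame (ruleset, metric, mean, p_adj, group) where
    ``group`` is high_mcc / high_precision / high_recall / other.
    """
    ok = rows[~rows["degenerate"]]
    if ok.empty:
        raise ValueError("no non-degenerate replicates to group")
    n_reps = ok.groupby("ruleset")["replicate"].nunique()
    rank_only = int(n_reps.min()) < 2
    if rank_only:
        warnings.warn("fewer than 2 replicates; grouping degraded to rank only")
    out = []
    for metric in METRICS:
        wide = ok.pivot_table(index="replicate", columns="ruleset", values=metric)
        means = wide.mean(axis=0)
        top_label = means.idxmax()
        others = [lab for lab in means.index if lab != top_label]
        if rank_only or not others:
            pvals = pd.Series(np.nan, index=others)
            padj = pvals
        else:
            top_vals = wide[top_label].to_numpy()
            pvals = pd.Series(
                [_paired_pvalue(top_vals, wide[lab].to_numpy(), test) for lab in others],
                index=others,
            )
            padj = pd.Series(
                multipletests(pvals.to_numpy(), method="fdr_bh")[1], index=others
            )
        for lab in means.index:
            if lab == top_label:
                in_group, p = True, np.nan
            elif rank_only:
                in_group, p = False, np.nan
            else:
                p = float(padj[lab])
                in_group = p >= alpha
            out.append(
                {
                    "ruleset": lab,
                    "metric": metric,
                    "mean": float(means[lab]),
                    "p_adj": p,
                    "group": f"high_{metric}" if in_group else "other",
                }
            )
    return pd.DataFrame(out)


def proportion_viral(predictions: Mapping[str, bool]) -> float:
    """Fraction of sequences called viral in one dataset."""
    if not predictions:
        raise ValueError("empty prediction set")
    return sum(bool(v) for v in predictions.values()) / len(predictions)


def vog_fraction(
    features: pd.DataFrame, labels: pd.DataFrame, viral_calls: set
) -> pd.DataFrame:
    """Per-sequence VOG-annotation fraction, grouped by true class.

    Restricted to sequences called viral (VIBRANT is the only tool that
    reports VOG annotations, so only its viral calls carry gene counts).
    Returns (seq_id, true_class, vog_count, total_genes, vog_proportion).
    """
    rows = []
    for sid in sorted(viral_calls):
        if sid not in features.index:
            continue
        total = features.at[sid, "vb_total_genes"]
        vogs = features.at[sid, "vb_vog_genes"]
        if pd.isna(total) or pd.isna(vogs):
            continue
        if total == 0:
            warnings.warn(f"{sid}: vb_total_genes is 0; skipped")
            continue
        rows.append(
            {
                "seq_id": sid,
                "true_class": labels.at[sid, "true_class"],
                "vog_count": int(vogs),
                "total_genes": int(total),
                "vog_proportion": float(vogs) / float(total),
            }
        )
    return pd.DataFrame(
        rows, columns=["seq_id", "true_class", "vog_count", "total_genes", "vog_proportion"]
    )
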