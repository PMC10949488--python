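"""Simulated tool outputs for a labeled sequence set.

Real runs of the six viral-identification tools require large databases and
hours of compute.  This module fakes their *output files* instead: given a
label table and per-tool error profiles (sensitivity, specificity,
low-confidence rate, dropout), it writes files in the exact dialects the
parsers read, with feature values drawn from the regions that satisfy (or
fail) the default subrule conditions.

The simulation is per sequence, per tool:

* with probability ``dropout`` the tool omits the sequence entirely;
* a true virus receives a positive signal with probability ``sensitivity``;
  a non-virus receives one with probability ``1 - specificity``;
* a positive signal is demoted to the low-confidence tier with probability
  ``low_confidence_rate``;
* negatives draw values satisfying no positive subrule; CheckV and Kaiju
  negatives additionally look distinctly cellular (host genes, cellular
  lineage), which is what the tuning-removal rule keys on.

VIBRANT and VirSorter only list sequences they consider phage, so for those
two dialects a negative and a dropout both surface as an absent row.

An optional shared latent "detectability" per sequence correlates the
tools' errors, emulating the observation that tools agree most on easy
viruses.  Feature values for positives are drawn uniformly from the region
satisfying the *default* subrule cutoffs; fixtures must be regenerated if a
custom config tightens those thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .features import TOOLS
from .mockmeta import CompositionSpec, MockMetagenome, build_mock, default_pools

#: Kaiju lineage strings by sampled status
_VIRAL_PATH = "Viruses; Duplodnaviria; Heunggongvirae; Caudoviricetes;"
_CELLULAR_PATHS = {
    "bacteria": "Bacteria; Pseudomonadota; Gammaproteobacteria;",
    "archaea": "Archaea; Euryarchaeota; Methanomada group;",
    "plasmid": "Bacteria; Bacillota; Bacilli;",
    "protist": "Eukaryota; Sar; Alveolata;",
    "fungi": "Eukaryota; Opisthokonta; Fungi;",
}


@dataclass(frozen=True)
class ToolErrorProfile:
    """Detection behavior of one simulated tool.

    sensitivity
        Probability a true virus receives a positive signal.
    specificity
        Probability a non-virus receives no positive signal.
    low_confidence_rate
        Probability a positive signal lands in the low-confidence tier
        (satisfying only the ±0.5 subrule) instead of the confident one.
    dropout
        Probability the tool omits the sequence from its output entirely.
    """

    sensitivity: float = 0.9
    specificity: float = 0.95
    low_confidence_rate: float = 0.0
    dropout: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "low_confidence_rate", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def default_profiles(**overrides: ToolErrorProfile) -> dict[str, ToolErrorProfile]:
    """One profile per tool; keyword overrides replace individual tools."""
    profiles = {tool: ToolErrorProfile() for tool in TOOLS}
    unknown = set(overrides) - set(TOOLS)
    if unknown:
        raise ValueError(f"unknown tool(s) {sorted(unknown)}")
    profiles.update(overrides)
    return profiles


def _statuses(
    is_virus: np.ndarray,
    profile: ToolErrorProfile,
    rng: np.random.Generator,
    detectability: np.ndarray | None,
) -> np.ndarray:
    """Per-sequence signal: 'drop', 'confident', 'low', or 'negative'.

    With a shared latent ``detectability`` in [0, 1] per sequence, the
    positive-signal draw compares that latent against the tool's rate
    instead of an independent uniform, correlating errors across tools.
    """
    n = len(is_virus)
    out = np.full(n, "negative", dtype=object)
    drop = rng.random(n) < profile.dropout
    p_positive = np.where(is_virus, profile.sensitivity, 1.0 - profile.specificity)
    u = rng.random(n) if detectability is None else detectability
    positive = u < p_positive
    low = rng.random(n) < profile.low_confidence_rate
    out[positive] = "confident"
    out[positive & low] = "low"
    out[drop] = "drop"
    return out


def simulate_tool_outputs(
    labels: pd.DataFrame,
    lengths: Mapping[str, int],
    profiles: Mapping[str, ToolErrorProfile],
    seed: int,
    outdir: str | Path,
    *,
    shared_detectability: bool = False,
) -> dict[str, Path]:
    """Write all six tool-output files for one labeled sequence set.

    ``labels`` is a label table (index seq_id, columns true_class/is_virus);
    ``lengths`` maps seq_id to sequence length.  Returns the paths written,
    keyed by tool (plus ``vibrant_annotations``).  Deterministic per seed.
    """
    missing = set(TOOLS) - set(profiles)
    if missing:
        raise ValueError(f"profiles missing for tool(s) {sorted(missing)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq_ids = list(labels.index)
    is_virus = labels["is_virus"].to_numpy(dtype=bool)
    true_class = labels["true_class"].to_numpy(dtype=object)
    n = len(seq_ids)
    rng = np.random.default_rng(seed)
    detect = rng.random(n) if shared_detectability else None

    status = {
        tool: _statuses(is_virus, profiles[tool], rng, detect) for tool in TOOLS
    }
    paths: dict[str, Path] = {}

    # --- VirSorter2: scores every sequence it does not drop
    rows = []
    for i, sid in enumerate(seq_ids):
        st = status["virsorter2"][i]
        if st == "drop":
            continue
        if st == "confident":
            score = rng.uniform(0.9, 1.0)
            hallmark = int(rng.integers(2, 11))
        elif st == "low":
            score = rng.uniform(0.5, 0.899)
            hallmark = 0
        else:
            score = rng.uniform(0.0, 0.499)
            hallmark = 0
        rows.append(
            {
                "seqname": sid,
                "max_score": round(score, 3),
                "max_score_group": "dsDNAphage",
                "length": lengths[sid],
                "hallmark": hallmark,
            }
        )
    paths["virsorter2"] = outdir / "final-viral-score.tsv"
    pd.DataFrame(
        rows, columns=["seqname", "max_score", "max_score_group", "length", "hallmark"]
    ).to_csv(paths["virsorter2"], sep="\t", index=False)

    # --- VIBRANT: only phage calls appear; negatives/dropouts are absent rows
    vb_rows, ann_rows = [], []
    for i, sid in enumerate(seq_ids):
        st = status["vibrant"][i]
        if st not in ("confident", "low"):
            continue
        quality = str(rng.choice(["high", "medium"])) if st == "confident" else "low"
        vb_rows.append({"scaffold": sid, "Quality": quality})
        total_genes = int(rng.integers(5, 41))
        # viruses carry a high VOG fraction; false-positive cells a lower one
        frac = rng.uniform(0.5, 0.9) if is_virus[i] else rng.uniform(0.05, 0.4)
        n_vog = int(round(frac * total_genes))
        for g in range(total_genes):
            ann_rows.append(
                {
                    "scaffold": sid,
                    "protein": f"{sid}_{g + 1}",
                    "VOG": f"VOG{rng.integers(1, 99999):05d}" if g < n_vog else "",
                }
            )
    paths["vibrant"] = outdir / "vibrant_quality.tsv"
    pd.DataFrame(vb_rows, columns=["scaffold", "Quality"]).to_csv(
        paths["vibrant"], sep="\t", index=False
    )
    paths["vibrant_annotations"] = outdir / "vibrant_annotations.tsv"
    pd.DataFrame(ann_rows, columns=["scaffold", "protein", "VOG"]).to_csv(
        paths["vibrant_annotations"], sep="\t", index=False
    )

    # --- VirSorter: only phage-signal rows appear
    vs_rows = []
    for i, sid in enumerate(seq_ids):
        st = status["virsorter"][i]
        if st == "confident":
            vs_rows.append({"contig_id": sid, "category": int(rng.integers(1, 3))})
        elif st == "low":
            vs_rows.append({"contig_id": sid, "category": 3})
    paths["virsorter"] = outdir / "virsorter_phage_signal.csv"
    pd.DataFrame(vs_rows, columns=["contig_id", "category"]).to_csv(
        paths["virsorter"], index=False
    )

    # --- DeepVirFinder: scores every sequence it does not drop
    dvf_rows = []
    for i, sid in enumerate(seq_ids):
        st = status["deepvirfinder"][i]
        if st == "drop":
            continue
        if st == "confident":
            score, pvalue = rng.uniform(0.9, 1.0), rng.uniform(0.0, 0.049)
        elif st == "low":
            score, pvalue = rng.uniform(0.7, 0.8999), rng.uniform(0.0, 0.049)
        else:
            score, pvalue = rng.uniform(0.0, 0.6999), rng.uniform(0.05, 1.0)
        dvf_rows.append(
            {
                "name": sid,
                "len": lengths[sid],
                "score": round(score, 4),
                "pvalue": round(pvalue, 4),
            }
        )
    paths["deepvirfinder"] = outdir / "dvf_scores.tsv"
    pd.DataFrame(dvf_rows, columns=["name", "len", "score", "pvalue"]).to_csv(
        paths["deepvirfinder"], sep="\t", index=False
    )

    # --- CheckV: quality summary for every sequence it does not drop
    cv_rows = []
    for i, sid in enumerate(seq_ids):
        st = status["checkv"][i]
        if st == "drop":
            continue
        if st == "confident":
            viral_genes = int(rng.integers(5, 21))
            host_genes = int(rng.integers(0, 2))
            quality = str(rng.choice(["complete", "high", "medium"]))
            completeness = round(rng.uniform(50.0, 100.0), 1)
        elif st == "low":
            # weak viral evidence: triggers neither tuning addition nor removal
            viral_genes = int(rng.integers(2, 6))
            host_genes = int(rng.integers(0, 2))
            quality = "low"
            completeness = round(rng.uniform(30.0, 49.8), 1)
        else:
            viral_genes = 0
            host_genes = int(rng.integers(2, 31))
            quality = str(rng.choice(["low", "not_determined"]))
            completeness = round(rng.uniform(0.0, 49.8), 1)
        cv_rows.append(
            {
                "contig_id": sid,
                "contig_length": lengths[sid],
                "gene_count": viral_genes + host_genes + int(rng.integers(0, 6)),
                "viral_genes": viral_genes,
                "host_genes": host_genes,
                "checkv_quality": quality,
                "completeness": completeness,
            }
        )
    paths["checkv"] = outdir / "quality_summary.tsv"
    pd.DataFrame(
        cv_rows,
        columns=[
            "contig_id",
            "contig_length",
            "gene_count",
            "viral_genes",
            "host_genes",
            "checkv_quality",
            "completeness",
        ],
    ).to_csv(paths["checkv"], sep="\t", index=False)

    # --- Kaiju: C/U status + lineage; dropouts are omitted rows
    kj_lines = []
    for i, sid in enumerate(seq_ids):
        st = status["kaiju"][i]
        if st == "drop":
            continue
        if st in ("confident", "low"):
            path_str, taxon_id = _VIRAL_PATH, 10239
        else:
            cls = true_class[i] if true_class[i] in _CELLULAR_PATHS else "bacteria"
            path_str, taxon_id = _CELLULAR_PATHS[cls], 2
        kj_lines.append(f"C\t{sid}\t{taxon_id}\t{path_str}")
    paths["kaiju"] = outdir / "kaiju_names.tsv"
    paths["kaiju"].write_text("\n".join(kj_lines) + ("\n" if kj_lines else ""))

    return paths


def make_benchmark_bundle(
    spec: CompositionSpec | None = None,
    profiles: Mapping[str, ToolErrorProfile] | None = None,
    seed: int = 0,
    outdir: str | Path = "benchmark_bundle",
    *,
    shared_detectability: bool = False,
    write_fasta: bool = True,
) -> dict:
    """A complete download-free benchmark: mocks + tool outputs + labels.

    Builds ``spec.n_replicates`` mock metagenomes from the bundled random
    pools, simulates all six tool outputs for each, and writes everything
    under ``outdir/rep<i>/``.  Returns a manifest dict with per-replicate
    paths and the :class:`MockMetagenome` objects.  Byte-identical for
    identical seeds.
    """
    spec = spec or CompositionSpec()
    profiles = dict(profiles) if profiles is not None else default_profiles()
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    pool_seed, mock_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    pools = default_pools(seed=pool_seed)
    mocks = build_mock(pools, spec, seed=mock_seed)
    replicates = []
    for mock in mocks:
        rep_dir = outdir / f"rep{mock.replicate}"
        rep_dir.mkdir(parents=True, exist_ok=True)
        lengths = {rec.id: len(rec.seq) for rec in mock.records}
        tool_paths = simulate_tool_outputs(
            mock.labels,
            lengths,
            profiles,
            seed=int(rng.integers(0, 2**31 - 1)),
            outdir=rep_dir,
            shared_detectability=shared_detectability,
        )
        files = {k: str(v) for k, v in tool_paths.items()}
        if write_fasta:
            written = mock.write(rep_dir)
            files.update({k: str(v) for k, v in written.items()})
        else:
            labels_path = rep_dir / f"mock_rep{mock.replicate}_labels.tsv"
            mock.labels[["true_class"]].to_csv(labels_path, sep="\t")
            files["labels"] = str(labels_path)
        replicates.append({"replicate": mock.replicate, "files": files})
    return {"outdir": str(outdir), "seed": seed, "replicates": replicates, "mocks": mocks}
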