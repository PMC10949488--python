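"""Mock-metagenome construction from class-labeled sequence pools.

A mock metagenome is a labeled contig set sampled with replacement from
per-class sequence pools, mimicking the composition of cellular-enriched
environmental metagenomes: the default mix is 68% bacteria, 10% archaea,
10% virus, 5% plasmid, 5% protist, and 2% fungi over ~8,000 sequences,
replicated five times.

Two length constraints shape every emitted sequence: contigs must be longer
than 3 kb (tool accuracy collapses below that) and shorter than 2,100 kb
(the DeepVirFinder input cap); long pool sequences are truncated, short
ones discarded.  A fragmenter additionally cuts 3-5 kb pieces to emulate
short-contig assemblies.

Pools can be real FASTA files (one per class) or generated random-composition
sequences (:func:`random_pool`), which keep the whole benchmark download-free.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import CLASSES

logger = logging.getLogger(__name__)

MIN_LENGTH_BP = 3_000
MAX_LENGTH_BP = 2_100_000

#: cellular-enriched metagenome composition
DEFAULT_COMPOSITION = {
    "bacteria": 0.68,
    "archaea": 0.10,
    "virus": 0.10,
    "plasmid": 0.05,
    "protist": 0.05,
    "fungi": 0.02,
}


@dataclass(frozen=True)
class CompositionSpec:
    """Target class fractions plus dataset size and replication."""

    fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION)
    )
    total_sequences: int = 8_000
    n_replicates: int = 5

    def __post_init__(self) -> None:
        bad = set(self.fractions) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class(es) {sorted(bad)}")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.total_sequences < 1 or self.n_replicates < 1:
            raise ValueError("total_sequences and n_replicates must be positive")


@dataclass(frozen=True)
class SequencePool:
    """A class label plus its candidate sequences (unique ids)."""

    label: str
    records: tuple

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"unknown class {self.label!r}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pool {self.label}: duplicate sequence ids")


@dataclass
class MockMetagenome:
    """One labeled replicate: records, label table, provenance."""

    records: list
    labels: pd.DataFrame  # index seq_id; true_class, is_virus
    provenance: pd.DataFrame  # seq_id, source_id, true_class, replicate, seed
    replicate: int
    seed: int

    def write(self, outdir: str | Path, prefix: str = "mock") -> dict[str, Path]:
        """Write FASTA + label TSV + provenance TSV for this replicate."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stem = f"{prefix}_rep{self.replicate}"
        fasta = outdir / f"{stem}.fasta"
        SeqIO.write(self.records, str(fasta), "fasta")
        labels = outdir / f"{stem}_labels.tsv"
        self.labels[["true_class"]].to_csv(labels, sep="\t")
        prov = outdir / f"{stem}_provenance.tsv"
        self.provenance.to_csv(prov, sep="\t", index=False)
        return {"fasta": fasta, "labels": labels, "provenance": prov}


def length_filter(
    sequences: Iterable[SeqRecord], min_length_bp: int = MIN_LENGTH_BP
) -> list[SeqRecord]:
    """Keep only sequences strictly longer than ``min_length_bp``."""
    return [rec for rec in sequences if len(rec.seq) > min_length_bp]


def trim_sequence(
    sequence: SeqRecord, max_length_bp: int = MAX_LENGTH_BP
) -> SeqRecord:
    """Truncate to strictly below ``max_length_bp`` (prefix kept).

    Sequences at or above the cap are cut to ``max_length_bp - 1``; shorter
    sequences pass through unchanged.
    """
    if len(sequence.seq) < max_length_bp:
        return sequence
    out = sequence[: max_length_bp - 1]
    out.id, out.description = sequence.id, sequence.description
    return out


def apportion_counts(spec: CompositionSpec) -> dict[str, int]:
    """Deterministic class counts by largest-remainder apportionment.

    Floors of fraction*total, with leftover seats given to the largest
    fractional remainders (ties broken by class name), so counts sum to the
    requested total exactly.
    """
    quotas = {cls: frac * spec.total_sequences for cls, frac in spec.fractions.items()}
    counts = {cls: int(np.floor(q)) for cls, q in quotas.items()}
    leftover = spec.total_sequences - sum(counts.values())
    remainders = sorted(
        quotas, key=lambda cls: (-(quotas[cls] - counts[cls]), cls)
    )
    for cls in remainders[:leftover]:
        counts[cls] += 1
    return counts


def build_mock(
    pools: Sequence[SequencePool],
    spec: CompositionSpec | None = None,
    seed: int = 0,
    *,
    method: str = "largest_remainder",
) -> list[MockMetagenome]:
    """Sample ``n_replicates`` labeled mock metagenomes from class pools.

    Sequences are drawn with replacement within class, trimmed below the
    DeepVirFinder cap, and length-filtered (> 3 kb); each draw gets a unique
    per-replicate id.  ``method="largest_remainder"`` (default) hits the
    target fractions exactly up to rounding; ``method="multinomial"`` draws
    class counts multinomially instead.  Output is bit-identical for
    identical seeds.
    """
    spec = spec or CompositionSpec()
    if method not in ("largest_remainder", "multinomial"):
        raise ValueError(f"unknown method {method!r}")
    by_class: dict[str, SequencePool] = {}
    for pool in pools:
        if pool.label in by_class:
            raise ValueError(f"duplicate pool for class {pool.label}")
        by_class[pool.label] = pool

    filtered: dict[str, list[SeqRecord]] = {}
    for cls, frac in spec.fractions.items():
        if frac == 0:
            continue
        if cls not in by_class:
            raise ValueError(f"no pool provided for required class {cls!r}")
        usable = length_filter(
            [trim_sequence(r) for r in by_class[cls].records]
        )
        if not usable:
            raise ValueError(
                f"pool for class {cls!r} has no sequences surviving the length filter"
            )
        filtered[cls] = usable

    rng = np.random.default_rng(seed)
    replicate_seeds = rng.integers(0, 2**31 - 1, size=spec.n_replicates)
    classes = sorted(filtered)
    out = []
    for rep, rep_seed in enumerate(replicate_seeds):
        rep_rng = np.random.default_rng(int(rep_seed))
        if method == "largest_remainder":
            counts = apportion_counts(spec)
        else:
            probs = [spec.fractions[c] for c in classes]
            draw = rep_rng.multinomial(spec.total_sequences, probs)
            counts = dict(zip(classes, (int(d) for d in draw)))
        records, label_rows, prov_rows = [], [], []
        i = 0
        for cls in classes:
            n = counts.get(cls, 0)
            pool_records = filtered[cls]
            picks = rep_rng.integers(0, len(pool_records), size=n)
            for k in picks:
                src = pool_records[int(k)]
                new_id = f"rep{rep}_seq{i:05d}"
                records.append(SeqRecord(src.seq, id=new_id, description=""))
                label_rows.append({"seq_id": new_id, "true_class": cls})
                prov_rows.append(
                    {
                        "seq_id": new_id,
                        "source_id": src.id,
                        "true_class": cls,
                        "replicate": rep,
                        "seed": int(rep_seed),
                    }
                )
                i += 1
        labels = pd.DataFrame(label_rows).set_index("seq_id")
        labels["is_virus"] = labels["true_class"] == "virus"
        out.append(
            MockMetagenome(
                records=records,
                labels=labels,
                provenance=pd.DataFrame(prov_rows),
                replicate=rep,
                seed=int(rep_seed),
            )
        )
    return out


def fragment_sequences(
    sequences: Iterable[SeqRecord],
    min_bp: int = 3_000,
    max_bp: int = 5_000,
    seed: int = 0,
) -> list[SeqRecord]:
    """Cut one random fragment per parent sequence (short-contig emulation).

    Fragment length is uniform on [min_bp, max_bp], capped at the parent
    length; the start position is uniform.  Parents shorter than ``min_bp``
    are skipped with a warning.  Fragment ids inherit the parent id.
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in sequences:
        parent_len = len(rec.seq)
        if parent_len < min_bp:
            warnings.warn(f"{rec.id}: shorter than {min_bp} bp; skipped")
            continue
        frag_len = int(rng.integers(min_bp, min(max_bp, parent_len) + 1))
        start = int(rng.integers(0, parent_len - frag_len + 1))
        frag = rec[start : start + frag_len]
        frag.id, frag.description = rec.id, ""
        out.append(frag)
    return out


def random_pool(
    label: str,
    n_sequences: int = 50,
    length_range: tuple[int, int] = (3_200, 8_000),
    gc: float = 0.5,
    seed: int = 0,
) -> SequencePool:
    """A synthetic pool of random-composition nucleotide sequences.

    Provides download-free pools for benchmarking the scoring stack; the
    sequences carry no biological signal (tool outputs are simulated
    separately, keyed on the label, not the sequence).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    alphabet = np.array(list("ACGT"))
    records = []
    for i in range(n_sequences):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        records.append(
            SeqRecord(Seq(seq), id=f"{label}_pool_{i:04d}", description="")
        )
    return SequencePool(label, tuple(records))


def default_pools(seed: int = 0) -> list[SequencePool]:
    """One bundled random pool per class (deterministic in ``seed``)."""
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(CLASSES))
    return [
        random_pool(cls, seed=int(s)) for cls, s in zip(sorted(CLASSES), seeds)
    ]


def load_pool(label: str, fasta_path: str | Path) -> SequencePool:
    """Load a class pool from a FASTA file."""
    records = tuple(SeqIO.parse(str(fasta_path), "fasta"))
    return SequencePool(label, records)
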