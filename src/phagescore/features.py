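"""Parse viral-identification tool outputs into a unified per-contig feature table.

Six tools are supported, each with its own tabular output dialect:

* **VirSorter2** -- ``final-viral-score.tsv``: per-contig classifier score in
  [0, 1], the best-scoring viral group, and a hallmark-gene count.
* **VIBRANT** -- phage quality TSV (high/medium/low quality calls) plus an
  optional per-protein annotation table from which VOG (virus orthologous
  group) gene counts are tallied.
* **VirSorter** -- global phage-signal CSV with a confidence category 1-6.
* **DeepVirFinder** -- per-contig score and p-value TSV.
* **CheckV** -- ``quality_summary.tsv``: viral/host gene counts, completeness
  estimate, and a quality tier.
* **Kaiju** -- per-sequence taxonomic classification TSV (C/U status plus an
  NCBI lineage string).

The merged :class:`pandas.DataFrame` ("feature table") has one row per
sequence id and one column per feature.  *Absent* (the tool did not report
the sequence) is encoded as NaN/None and is distinct from zero; the only
exceptions are ``vb_quality`` (absence from VIBRANT's phage list means
``"none"``) and ``kj_classified`` (absence means unclassified, ``False``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TOOLS = ("virsorter2", "vibrant", "virsorter", "deepvirfinder", "checkv", "kaiju")

#: canonical feature-table columns and their dtype kind
FEATURES: dict[str, str] = {
    "length_bp": "int",
    "vs2_score": "float",
    "vs2_hallmark": "float",  # float so NaN can mark absence
    "vs2_group": "str",
    "vb_quality": "enum",  # high / medium / low / none
    "vb_vog_genes": "float",
    "vb_total_genes": "float",
    "vs_category": "float",
    "dvf_score": "float",
    "dvf_pvalue": "float",
    "cv_viral_genes": "float",
    "cv_host_genes": "float",
    "cv_completeness": "float",
    "cv_quality": "enum",  # complete / high / medium / low / not_determined
    "kj_classified": "bool",
    "kj_taxon_path": "str",
    "kj_is_viral": "object",  # True / False / None (unclassified)
}

#: features each tool may populate
TOOL_FEATURES: dict[str, tuple[str, ...]] = {
    "virsorter2": ("vs2_score", "vs2_group", "vs2_hallmark", "length_bp"),
    "vibrant": ("vb_quality", "vb_vog_genes", "vb_total_genes"),
    "virsorter": ("vs_category",),
    "deepvirfinder": ("dvf_score", "dvf_pvalue", "length_bp"),
    "checkv": (
        "cv_viral_genes",
        "cv_host_genes",
        "cv_completeness",
        "cv_quality",
        "length_bp",
    ),
    "kaiju": ("kj_classified", "kj_taxon_path"),
}

CLASSES = ("virus", "bacteria", "archaea", "plasmid", "protist", "fungi")

VB_QUALITIES = ("high", "medium", "low", "none")
CV_QUALITIES = ("complete", "high", "medium", "low", "not_determined")

#: default decorations stripped from contig ids at parse time.  VirSorter2
#: appends ``||full`` / ``||N_partial`` / ``||lt2gene``; VirSorter marks
#: circular contigs; VIBRANT emits ``_fragment_N`` pieces for prophages.
DEFAULT_ID_PATTERNS = (
    r"\|\|.*$",
    r"-circular$",
    r"_fragment_\d+$",
)


class DialectError(ValueError):
    """A tool-output file does not match its expected column layout."""


class DuplicateIdError(ValueError):
    """One tool reported the same sequence id more than once."""


class LabelError(ValueError):
    """A label file contains a class token outside the known six."""


@dataclass(frozen=True)
class ToolRecordFragment:
    """One tool's parsed signals for one sequence."""

    seq_id: str
    tool: str
    features: Mapping[str, object]

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        bad = set(self.features) - set(TOOL_FEATURES[self.tool])
        if bad:
            raise ValueError(f"features {sorted(bad)} not defined for tool {self.tool}")


@dataclass
class IdNormalizer:
    """Regex-based contig-id normalizer applied at parse time.

    Several tools decorate contig names (circular/provirus markers, fragment
    suffixes), which breaks cross-tool joins.  Patterns are removed in order.
    """

    patterns: tuple[str, ...] = DEFAULT_ID_PATTERNS

    def __post_init__(self) -> None:
        self._compiled = [re.compile(p) for p in self.patterns]

    def __call__(self, seq_id: str) -> str:
        out = seq_id.strip()
        for pat in self._compiled:
            out = pat.sub("", out)
        return out


_REQUIRED_COLUMNS = {
    "virsorter2": ("seqname", "max_score", "max_score_group", "length", "hallmark"),
    "vibrant": ("scaffold", "Quality"),
    "virsorter": ("contig_id", "category"),
    "deepvirfinder": ("name", "len", "score", "pvalue"),
    "checkv": (
        "contig_id",
        "contig_length",
        "gene_count",
        "viral_genes",
        "host_genes",
        "checkv_quality",
        "completeness",
    ),
}


def _read_table(path: Path, tool: str, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DialectError(f"{tool}: file {path} has no header row")
    required = _REQUIRED_COLUMNS[tool]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DialectError(f"{tool}: missing required column(s) {missing} in {path}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s in %s", tool, extra, path)
    return df


def _num(value: str, caster, tool: str, column: str, line: int):
    try:
        return caster(value)
    except (TypeError, ValueError):
        raise DialectError(
            f"{tool}: unparseable {column}={value!r} at data row {line}"
        )


def _check_duplicates(ids: Iterable[str], tool: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for sid in ids:
        if sid in seen:
            dups.append(sid)
        seen.add(sid)
    if dups:
        raise DuplicateIdError(f"{tool}: duplicate seq_id(s) {sorted(set(dups))}")


def read_tool_output(
    path: str | Path,
    tool: str,
    *,
    annotation_path: str | Path | None = None,
    normalizer: IdNormalizer | None = None,
) -> list[ToolRecordFragment]:
    """Read one tool's output file into :class:`ToolRecordFragment` records.

    Parameters
    ----------
    path:
        The tool's main output table (see module docstring for dialects).
    tool:
        One of ``virsorter2, vibrant, virsorter, deepvirfinder, checkv, kaiju``.
    annotation_path:
        VIBRANT only: the per-protein annotation TSV from which VOG and total
        gene counts are tallied.
    normalizer:
        Contig-id normalizer; defaults to stripping the known decorations.
    """
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}; expected one of {TOOLS}")
    norm = normalizer or IdNormalizer()
    path = Path(path)
    reader = {
        "virsorter2": _read_virsorter2,
        "vibrant": _read_vibrant,
        "virsorter": _read_virsorter,
        "deepvirfinder": _read_deepvirfinder,
        "checkv": _read_checkv,
        "kaiju": _read_kaiju,
    }[tool]
    if tool == "vibrant":
        return reader(path, norm, annotation_path)
    return reader(path, norm)


def _read_virsorter2(path: Path, norm: IdNormalizer) -> list[ToolRecordFragment]:
    df = _read_table(path, "virsorter2", sep="\t")
    frags = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = norm(row.seqname)
        frags.append(
            ToolRecordFragment(
                sid,
                "virsorter2",
                {
                    "vs2_score": _num(row.max_score, float, "virsorter2", "max_score", i),
                    "vs2_group": row.max_score_group,
                    "vs2_hallmark": _num(row.hallmark, int, "virsorter2", "hallmark", i),
                    "length_bp": _num(row.length, int, "virsorter2", "length", i),
                },
            )
        )
    _check_duplicates((f.seq_id for f in frags), "virsorter2")
    return frags


def _read_vibrant(
    path: Path, norm: IdNormalizer, annotation_path: str | Path | None
) -> list[ToolRecordFragment]:
    df = _read_table(path, "vibrant", sep="\t")
    vog: dict[str, int] = {}
    total: dict[str, int] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", dtype=str, keep_default_na=False)
        for col in ("scaffold", "protein", "VOG"):
            if col not in ann.columns:
                raise DialectError(f"vibrant annotation: missing column {col!r}")
        for row in ann.itertuples(index=False):
            sid = norm(row.scaffold)
            total[sid] = total.get(sid, 0) + 1
            if row.VOG:
                vog[sid] = vog.get(sid, 0) + 1
    frags = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        sid = norm(row.scaffold)
        quality = row.Quality.strip().lower()
        if quality not in ("high", "medium", "low"):
            raise DialectError(
                f"vibrant: unparseable Quality={row.Quality!r} at data row {i}"
            )
        feats: dict[str, object] = {"vb_quality": quality}
        if sid in total:
            feats["vb_total_genes"] = total[sid]
            feats["vb_vog_genes"] = vog.get(sid, 0)
        frags.append(ToolRecordFragment(sid, "vibrant", feats))
    _check_duplicates((f.seq_id for f in frags), "vibrant")
    return frags


def _read_virsorter(path: Path, norm: IdNormalizer) -> list[ToolRecordFragment]:
    df = _read_table(path, "virsorter", sep=",")
    frags = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cat = _num(row.category, int, "virsorter", "category", i)
        if not 1 <= cat <= 6:
            raise DialectError(f"virsorter: category {cat} out of range at row {i}")
        frags.append(
            ToolRecordFragment(norm(row.contig_id), "virsorter", {"vs_category": cat})
        )
    _check_duplicates((f.seq_id for f in frags), "virsorter")
    return frags


def _read_deepvirfinder(path: Path, norm: IdNormalizer) -> list[ToolRecordFragment]:
    df = _read_table(path, "deepvirfinder", sep="\t")
    frags = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        frags.append(
            ToolRecordFragment(
                norm(row.name),
                "deepvirfinder",
                {
                    "dvf_score": _num(row.score, float, "deepvirfinder", "score", i),
                    "dvf_pvalue": _num(row.pvalue, float, "deepvirfinder", "pvalue", i),
                    "length_bp": _num(row.len, int, "deepvirfinder", "len", i),
                },
            )
        )
    _check_duplicates((f.seq_id for f in frags), "deepvirfinder")
    return frags


def _read_checkv(path: Path, norm: IdNormalizer) -> list[ToolRecordFragment]:
    df = _read_table(path, "checkv", sep="\t")
    frags = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        quality = row.checkv_quality.strip().lower().replace("-quality", "").replace(
            " ", "_"
        )
        if quality not in CV_QUALITIES:
            raise DialectError(
                f"checkv: unparseable checkv_quality={row.checkv_quality!r} at row {i}"
            )
        feats: dict[str, object] = {
            "cv_viral_genes": _num(row.viral_genes, int, "checkv", "viral_genes", i),
            "cv_host_genes": _num(row.host_genes, int, "checkv", "host_genes", i),
            "cv_quality": quality,
            "length_bp": _num(row.contig_length, int, "checkv", "contig_length", i),
        }
        # CheckV prints NA completeness for undetermined contigs
        if row.completeness not in ("", "NA"):
            feats["cv_completeness"] = _num(
                row.completeness, float, "checkv", "completeness", i
            )
        frags.append(ToolRecordFragment(norm(row.contig_id), "checkv", feats))
    _check_duplicates((f.seq_id for f in frags), "checkv")
    return frags


def _read_kaiju(path: Path, norm: IdNormalizer) -> list[ToolRecordFragment]:
    # kaiju writes no header; tolerate one if present
    frags = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if i == 1 and parts[0] not in ("C", "U"):
                continue  # header row
            if parts[0] not in ("C", "U") or len(parts) < 2:
                raise DialectError(f"kaiju: unparseable status at data row {i}")
            sid = norm(parts[1])
            classified = parts[0] == "C"
            feats: dict[str, object] = {"kj_classified": classified}
            if classified:
                taxon_path = parts[3] if len(parts) > 3 else ""
                feats["kj_taxon_path"] = taxon_path
            frags.append(ToolRecordFragment(sid, "kaiju", feats))
    _check_duplicates((f.seq_id for f in frags), "kaiju")
    return frags


def _is_viral_path(taxon_path: str) -> bool:
    """True iff the lineage's first-rank token is the viral superkingdom."""
    first = taxon_path.split(";")[0].strip()
    return first.lower() == "viruses"


def empty_feature_table(seq_ids: Iterable[str] = ()) -> pd.DataFrame:
    """A feature table with all tool features absent."""
    idx = pd.Index(list(seq_ids), name="seq_id")
    df = pd.DataFrame(index=idx)
    for name, kind in FEATURES.items():
        if name == "vb_quality":
            df[name] = "none"
        elif name == "kj_classified":
            df[name] = False
        elif kind in ("str", "enum", "object"):
            df[name] = pd.Series([None] * len(idx), index=idx, dtype=object)
        else:
            df[name] = np.nan
    return df


def merge_features(
    fragments: Iterable[ToolRecordFragment],
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Merge tool fragments (outer union of seq_ids) into one feature table.

    ``lengths`` (typically from the assembly FASTA) wins over tool-reported
    lengths; disagreements are logged.  ``kj_is_viral`` is derived from the
    Kaiju lineage string.  Conflicting duplicate fragments raise.
    """
    fragments = list(fragments)
    lengths = dict(lengths or {})
    seen: dict[tuple[str, str], Mapping[str, object]] = {}
    for frag in fragments:
        key = (frag.tool, frag.seq_id)
        if key in seen:
            if dict(seen[key]) != dict(frag.features):
                raise DuplicateIdError(
                    f"conflicting fragments for {frag.seq_id!r} from {frag.tool}"
                )
        seen[key] = frag.features

    ids = sorted(set(lengths) | {sid for (_, sid) in seen})
    table = empty_feature_table(ids)

    for (tool, sid), feats in sorted(seen.items()):
        for name, value in feats.items():
            if name == "length_bp":
                if sid in lengths and lengths[sid] != value:
                    logger.warning(
                        "length mismatch for %s: FASTA=%d, %s=%s (keeping FASTA)",
                        sid,
                        lengths[sid],
                        tool,
                        value,
                    )
                    continue
                if sid not in lengths and not pd.isna(table.at[sid, "length_bp"]):
                    if table.at[sid, "length_bp"] != value:
                        logger.warning(
                            "length mismatch for %s between tools; keeping first", sid
                        )
                    continue
            table.at[sid, name] = value

    for sid, length in lengths.items():
        table.at[sid, "length_bp"] = length

    classified = table["kj_classified"].astype(bool)
    viral = table.loc[classified, "kj_taxon_path"].map(
        lambda p: _is_viral_path(p) if isinstance(p, str) else False
    )
    table["kj_is_viral"] = pd.Series([None] * len(table), index=table.index, dtype=object)
    table.loc[classified, "kj_is_viral"] = viral
    return table


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read the ground-truth label table (seq_id, class).

    Returns a DataFrame indexed by seq_id with ``true_class`` and the derived
    boolean ``is_virus``.  Class tokens outside the six known classes raise.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else None
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise LabelError(f"label file {path} needs two columns (seq_id, class)")
    df = df.iloc[:, :2]
    df.columns = ["seq_id", "true_class"]
    df["true_class"] = df["true_class"].str.strip().str.lower()
    bad = df[~df["true_class"].isin(CLASSES)]
    if not bad.empty:
        first = bad.iloc[0]
        raise LabelError(
            f"unknown class {first['true_class']!r} at line "
            f"{bad.index[0] + 2} of {path}"
        )
    _check_duplicates(df["seq_id"], "labels")
    df = df.set_index("seq_id")
    df["is_virus"] = df["true_class"] == "virus"
    return df


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Sequence lengths from a FASTA file, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
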