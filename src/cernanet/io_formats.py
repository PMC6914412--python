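"""Readers and writers for the external formats the pipeline touches.

All tabular formats are plain tab-separated text; sequences are FASTA;
networks are exported as SIF, GraphML, or an edge TSV.  Every reader
validates its input strictly and every reader/writer pair is a lossless
round trip on valid data.  Expression values are assumed to arrive already
log2-transformed and normalized (pass ``log2_input=False`` to apply
``log2(x + 1)`` on read).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("mRNA", "lncRNA", "miRNA")
CONDITIONS = ("tumor", "normal")
_NUC_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleInfo:
    """Annotation for one array/library column.

    ``pair_id`` links a tumor sample to its matched normal within a cohort.
    """

    sample_id: str
    condition: str  # "tumor" | "normal"
    cohort: str
    pair_id: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"sample {self.sample_id!r}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )


@dataclass
class ExpressionMatrix:
    """A log2 feature-by-sample expression matrix with sample annotations.

    ``values`` is a features x samples DataFrame indexed by feature_id;
    ``feature_class`` maps every feature to one of mRNA/lncRNA/miRNA.
    """

    values: pd.DataFrame
    feature_class: pd.Series
    samples: list[SampleInfo]

    def __post_init__(self) -> None:
        ids = self.values.index
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature_id(s): {dups[:5]}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError("duplicate sample_id in sample list")
        if list(self.values.columns) != sample_ids:
            raise FormatError("matrix columns do not match sample sheet order")
        self.feature_class = self.feature_class.reindex(ids)
        if self.feature_class.isna().any():
            missing = ids[self.feature_class.isna()].tolist()
            raise FormatError(f"feature_class missing for {missing[:5]}")
        bad = set(self.feature_class.unique()) - set(FEATURE_CLASSES)
        if bad:
            raise FormatError(f"unknown feature_class value(s): {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError(
                "non-finite expression values; use missing='drop' on read "
                "or clean the matrix"
            )
        self._check_pairing()

    def _check_pairing(self) -> None:
        by_pair: dict[tuple[str, str], list[str]] = {}
        for s in self.samples:
            if s.pair_id is not None:
                by_pair.setdefault((s.cohort, s.pair_id), []).append(s.condition)
        for (cohort, pair), conds in by_pair.items():
            if sorted(conds) != ["normal", "tumor"]:
                raise FormatError(
                    f"pair {pair!r} in cohort {cohort!r} must contain exactly one "
                    f"tumor and one normal sample, got {conds}"
                )

    # -- convenience accessors ------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cohorts(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cohort, None)
        return list(seen)

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.array([s.condition == condition for s in self.samples])

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        info = {s.sample_id: s for s in self.samples}
        missing = [k for k in keep if k not in info]
        if missing:
            raise KeyError(f"unknown sample(s): {missing[:5]}")
        return ExpressionMatrix(
            values=self.values[keep].copy(),
            feature_class=self.feature_class.copy(),
            samples=[info[k] for k in keep],
        )

    def subset_cohort(self, cohort: str) -> "ExpressionMatrix":
        keep = [s.sample_id for s in self.samples if s.cohort == cohort]
        if not keep:
            raise KeyError(f"no samples in cohort {cohort!r}")
        return self.subset_samples(keep)

    def subset_condition(self, condition: str) -> "ExpressionMatrix":
        keep = [s.sample_id for s in self.samples if s.condition == condition]
        if not keep:
            raise KeyError(f"no {condition} samples")
        return self.subset_samples(keep)

    def subset_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        missing = [k for k in keep if k not in self.values.index]
        if missing:
            raise KeyError(f"unknown feature(s): {missing[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[keep].copy(),
            feature_class=self.feature_class.loc[keep].copy(),
            samples=list(self.samples),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.feature_class.equals(other.feature_class)
            and self.samples == other.samples
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: set_id -> (description, ordered member ids)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {set_id!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def members(self, set_id: str) -> tuple[str, ...]:
        return self.sets[set_id][1]


@dataclass(frozen=True)
class Relation:
    source: str
    target: str
    relation: str = "interaction"
    weight: float = 1.0
    directed: bool = True

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise FormatError(f"negative weight on edge {self.source}->{self.target}")


@dataclass
class RelationTable:
    """A list of (source, target, relation, weight, directed) gene-gene edges."""

    edges: list[Relation] = field(default_factory=list)
    allow_self_loops: bool = False

    def __post_init__(self) -> None:
        if not self.allow_self_loops:
            loops = [e for e in self.edges if e.source == e.target]
            if loops:
                raise FormatError(
                    f"self-loop(s) not allowed: {loops[0].source}->{loops[0].target}"
                )

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


@dataclass
class SequenceSet:
    """Nucleotide sequences keyed by feature id, stored 5'->3' with U->T applied."""

    records: dict[str, str]
    moltype: str  # "miRNA" | "transcript"

    def __post_init__(self) -> None:
        if self.moltype not in ("miRNA", "transcript"):
            raise FormatError(f"moltype must be 'miRNA' or 'transcript', got {self.moltype!r}")
        clean: dict[str, str] = {}
        for name, seq in self.records.items():
            s = seq.upper().replace("U", "T")
            if not s:
                raise FormatError(f"empty sequence for {name!r}")
            bad = set(s) - _NUC_ALPHABET
            if bad:
                raise FormatError(f"invalid character(s) {sorted(bad)} in sequence {name!r}")
            clean[name] = s
        self.records = clean

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __iter__(self):
        return iter(self.records.items())


ENDPOINTS = ("OS", "PFS", "DmFS")


@dataclass
class ClinicalTable:
    """Per-patient follow-up: time (months), event flag, endpoint, covariates.

    ``data`` has columns patient_id, time, event, endpoint plus arbitrary
    covariate columns; one row per patient per endpoint.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"patient_id", "time", "event", "endpoint"}
        missing = req - set(self.data.columns)
        if missing:
            raise FormatError(f"clinical table missing column(s): {sorted(missing)}")
        if (self.data["time"] <= 0).any():
            raise FormatError("clinical times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise FormatError("event must be 0 or 1")
        bad = set(self.data["endpoint"].unique()) - set(ENDPOINTS)
        if bad:
            raise FormatError(f"unknown endpoint(s): {sorted(bad)}")
        if self.data.duplicated(subset=["patient_id", "endpoint"]).any():
            raise FormatError("more than one row per patient per endpoint")

    @property
    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("patient_id", "time", "event", "endpoint")]

    def endpoint_frame(self, endpoint: str) -> pd.DataFrame:
        sub = self.data[self.data["endpoint"] == endpoint]
        if sub.empty:
            raise KeyError(f"no rows for endpoint {endpoint!r}")
        return sub.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Expression matrix + sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    """Read a sample sheet TSV with columns sample_id, condition, cohort[, pair_id]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    req = {"sample_id", "condition", "cohort"}
    missing = req - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing column(s): {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        pair = row.get("pair_id")
        if pair is not None and (pd.isna(pair) or pair == ""):
            pair = None
        out.append(
            SampleInfo(
                sample_id=row["sample_id"],
                condition=row["condition"],
                cohort=row["cohort"],
                pair_id=pair,
            )
        )
    return out


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "condition": [s.condition for s in samples],
            "cohort": [s.cohort for s in samples],
            "pair_id": [s.pair_id if s.pair_id is not None else "" for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | Path,
    sample_sheet: str | Path | Sequence[SampleInfo],
    feature_class: str | Mapping[str, str] = "mRNA",
    log2_input: bool = True,
    missing: str = "error",
) -> ExpressionMatrix:
    """Read a tab-separated expression matrix.

    First column is feature_id, header row holds sample ids.  Sample order in
    the returned matrix follows the sample sheet.  ``feature_class`` is either
    one label applied to all features (the usual case: one file per RNA class)
    or a per-feature mapping.  ``missing='drop'`` removes rows with missing
    values instead of raising.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature row(s): {dups[:5]}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from None

    if isinstance(sample_sheet, (str, Path)):
        samples = read_sample_sheet(sample_sheet)
    else:
        samples = list(sample_sheet)
    sheet_ids = [s.sample_id for s in samples]
    unknown = [c for c in df.columns if c not in set(sheet_ids)]
    if unknown:
        raise FormatError(f"{path}: sample(s) absent from sample sheet: {unknown[:5]}")
    keep = [s for s in samples if s.sample_id in set(df.columns)]
    df = df[[s.sample_id for s in keep]]

    if df.isna().any().any():
        if missing == "drop":
            n_before = len(df)
            bad_rows = df.index[df.isna().any(axis=1)]
            for fid in bad_rows:
                logger.warning("dropping feature %s: missing values", fid)
            df = df.dropna(axis=0)
            logger.info("dropped %d/%d rows with missing values", n_before - len(df), n_before)
        else:
            raise FormatError(f"{path}: missing expression values (set missing='drop' to drop rows)")

    if not log2_input:
        if (df.to_numpy() < 0).any():
            raise FormatError("negative values incompatible with log2(x+1) transform")
        df = np.log2(df + 1.0)

    if isinstance(feature_class, str):
        fclass = pd.Series(feature_class, index=df.index)
    else:
        fclass = pd.Series({f: feature_class[f] for f in df.index})
    return ExpressionMatrix(values=df, feature_class=fclass, samples=keep)


def write_expression(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id", float_format=float_format)


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            set_id, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {set_id!r} has no members")
            if set_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set_id {set_id!r}")
            sets[set_id] = (desc, tuple(members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# FASTA sequences
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, moltype: str) -> SequenceSet:
    """Read FASTA sequences; U is normalized to T for seed matching."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    return SequenceSet(records=records, moltype=moltype)


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Relation tables and generic edge tables
# ---------------------------------------------------------------------------

_REL_COLUMNS = ["source", "target", "relation", "weight", "directed"]


def read_relations(path: str | Path, allow_self_loops: bool = False) -> RelationTable:
    """Read a KEGG-relation-like TSV: source, target, relation[, weight, directed]."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = {"source", "target"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: relation table missing column(s): {sorted(missing)}")
    edges = []
    for _, row in df.iterrows():
        edges.append(
            Relation(
                source=row["source"],
                target=row["target"],
                relation=str(row.get("relation", "interaction")),
                weight=float(row.get("weight", 1.0)),
                directed=bool(row.get("directed", True)),
            )
        )
    return RelationTable(edges=edges, allow_self_loops=allow_self_loops)


def write_relations(table: RelationTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.source, e.target, e.relation, e.weight, e.directed) for e in table.edges],
        columns=_REL_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path, min_confidence: float = 0.4) -> RelationTable:
    """Import a confidence-scored edge table (STRING-style export), keeping
    edges with score strictly greater than ``min_confidence``.

    Expected columns: source, target, score[, relation].  Retained edges are
    undirected with the score as weight.
    """
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = {"source", "target", "score"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: edge table missing column(s): {sorted(missing)}")
    n_total = len(df)
    df = df[df["score"].astype(float) > min_confidence]
    logger.info("edge table: kept %d/%d edges with score > %g", len(df), n_total, min_confidence)
    edges = [
        Relation(
            source=row["source"],
            target=row["target"],
            relation=str(row.get("relation", "ppi")),
            weight=float(row["score"]),
            directed=False,
        )
        for _, row in df.iterrows()
    ]
    return RelationTable(edges=edges)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t")
    df["patient_id"] = df["patient_id"].astype(str)
    return ClinicalTable(data=df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def write_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Export a network as GraphML (lossless for node/edge attributes), SIF
    (``source TAB relation TAB target`` rows), or a flat edge TSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(graph, str(path))
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, data in graph.edges(data=True):
                rel = data.get("relation", "interaction")
                fh.write(f"{u}\t{rel}\t{v}\n")
    elif format == "edge-tsv":
        rows = []
        for u, v, data in graph.edges(data=True):
            row = {"source": u, "target": v}
            row.update(data)
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {format!r} (use graphml, sif, or edge-tsv)")


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))


def validate_file(path: str | Path) -> str:
    """Best-effort detection + validation of a pipeline input file.

    Returns the detected kind; raises :class:`FormatError` on invalid content.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta"):
        read_fasta(path, moltype="transcript")
        return "fasta"
    if suffix == ".gmt":
        read_gmt(path)
        return "gmt"
    if suffix == ".graphml":
        read_network(path)
        return "graphml"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if {"sample_id", "condition", "cohort"} <= set(header):
        read_sample_sheet(path)
        return "sample_sheet"
    if {"source", "target"} <= set(header):
        if "score" in header:
            read_edge_table(path, min_confidence=-math.inf)
            return "edge_table"
        read_relations(path)
        return "relations"
    if {"patient_id", "time", "event", "endpoint"} <= set(header):
        read_clinical(path)
        return "clinical"
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: unrecognized format ({exc})") from None
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate feature rows")
    return "expression"
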