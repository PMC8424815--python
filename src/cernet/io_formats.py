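"""Readers and writers for the standard formats the pipeline touches.

All downstream stages consume only the domain types defined here:
:class:`Transcript`, :class:`GeneAnnotation` and :class:`ExpressionMatrix`.
Sequences are canonicalized to the DNA alphabet (U -> T) on read; genomic
coordinates are 1-based closed (GTF convention) everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Transcript",
    "Gene",
    "GeneAnnotation",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "export_network",
]

BIOTYPES = frozenset({"mRNA", "lncRNA_candidate", "lncRNA", "miRNA"})
UNITS = frozenset({"count", "RPKM", "TPM"})
_ALPHABET = frozenset("ACGTN")

_U_TO_T = str.maketrans("Uu", "Tt")


def canonicalize_seq(seq: str) -> str:
    """Uppercase and map U -> T (internal alphabet is DNA)."""
    return seq.translate(_U_TO_T).upper()


@dataclass(frozen=True)
class Transcript:
    """One sequence record with optional genomic placement.

    exons are 1-based closed intervals on ``chrom``, sorted ascending and
    non-overlapping. A miRNA must be 18-26 nt.
    """

    id: str
    seq: str
    biotype: str = "mRNA"
    chrom: str | None = None
    strand: str | None = None
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"transcript {self.id!r} has an empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-alphabet characters: "
                f"{sorted(bad)}"
            )
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.biotype == "miRNA" and not (18 <= len(self.seq) <= 26):
            raise ValueError(
                f"miRNA {self.id!r} has length {len(self.seq)}, expected 18-26 nt"
            )
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise ValueError(f"exon ({start}, {end}) has end < start")
            if start <= prev_end:
                raise ValueError("exons must be sorted ascending and non-overlapping")
            prev_end = end

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def span(self) -> tuple[int, int] | None:
        """Genomic span (min exon start, max exon end), or None if unplaced."""
        if not self.exons:
            return None
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def exon_count(self) -> int:
        # a transcript without recorded structure is treated as single-exon
        return len(self.exons) if self.exons else 1


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    # transcript_id -> ordered exon intervals (1-based closed)
    transcripts: Mapping[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    def introns(self) -> list[tuple[str, tuple[int, int]]]:
        """All (transcript_id, intron interval) pairs of this gene."""
        out = []
        for tx_id, exons in self.transcripts.items():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1 + 1:
                    out.append((tx_id, (e1 + 1, s2 - 1)))
        return out


@dataclass(frozen=True)
class GeneAnnotation:
    genes: tuple[Gene, ...] = ()

    def by_chrom(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.chrom, []).append(g)
        return out

    def __len__(self) -> int:
        return len(self.genes)


class ExpressionMatrix:
    """Features x samples abundance table with condition labels and a unit tag.

    Values are non-negative; every sample carries a condition label in
    {control, treated} and each condition has at least two samples.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        condition: Mapping[str, str],
        unit: str,
    ) -> None:
        if unit not in UNITS:
            raise ValueError(f"unknown unit {unit!r}, expected one of {sorted(UNITS)}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values (ragged rows?)")
        if (values.values < 0).any():
            raise ValueError("expression matrix contains negative values")
        missing = [s for s in values.columns if s not in condition]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        cond = {s: condition[s] for s in values.columns}
        bad = {c for c in cond.values() if c not in {"control", "treated"}}
        if bad:
            raise ValueError(f"invalid condition labels: {sorted(bad)}")
        for level in ("control", "treated"):
            n = sum(1 for c in cond.values() if c == level)
            if n < 2:
                raise ValueError(f"condition {level!r} has {n} samples, need >= 2")
        self.values = values.astype(float)
        self.values.index.name = "feature_id"
        self.condition = cond
        self.unit = unit

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, level: str) -> list[str]:
        return [s for s in self.sample_ids if self.condition[s] == level]

    def with_values(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.condition, unit)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ExpressionMatrix({len(self.feature_ids)} features x "
            f"{len(self.sample_ids)} samples, unit={self.unit})"
        )


def read_fasta(path: str | Path, biotype: str = "mRNA") -> list[Transcript]:
    """Read a FASTA file into Transcripts.

    The header token before the first whitespace is the id; sequences are
    uppercased with U -> T canonicalization. Duplicate ids, empty sequences
    and non-alphabet characters raise ValueError.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        rec_id = record.id
        if rec_id in seen:
            raise ValueError(f"duplicate id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = canonicalize_seq(str(record.seq))
        if not seq:
            raise ValueError(f"record {rec_id!r} in {path} has an empty sequence")
        transcripts.append(Transcript(id=rec_id, seq=seq, biotype=biotype))
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i : i + width] + "\n")


def _parse_attributes(attr_field: str) -> dict[str, str]:
    """Parse a column-9 attribute string (GTF 'key \"value\";' or GFF3 'key=value')."""
    attrs: dict[str, str] = {}
    if "=" in attr_field and '"' not in attr_field:
        for part in attr_field.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition("=")
            attrs[key.strip()] = value.strip()
    else:
        for part in attr_field.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            key, _, value = part.partition(" ")
            attrs[key.strip()] = value.strip().strip('"')
    return attrs


def _validate_annotation_lines(path: Path) -> tuple[int, bool]:
    """Pre-validate a GTF/GFF3 file, raising errors that carry line numbers.

    Returns (number of feature lines, whether explicit gene features exist).
    """
    n_features = 0
    has_genes = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields")
            _, _, ftype, start_s, end_s, _, _, _, attr_field = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start ({start}..{end})")
            attrs = _parse_attributes(attr_field)
            if ftype in {"gene", "exon"} and not (
                "gene_id" in attrs or "ID" in attrs or "Parent" in attrs
            ):
                raise ValueError(
                    f"{path}:{lineno}: {ftype} feature lacks gene_id (or ID/Parent)"
                )
            if ftype == "gene":
                has_genes = True
            n_features += 1
    return n_features, has_genes


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a GTF or GFF3 gene annotation via gffutils.

    Accepts gene/exon features; GFF3 is keyed on ID=/Parent= attributes and
    GTF on gene_id/transcript_id (gene extents inferred when absent).
    Coordinates stay 1-based closed. Empty files yield an empty annotation
    with a warning.
    """
    import gffutils

    path = Path(path)
    n_features, has_genes = _validate_annotation_lines(path)
    if n_features == 0:
        warnings.warn(f"annotation file {path} contains no features", stacklevel=2)
        return GeneAnnotation()

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        verbose=False,
        disable_infer_genes=has_genes,
        disable_infer_transcripts=has_genes,
    )

    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        transcripts: dict[str, list[tuple[int, int]]] = {}
        for ex in db.children(g, featuretype="exon"):
            tid = (
                ex.attributes.get("transcript_id", [None])[0]
                or ex.attributes.get("Parent", [g.id])[0]
            )
            transcripts.setdefault(tid, []).append((ex.start, ex.end))
        genes.append(
            Gene(
                gene_id=g.attributes.get("gene_id", [g.id])[0],
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                transcripts={
                    tid: tuple(sorted(ivals)) for tid, ivals in transcripts.items()
                },
            )
        )
    return GeneAnnotation(genes=tuple(genes))


def read_expression_matrix(
    path: str | Path,
    condition_map: Mapping[str, str],
    unit: str,
) -> ExpressionMatrix:
    """Read a TSV expression table (first column feature id, header row present)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged or missing values")
    return ExpressionMatrix(df, condition_map, unit)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def export_network(network, path_prefix: str | Path) -> tuple[Path, Path]:
    """Write a ceRNA network as Cytoscape-compatible SIF and GraphML files.

    The SIF uses relation tokens "targets" (miRNA->lncRNA, miRNA->mRNA) and
    "competes" (lncRNA-mRNA). GraphML nodes carry node_type; edges carry
    relation and, where defined, pcc and cerna_score.
    """
    import networkx as nx

    prefix = Path(path_prefix)
    sif_path = prefix.with_suffix(".sif")
    graphml_path = prefix.with_suffix(".graphml")

    graph = network.graph
    with open(sif_path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{data['relation']}\t{b}\n")

    out = nx.Graph()
    for node, data in sorted(graph.nodes(data=True)):
        out.add_node(node, node_type=data["node_type"])
    for a, b, data in sorted(graph.edges(data=True)):
        attrs = {k: v for k, v in data.items() if v is not None}
        out.add_edge(a, b, **attrs)
    nx.write_graphml(out, graphml_path, named_key_ids=True)
    return sif_path, graphml_path
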