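"""lncRNA candidate filtering, positional classification and summaries.

Candidates must be longer than 200 bp and show no substantial coding
potential; here coding potential is approximated by the longest ATG-initiated,
stop-terminated open reading frame on the given strand (dedicated classifiers
such as CPAT/CNCI/CPC are out of scope). Positional classes relative to a
gene annotation follow the usual conventions: intergenic (no gene overlap),
antisense (overlaps an exon of an opposite-strand gene), intronic (entirely
within one intron of a same-strand gene), with precedence
antisense > intronic > ambiguous on multiple hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GeneAnnotation, Transcript

__all__ = [
    "LncRNAClass",
    "TranscriptSummary",
    "longest_orf_length",
    "filter_lncrna_candidates",
    "classify_positional",
    "summarize_transcripts",
    "classification_table",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class LncRNAClass:
    transcript_id: str
    positional_class: str = "unclassified"
    passed_filters: bool = True
    fail_reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.passed_filters and not self.fail_reasons:
            raise ValueError("failed candidates must carry at least one fail reason")


@dataclass(frozen=True)
class TranscriptSummary:
    """Length/exon-count distributions of a transcript set.

    length_histogram keys are bin lower bounds: 0 collects lengths <= 200,
    then 100-bp bins starting at 201 (201-300, 301-400, ...).
    """

    length_histogram: dict[int, int] = field(default_factory=dict)
    exon_count_histogram: dict[int, int] = field(default_factory=dict)
    fraction_len_201_1900: float = 0.0
    fraction_exons_le3: float = 0.0


def longest_orf_length(seq: str) -> int:
    """Length in nt (ATG through stop codon inclusive) of the longest
    stop-terminated ORF on the given strand, over all three frames.

    ORFs running off the 3' end without a stop codon do not count.
    """
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def filter_lncrna_candidates(
    transcripts: list[Transcript],
    min_length: int = 200,
    max_orf_nt: int = 300,
) -> list[LncRNAClass]:
    """Apply the lncRNA length and coding-potential filters.

    A candidate fails iff len(seq) <= min_length (the length rule is strict:
    "larger than 200 bp") or its longest ORF is >= max_orf_nt.
    """
    results = []
    for t in transcripts:
        reasons = []
        if len(t.seq) <= min_length:
            reasons.append("too_short")
        if longest_orf_length(t.seq) >= max_orf_nt:
            reasons.append("coding_orf")
        results.append(
            LncRNAClass(
                transcript_id=t.id,
                passed_filters=not reasons,
                fail_reasons=tuple(reasons),
            )
        )
    return results


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_positional(transcript: Transcript, annotation: GeneAnnotation) -> str:
    """Assign a positional class in {intergenic, antisense, intronic, ambiguous}.

    Deterministic and independent of gene order: all genes are examined and
    the class with highest precedence (antisense > intronic) wins.
    """
    if transcript.chrom is None or transcript.strand is None or not transcript.exons:
        raise ValueError(f"unplaced transcript {transcript.id!r}")
    span = transcript.span
    assert span is not None

    overlapping = [
        g
        for g in annotation.genes
        if g.chrom == transcript.chrom and _overlaps(span, (g.start, g.end))
    ]
    if not overlapping:
        return "intergenic"

    antisense = any(
        g.strand != transcript.strand
        and any(
            _overlaps(t_exon, g_exon)
            for _, exons in g.transcripts.items()
            for g_exon in exons
            for t_exon in transcript.exons
        )
        for g in overlapping
    )
    if antisense:
        return "antisense"

    intronic = any(
        g.strand == transcript.strand
        and any(
            intron[0] <= span[0] and span[1] <= intron[1] for _, intron in g.introns()
        )
        for g in overlapping
    )
    if intronic:
        return "intronic"
    return "ambiguous"


def summarize_transcripts(transcripts: list[Transcript]) -> TranscriptSummary:
    """Length and exon-count histograms plus the two headline fractions."""
    if not transcripts:
        raise ValueError("cannot summarize an empty transcript list")
    length_hist: dict[int, int] = {}
    exon_hist: dict[int, int] = {}
    n_in_range = 0
    n_few_exons = 0
    for t in transcripts:
        length = len(t.seq)
        bin_start = 0 if length <= 200 else 201 + 100 * ((length - 201) // 100)
        length_hist[bin_start] = length_hist.get(bin_start, 0) + 1
        exon_hist[t.exon_count] = exon_hist.get(t.exon_count, 0) + 1
        if 201 <= length <= 1900:
            n_in_range += 1
        if t.exon_count <= 3:
            n_few_exons += 1
    n = len(transcripts)
    return TranscriptSummary(
        length_histogram=dict(sorted(length_hist.items())),
        exon_count_histogram=dict(sorted(exon_hist.items())),
        fraction_len_201_1900=n_in_range / n,
        fraction_exons_le3=n_few_exons / n,
    )


def classification_table(
    transcripts: list[Transcript],
    annotation: GeneAnnotation,
    min_length: int = 200,
    max_orf_nt: int = 300,
) -> pd.DataFrame:
    """Per-transcript TSV-ready table: filters plus positional class.

    Positional classes are computed only for placed transcripts; unplaced
    ones are reported as 'unplaced'.
    """
    filtered = filter_lncrna_candidates(transcripts, min_length, max_orf_nt)
    rows = []
    for t, f in zip(transcripts, filtered):
        placed = t.chrom is not None and t.strand is not None and bool(t.exons)
        rows.append(
            {
                "transcript_id": t.id,
                "length": len(t.seq),
                "exon_count": t.exon_count,
                "positional_class": (
                    classify_positional(t, annotation) if placed else "unplaced"
                ),
                "passed_filters": f.passed_filters,
                "fail_reasons": ",".join(f.fail_reasons),
            }
        )
    return pd.DataFrame(rows)
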