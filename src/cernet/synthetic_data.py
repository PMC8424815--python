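"""Synthetic datasets with planted ceRNA triplets and full ground truth.

The generator emulates the experimental design the pipeline assumes: a
control vs treated comparison in which a set of miRNAs is induced
(miRNA-up) and represses both an lncRNA and an mRNA carrying its response
elements (targets-down), creating negative miRNA-target and positive
lncRNA-mRNA co-expression among planted triplets. Sequences carry 1-3
perfect reverse-complement MREs per planted target; expression noise is
log-normal (Gaussian on the log2 scale); everything is reproducible from a
single seed.

When planted assignments reuse a miRNA, every (lncRNA, miRNA, mRNA)
combination within that miRNA's assigned sets is a true triplet — the shared
repressor couples all of them — so the recorded ground-truth triplet set is
the per-miRNA closure of the drawn assignments, not just the assignments
themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    Gene,
    GeneAnnotation,
    Transcript,
    write_expression_matrix,
    write_fasta,
)

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "generate_sequences",
    "generate_annotation",
    "generate_expression",
    "write_bundle",
    "load_truth",
]

_BASES = np.array(list("ACGT"))
_REVCOMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class SimulationParams:
    """Study-design parameters for the synthetic dataset.

    Defaults model a drought-style two-condition small/long RNA experiment:
    planted miRNAs are induced 4-fold (log2FC 2) under treatment and repress
    their targets with strength beta = 1.5 on the log2 scale, under log-normal
    noise of sd 0.25 (log2 units). Six samples per condition keep the
    r/p co-expression thresholds attainable at this noise level.
    """

    n_mirna: int = 20
    n_mrna: int = 200
    n_lncrna: int = 50
    n_planted_triplets: int = 30
    samples_per_condition: int = 6
    mirna_len: int = 21
    mrna_len: int = 1500
    lncrna_len: int = 800
    sites_min: int = 1
    sites_max: int = 3
    repression_strength: float = 1.5  # beta, log2-scale
    noise_sd: float = 0.25  # sigma, log2-scale
    mirna_condition_log2fc: float = 2.0
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mirna", "n_mrna", "n_lncrna", "samples_per_condition"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted_triplets < 0:
            raise ValueError("n_planted_triplets must be >= 0")
        if self.n_planted_triplets > min(self.n_mrna, self.n_lncrna):
            raise ValueError(
                "n_planted_triplets must be <= min(n_mrna, n_lncrna): "
                "each planted assignment uses a distinct lncRNA and mRNA"
            )
        if not (1 <= self.sites_min <= self.sites_max):
            raise ValueError("need 1 <= sites_min <= sites_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure: triplets (per-miRNA closure of the drawn
    assignments), MRE sites, true DE labels and expected lncRNA classes."""

    planted_triplets: list[tuple[str, str, str]] = field(default_factory=list)
    assignments: list[tuple[str, str, str]] = field(default_factory=list)
    planted_sites: list[dict] = field(default_factory=list)
    true_de: dict[str, str] = field(default_factory=dict)
    lncrna_classes: dict[str, str] = field(default_factory=dict)
    trait_feature: str | None = None


def _rngs(seed: int) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)  # seq, placement, expr


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_positions(
    rng: np.random.Generator, seq_len: int, k: int, site_len: int
) -> list[int]:
    """k 0-based site starts with pairwise separation >= 2*site_len."""
    min_sep = 2 * site_len
    if seq_len < (k - 1) * min_sep + site_len:
        raise ValueError(
            f"sequence of {seq_len} nt too short for {k} sites of {site_len} nt"
        )
    while True:  # rejection sampling; cheap at k <= 3
        starts = sorted(rng.integers(0, seq_len - site_len + 1, size=k).tolist())
        if all(b - a >= min_sep for a, b in zip(starts, starts[1:])):
            return starts


def generate_sequences(
    params: SimulationParams,
) -> tuple[list[Transcript], GroundTruth]:
    """Random transcripts with perfect MREs planted into triplet members.

    miRNA i of planted assignment j is mirnas[j mod n_mirna]; lncRNAs and
    mRNAs are drawn without replacement, so each hosts sites of exactly one
    miRNA. Sites are the miRNA's reverse complement, overwritten in place at
    positions separated by >= 2 x miRNA length.
    """
    rng, _, _ = _rngs(params.seed)
    mirna_ids = [f"osa-miR{i + 1:03d}" for i in range(params.n_mirna)]
    mrna_ids = [f"LOC_Os{i + 1:05d}" for i in range(params.n_mrna)]
    lnc_ids = [f"TCONS_{i + 1:08d}" for i in range(params.n_lncrna)]

    mirna_seqs = {m: _random_seq(rng, params.mirna_len) for m in mirna_ids}
    mrna_seqs = {m: _random_seq(rng, params.mrna_len) for m in mrna_ids}
    lnc_seqs = {m: _random_seq(rng, params.lncrna_len) for m in lnc_ids}

    truth = GroundTruth()
    lnc_pick = rng.permutation(params.n_lncrna)[: params.n_planted_triplets]
    mrna_pick = rng.permutation(params.n_mrna)[: params.n_planted_triplets]

    for j in range(params.n_planted_triplets):
        mid = mirna_ids[j % params.n_mirna]
        lid = lnc_ids[lnc_pick[j]]
        gid = mrna_ids[mrna_pick[j]]
        truth.assignments.append((lid, mid, gid))
        site = _revcomp(mirna_seqs[mid])
        for tid, seqs, length in (
            (lid, lnc_seqs, params.lncrna_len),
            (gid, mrna_seqs, params.mrna_len),
        ):
            k = int(rng.integers(params.sites_min, params.sites_max + 1))
            seq = list(seqs[tid])
            for start in _plant_positions(rng, length, k, params.mirna_len):
                seq[start : start + params.mirna_len] = site
                truth.planted_sites.append(
                    {
                        "mirna_id": mid,
                        "target_id": tid,
                        "target_start": start + 1,  # 1-based
                    }
                )
            seqs[tid] = "".join(seq)

    # ground-truth triplet set: per-miRNA closure of the assignments
    lncs_of: dict[str, set[str]] = {}
    mrnas_of: dict[str, set[str]] = {}
    for lid, mid, gid in truth.assignments:
        lncs_of.setdefault(mid, set()).add(lid)
        mrnas_of.setdefault(mid, set()).add(gid)
    truth.planted_triplets = sorted(
        (lid, mid, gid)
        for mid in lncs_of
        for lid in lncs_of[mid]
        for gid in mrnas_of[mid]
    )

    transcripts = (
        [Transcript(id=m, seq=mirna_seqs[m], biotype="miRNA") for m in mirna_ids]
        + [Transcript(id=m, seq=mrna_seqs[m], biotype="mRNA") for m in mrna_ids]
        + [
            Transcript(id=m, seq=lnc_seqs[m], biotype="lncRNA_candidate")
            for m in lnc_ids
        ]
    )
    return transcripts, truth


_GENE_SPACING = 20_000
_INTRON_LEN = 2_000


def generate_annotation(
    params: SimulationParams, transcripts: list[Transcript], truth: GroundTruth
) -> tuple[list[Transcript], GeneAnnotation]:
    """Place transcripts on a toy chromosome and build the matching annotation.

    Every mRNA becomes a 3-exon '+'-strand gene at regular spacing; lncRNAs
    cycle through intergenic / antisense / intronic placements relative to a
    host gene, recorded in truth.lncrna_classes. miRNAs stay unplaced.
    """
    mrnas = [t for t in transcripts if t.biotype == "mRNA"]
    lncs = [t for t in transcripts if t.biotype == "lncRNA_candidate"]
    others = [t for t in transcripts if t.biotype not in {"mRNA", "lncRNA_candidate"}]

    placed: dict[str, Transcript] = {}
    genes = []
    gene_start_of: dict[int, int] = {}
    exon1_len_of: dict[int, int] = {}
    for i, t in enumerate(mrnas):
        start = 1 + i * _GENE_SPACING
        third = len(t.seq) // 3
        exon_lens = [third, third, len(t.seq) - 2 * third]
        exons = []
        pos = start
        for el in exon_lens:
            exons.append((pos, pos + el - 1))
            pos += el + _INTRON_LEN
        span_end = exons[-1][1]
        gene_start_of[i] = start
        exon1_len_of[i] = exon_lens[0]
        placed[t.id] = Transcript(
            id=t.id,
            seq=t.seq,
            biotype=t.biotype,
            chrom="Chr1",
            strand="+",
            exons=tuple(exons),
        )
        genes.append(
            Gene(
                gene_id=t.id,
                chrom="Chr1",
                strand="+",
                start=start,
                end=span_end,
                transcripts={f"{t.id}.1": tuple(exons)},
            )
        )

    classes = ("intergenic", "antisense", "intronic")
    for i, t in enumerate(lncs):
        cls = classes[i % 3]
        host = i % len(mrnas)
        gstart = gene_start_of[host]
        gene_span = len(mrnas[host].seq) + 2 * _INTRON_LEN
        if cls == "intergenic":
            start = gstart + gene_span + 3_000
            strand = "+"
        elif cls == "antisense":
            start = gstart  # overlaps exon 1 of the host gene
            strand = "-"
        else:  # intronic: inside intron 1, same strand
            start = gstart + exon1_len_of[host] + 100
            strand = "+"
        placed[t.id] = Transcript(
            id=t.id,
            seq=t.seq,
            biotype=t.biotype,
            chrom="Chr1",
            strand=strand,
            exons=((start, start + len(t.seq) - 1),),
        )
        truth.lncrna_classes[t.id] = cls

    out = [placed.get(t.id, t) for t in transcripts]
    return out, GeneAnnotation(genes=tuple(genes))


def generate_expression(
    params: SimulationParams,
    transcripts: list[Transcript],
    truth: GroundTruth,
) -> tuple[ExpressionMatrix, pd.Series, GroundTruth]:
    """Log-normal expression with the planted repression structure.

    Planted miRNAs: log2 abundance = baseline + log2FC x 1[treated] + noise.
    Planted targets: baseline - beta x (their miRNA's centered log2
    abundance) + noise, which makes miRNA-target correlations negative and
    lncRNA-mRNA correlations within a triplet positive. Background features
    have no condition effect. The trait is a linear readout of the first
    planted mRNA's abundance plus noise.
    """
    _, _, rng = _rngs(params.seed)
    n = params.samples_per_condition
    samples = [f"C{i + 1}" for i in range(n)] + [f"T{i + 1}" for i in range(n)]
    condition = {s: ("control" if s.startswith("C") else "treated") for s in samples}
    treated = np.array([0.0] * n + [1.0] * n)

    feature_ids = [t.id for t in transcripts]
    planted_mirnas = {mid for _, mid, _ in truth.assignments}
    mirna_of_target: dict[str, str] = {}
    for lid, mid, gid in truth.assignments:
        mirna_of_target[lid] = mid
        mirna_of_target[gid] = mid

    baselines = {
        fid: rng.normal(params.baseline_log2_mean, params.baseline_log2_sd)
        for fid in feature_ids
    }
    log2_expr: dict[str, np.ndarray] = {}
    # miRNAs first: targets reference their realized (noisy) profiles
    for t in transcripts:
        if t.biotype != "miRNA":
            continue
        fc = params.mirna_condition_log2fc if t.id in planted_mirnas else 0.0
        log2_expr[t.id] = (
            baselines[t.id] + fc * treated + rng.normal(0, params.noise_sd, 2 * n)
        )
    for t in transcripts:
        if t.biotype == "miRNA":
            continue
        noise = rng.normal(0, params.noise_sd, 2 * n)
        mid = mirna_of_target.get(t.id)
        if mid is not None:
            mir = log2_expr[mid]
            log2_expr[t.id] = (
                baselines[t.id]
                - params.repression_strength * (mir - mir.mean())
                + noise
            )
        else:
            log2_expr[t.id] = baselines[t.id] + noise

    values = pd.DataFrame(
        {s: [2.0 ** log2_expr[f][j] for f in feature_ids] for j, s in enumerate(samples)},
        index=feature_ids,
    )
    matrix = ExpressionMatrix(values, condition, unit="RPKM")

    truth.true_de = {
        fid: (
            "up"
            if fid in planted_mirnas
            else "down" if fid in mirna_of_target else "ns"
        )
        for fid in feature_ids
    }

    if truth.assignments:
        truth.trait_feature = truth.assignments[0][2]
        base = values.loc[truth.trait_feature].to_numpy()
        noise_sd = 0.2 * base.std(ddof=1) if base.std(ddof=1) > 0 else 0.0
        trait_values = 0.8 * base + rng.normal(0, noise_sd, 2 * n)
    else:
        trait_values = rng.normal(0, 1, 2 * n)
    trait = pd.Series(trait_values, index=samples, name="trait")
    return matrix, trait, truth


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tcernet\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tid, exons in g.transcripts.items():
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}";'
                for s, e in exons:
                    fh.write(
                        f"{g.chrom}\tcernet\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )


def write_bundle(params: SimulationParams, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture bundle.

    Files: mirna.fasta, mrna.fasta, lncrna.fasta, annotation.gtf,
    expression.tsv, conditions.tsv, trait.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = generate_sequences(params)
    transcripts, annotation = generate_annotation(params, transcripts, truth)
    matrix, trait, truth = generate_expression(params, transcripts, truth)

    paths = {
        "mirna_fasta": outdir / "mirna.fasta",
        "mrna_fasta": outdir / "mrna.fasta",
        "lncrna_fasta": outdir / "lncrna.fasta",
        "annotation": outdir / "annotation.gtf",
        "expression": outdir / "expression.tsv",
        "conditions": outdir / "conditions.tsv",
        "trait": outdir / "trait.tsv",
        "truth": outdir / "truth.json",
    }
    by_type = {
        "miRNA": paths["mirna_fasta"],
        "mRNA": paths["mrna_fasta"],
        "lncRNA_candidate": paths["lncrna_fasta"],
    }
    for biotype, path in by_type.items():
        write_fasta([t for t in transcripts if t.biotype == biotype], path)
    # the GTF carries the coding genes plus the lncRNA placements, as an
    # assembly GTF would
    lnc_genes = tuple(
        Gene(
            gene_id=t.id,
            chrom=t.chrom,
            strand=t.strand,
            start=t.exons[0][0],
            end=t.exons[-1][1],
            transcripts={f"{t.id}.1": t.exons},
        )
        for t in transcripts
        if t.biotype == "lncRNA_candidate" and t.exons
    )
    write_gtf(GeneAnnotation(annotation.genes + lnc_genes), paths["annotation"])
    write_expression_matrix(matrix, paths["expression"])
    pd.DataFrame(
        {"sample_id": matrix.sample_ids, "condition": [matrix.condition[s] for s in matrix.sample_ids]}
    ).to_csv(paths["conditions"], sep="\t", index=False)
    trait.rename_axis("sample_id").to_frame().to_csv(paths["trait"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(asdict(truth), fh, indent=1, sort_keys=True)
    return paths


def load_truth(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        raw = json.load(fh)
    return GroundTruth(
        planted_triplets=[tuple(t) for t in raw["planted_triplets"]],
        assignments=[tuple(t) for t in raw["assignments"]],
        planted_sites=raw["planted_sites"],
        true_de=raw["true_de"],
        lncrna_classes=raw.get("lncrna_classes", {}),
        trait_feature=raw.get("trait_feature"),
    )
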