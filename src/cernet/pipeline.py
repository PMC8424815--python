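"""End-to-end orchestration: annotate -> diffexpr -> targeting -> coexpr ->
cerna_network, with a run manifest and a planted-truth evaluator.

All outputs are deterministic functions of the inputs and configuration, so
rerunning a pipeline on the same inputs reproduces every file byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import annotate as _annotate
from . import cerna_network as _net
from . import coexpr as _coexpr
from . import diffexpr as _de
from . import io_formats as _io
from . import targeting as _targeting
from .synthetic_data import GroundTruth

__all__ = ["PipelineConfig", "run_pipeline", "evaluate_triplets", "read_conditions"]

logger = logging.getLogger("cernet")


@dataclass
class PipelineConfig:
    """Declarative configuration of one pipeline run."""

    mirna_fasta: str
    mrna_fasta: str
    lncrna_fasta: str
    expression: str
    conditions: str
    outdir: str
    annotation: str | None = None
    key_genes: str | None = None
    trait: str | None = None
    expression_unit: str = "RPKM"
    # stage parameters
    min_lnc_length: int = 200
    max_orf_nt: int = 300
    pseudo: float = 1.0
    log2fc_cutoff: float = 1.0
    padj_cutoff: float = 0.05
    duplex: _targeting.DuplexParams = field(default_factory=_targeting.DuplexParams)
    r_max: float = -0.7
    r_min: float = 0.7
    p_max: float = 0.01
    score_min: float = 0.5
    score_mode: str = "sites"
    de_restrict: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        duplex = _targeting.DuplexParams(**raw.pop("duplex", {}))
        return cls(duplex=duplex, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def read_conditions(path: str | Path) -> dict[str, str]:
    """TSV with columns sample_id, condition."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, condition")
    return dict(zip(df["sample_id"].astype(str), df["condition"].astype(str)))


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write per-stage TSVs, the network and a manifest.

    Returns a summary dict with per-stage feature counts and key paths.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- load inputs ---------------------------------------------------
    for name in ("mirna_fasta", "mrna_fasta", "lncrna_fasta", "expression", "conditions"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"input {name} not found: {p}")
    mirnas = _io.read_fasta(config.mirna_fasta, biotype="miRNA")
    mrnas = _io.read_fasta(config.mrna_fasta, biotype="mRNA")
    lnc_candidates = _io.read_fasta(config.lncrna_fasta, biotype="lncRNA_candidate")
    condition_map = read_conditions(config.conditions)
    expr = _io.read_expression_matrix(
        config.expression, condition_map, config.expression_unit
    )
    annotation = (
        _io.read_annotation(config.annotation)
        if config.annotation
        else _io.GeneAnnotation()
    )
    logger.info(
        "loaded %d miRNAs, %d mRNAs, %d lncRNA candidates, %d x %d expression",
        len(mirnas), len(mrnas), len(lnc_candidates),
        len(expr.feature_ids), len(expr.sample_ids),
    )

    counts: dict[str, int] = {}

    # --- stage 1: annotate ---------------------------------------------
    # lncRNA placements are taken from GTF records whose gene_id matches the
    # candidate id (assembly GTFs list candidate transcripts alongside coding
    # genes); positional classes are assigned against the coding genes only.
    mrna_id_set = {t.id for t in mrnas}
    coding_annotation = _io.GeneAnnotation(
        genes=tuple(g for g in annotation.genes if g.gene_id in mrna_id_set)
    )
    placement = {g.gene_id: g for g in annotation.genes}
    placed_candidates = []
    for t in lnc_candidates:
        g = placement.get(t.id)
        if g is not None and g.transcripts:
            exons = next(iter(g.transcripts.values()))
            t = _io.Transcript(
                id=t.id, seq=t.seq, biotype=t.biotype,
                chrom=g.chrom, strand=g.strand, exons=exons,
            )
        placed_candidates.append(t)
    class_df = _annotate.classification_table(
        placed_candidates, coding_annotation, config.min_lnc_length, config.max_orf_nt
    )
    class_df.to_csv(outdir / "lncrna_classes.tsv", sep="\t", index=False)
    kept_lnc_ids = set(class_df.loc[class_df["passed_filters"], "transcript_id"])
    lncrnas = [t for t in lnc_candidates if t.id in kept_lnc_ids]
    counts["lncrna_candidates"] = len(lnc_candidates)
    counts["lncrna_kept"] = len(lncrnas)
    logger.info("annotate: %d/%d lncRNA candidates kept", len(lncrnas), len(lnc_candidates))

    # --- stage 2: differential expression -------------------------------
    de_records = _de.differential_expression(
        expr, config.pseudo, config.log2fc_cutoff, config.padj_cutoff
    )
    de_df = _de.de_table(de_records)
    de_df.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    de_status = {r.feature_id: r.status for r in de_records}
    counts["de_up"] = sum(1 for r in de_records if r.status == "up")
    counts["de_down"] = sum(1 for r in de_records if r.status == "down")
    logger.info("diffexpr: %d up, %d down", counts["de_up"], counts["de_down"])

    # --- stage 3: MRE targeting -----------------------------------------
    targets = lncrnas + mrnas
    all_sites = []
    for m in mirnas:
        for t in targets:
            all_sites.extend(_targeting.find_mre_sites(m, t, config.duplex))
    mre_counts: dict[tuple[str, str], int] = {}
    for s in all_sites:
        mre_counts[(s.mirna_id, s.target_id)] = (
            mre_counts.get((s.mirna_id, s.target_id), 0) + 1
        )
    _targeting.sites_table(all_sites).to_csv(outdir / "mre_sites.tsv", sep="\t", index=False)
    counts["mre_sites"] = len(all_sites)
    counts["mre_pairs"] = len(mre_counts)
    logger.info("targeting: %d sites over %d pairs", len(all_sites), len(mre_counts))

    # --- stage 4: co-expression -----------------------------------------
    target_kinds = {t.id: "lncRNA" for t in lncrnas}
    target_kinds.update({t.id: "mRNA" for t in mrnas})
    interactions = _coexpr.mirna_target_interactions(
        mre_counts, expr, target_kinds, config.r_max, config.p_max
    )
    mir_lnc = [i for i in interactions if i.target_kind == "lncRNA"]
    mir_mrna = [i for i in interactions if i.target_kind == "mRNA"]
    lnc_mrna = _coexpr.lncrna_mrna_pairs(
        expr,
        [t.id for t in lncrnas],
        [t.id for t in mrnas],
        config.r_min,
        config.p_max,
    )
    pd.DataFrame([i.__dict__ for i in interactions]).to_csv(
        outdir / "mirna_target_interactions.tsv", sep="\t", index=False
    )
    pd.DataFrame([c.__dict__ for c in lnc_mrna]).to_csv(
        outdir / "lncrna_mrna_pairs.tsv", sep="\t", index=False
    )
    counts["mir_lnc_interactions"] = len(mir_lnc)
    counts["mir_mrna_interactions"] = len(mir_mrna)
    counts["lnc_mrna_pairs"] = len(lnc_mrna)
    logger.info(
        "coexpr: %d miRNA-lncRNA, %d miRNA-mRNA, %d lncRNA-mRNA pairs",
        len(mir_lnc), len(mir_mrna), len(lnc_mrna),
    )

    # --- stage 5: ceRNA network -----------------------------------------
    lnc_ids = {t.id for t in lncrnas}
    lnc_mre_counts = {k: v for k, v in mre_counts.items() if k[1] in lnc_ids}
    triplets = _net.assemble_triplets(
        mir_lnc,
        mir_mrna,
        lnc_mrna,
        lnc_mre_counts,
        score_min=config.score_min,
        de_status=de_status if config.de_restrict else None,
        score_mode=config.score_mode,
    )
    if config.key_genes:
        key_genes = {
            line.strip()
            for line in Path(config.key_genes).read_text().splitlines()
            if line.strip()
        }
        triplets = _net.restrict_to_genes(triplets, key_genes)
    network = _net.build_network(triplets)
    _net.triplet_table(triplets).to_csv(outdir / "triplets.tsv", sep="\t", index=False)
    _net.degree_table(network).to_csv(outdir / "degree.tsv", sep="\t", index=False)
    _io.export_network(network, outdir / "network")
    counts["triplets"] = len(triplets)
    counts["network_nodes"] = len(network.nodes)
    counts["network_edges"] = network.n_edges
    logger.info(
        "network: %d triplets, %d nodes, %d edges, hub %s",
        len(triplets), len(network.nodes), network.n_edges, network.primary_hub,
    )

    # --- optional: expression-trait correlations ------------------------
    if config.trait:
        trait_df = pd.read_csv(config.trait, sep="\t", index_col=0)
        trait_vec = trait_df.iloc[:, 0].reindex(expr.sample_ids)
        rows = []
        for node in sorted(network.nodes):
            if node in expr.values.index:
                res = _coexpr.trait_correlation(
                    expr.values.loc[node], trait_vec.to_numpy(), node, "trait"
                )
                rows.append({"feature_id": node, "r": res.r, "pvalue": res.pvalue})
        pd.DataFrame(rows, columns=["feature_id", "r", "pvalue"]).to_csv(
            outdir / "trait_correlations.tsv", sep="\t", index=False
        )

    manifest = {
        "config": config.to_dict(),
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in (
                "mirna_fasta", "mrna_fasta", "lncrna_fasta",
                "expression", "conditions", "annotation", "key_genes", "trait",
            )
            if getattr(config, name)
        },
        "stages": ["annotate", "diffexpr", "targeting", "coexpr", "cerna_network"],
        "counts": counts,
        "hubs": sorted(network.hubs),
        "primary_hub": network.primary_hub,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def evaluate_triplets(
    reported: list[tuple[str, str, str]],
    truth: GroundTruth,
    expr: _io.ExpressionMatrix,
    r_max: float = -0.7,
    r_min: float = 0.7,
    p_max: float = 0.01,
) -> dict:
    """Precision/recall of reported triplets against the planted truth.

    precision = |reported ∩ planted| / |reported| (None when nothing was
    reported); recall = |reported ∩ planted| / |eligible|, where a planted
    triplet is eligible iff its realized correlations pass the configured
    thresholds (miRNA-lncRNA and miRNA-mRNA negative, lncRNA-mRNA positive).
    """
    planted = {tuple(t) for t in truth.planted_triplets}
    values = expr.values
    missing = {f for t in planted for f in t if f not in values.index}
    if missing:
        raise ValueError(f"truth features missing from expression: {sorted(missing)[:5]}")

    def _passes(lnc: str, mid: str, mrna: str) -> bool:
        ml = _coexpr.pearson(values.loc[mid], values.loc[lnc])
        mm = _coexpr.pearson(values.loc[mid], values.loc[mrna])
        lm = _coexpr.pearson(values.loc[lnc], values.loc[mrna])
        return (
            ml.r < r_max and ml.pvalue < p_max
            and mm.r < r_max and mm.pvalue < p_max
            and lm.r > r_min and lm.pvalue < p_max
        )

    eligible = {t for t in planted if _passes(*t)}
    reported_set = {tuple(t) for t in reported}
    tp = len(reported_set & planted)
    precision = tp / len(reported_set) if reported_set else None
    recall = tp / len(eligible) if eligible else None
    return {
        "n_reported": len(reported_set),
        "n_planted": len(planted),
        "n_eligible": len(eligible),
        "true_positives": tp,
        "precision": precision,
        "recall": recall,
    }
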