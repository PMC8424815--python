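"""ceRNA scoring, triplet assembly, network construction and hub analysis.

A triplet (lncRNA L, miRNA m, mRNA M) is emitted when m targets both L and M
(sequence + negative co-expression evidence), L and M are positively
co-expressed, and the lncRNA's ceRNA score for M clears the threshold. The
ceRNA score of an (L, M) pair is the fraction of the lncRNA's MREs
attributable to miRNAs shared with the mRNA:

    score(L, M) = sum of L's MRE counts over shared miRNAs
                  / sum of all L's MRE counts

("sites" mode; a "species" mode counting shared miRNA species instead of
sites is available). The network has one node per molecule, edges
miRNA-lncRNA and miRNA-mRNA ("targets") and lncRNA-mRNA ("competes"); the
hub is the node of highest degree (all ties reported, with the
lexicographically smallest id designated primary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .coexpr import CorrelationResult, TargetInteraction

__all__ = [
    "CeRNAPair",
    "Triplet",
    "CeRNANetwork",
    "cerna_score",
    "assemble_triplets",
    "restrict_to_genes",
    "build_network",
    "triplet_table",
    "degree_table",
    "SCORE_MIN",
]

SCORE_MIN = 0.5


@dataclass(frozen=True)
class CeRNAPair:
    lncrna_id: str
    mrna_id: str
    shared_mirnas: frozenset[str]
    cerna_score: float
    pcc: float
    pcc_pvalue: float


@dataclass(frozen=True)
class Triplet:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    cerna_score: float
    lnc_mrna_pcc: float
    mir_lnc_pcc: float
    mir_mrna_pcc: float

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.lncrna_id, self.mirna_id, self.mrna_id)


class CeRNANetwork:
    """Typed tripartite graph over {lncRNA, miRNA, mRNA} nodes."""

    def __init__(self, graph: nx.Graph) -> None:
        self.graph = graph

    @property
    def nodes(self) -> dict[str, str]:
        return {n: d["node_type"] for n, d in self.graph.nodes(data=True)}

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    @property
    def hubs(self) -> set[str]:
        deg = self.degree
        if not deg:
            return set()
        top = max(deg.values())
        return {n for n, d in deg.items() if d == top}

    @property
    def primary_hub(self) -> str | None:
        hubs = self.hubs
        return min(hubs) if hubs else None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def cerna_score(
    lnc_mre_counts: Mapping[str, int],
    shared_mirnas: Iterable[str],
    mode: str = "sites",
) -> float:
    """ceRNA score of an lncRNA-mRNA pair.

    lnc_mre_counts maps miRNA id -> MRE count on the lncRNA. In "sites" mode
    the score is the shared-site fraction (default); in "species" mode it is
    the fraction of the lncRNA's miRNA species that are shared.
    """
    if not lnc_mre_counts:
        raise ValueError("lncRNA has no MREs")
    shared = set(shared_mirnas)
    extra = shared - set(lnc_mre_counts)
    if extra:
        raise ValueError(f"shared miRNAs absent from lncRNA MRE counts: {sorted(extra)}")
    if mode == "sites":
        num = sum(lnc_mre_counts[m] for m in shared)
        den = sum(lnc_mre_counts.values())
    elif mode == "species":
        num = len(shared)
        den = len(lnc_mre_counts)
    else:
        raise ValueError(f"unknown score mode {mode!r}")
    return num / den


def assemble_triplets(
    mir_lnc: list[TargetInteraction],
    mir_mrna: list[TargetInteraction],
    lnc_mrna: list[CorrelationResult],
    lnc_mre_counts: Mapping[tuple[str, str], int],
    score_min: float = SCORE_MIN,
    de_status: Mapping[str, str] | None = None,
    score_mode: str = "sites",
) -> list[Triplet]:
    """Join the three evidence layers into ceRNA triplets.

    Emits (L, m, M) iff m targets L, m targets M, L and M are positively
    co-expressed, the (L, M) ceRNA score is >= score_min and — when de_status
    is supplied — all three members are differentially expressed (status !=
    ns). Output is deduplicated and sorted (L, m, M) lexicographically,
    making it invariant to input ordering.
    """
    mir_lnc_map = {(i.mirna_id, i.target_id): i for i in mir_lnc}
    mir_mrna_map = {(i.mirna_id, i.target_id): i for i in mir_mrna}
    counts_by_lnc: dict[str, dict[str, int]] = {}
    for (mid, lid), c in lnc_mre_counts.items():
        counts_by_lnc.setdefault(lid, {})[mid] = c
    mirnas_of_lnc: dict[str, set[str]] = {}
    for mid, lid in mir_lnc_map:
        mirnas_of_lnc.setdefault(lid, set()).add(mid)
    mirnas_of_mrna: dict[str, set[str]] = {}
    for mid, tid in mir_mrna_map:
        mirnas_of_mrna.setdefault(tid, set()).add(mid)

    triplets: dict[tuple[str, str, str], Triplet] = {}
    for corr in lnc_mrna:
        lnc, mrna = corr.id_a, corr.id_b
        shared = mirnas_of_lnc.get(lnc, set()) & mirnas_of_mrna.get(mrna, set())
        if not shared:
            continue
        if lnc not in counts_by_lnc:
            continue
        score = cerna_score(counts_by_lnc[lnc], shared, mode=score_mode)
        if score < score_min:
            continue
        if de_status is not None and (
            de_status.get(lnc, "ns") == "ns" or de_status.get(mrna, "ns") == "ns"
        ):
            continue
        for mid in shared:
            if de_status is not None and de_status.get(mid, "ns") == "ns":
                continue
            t = Triplet(
                lncrna_id=lnc,
                mirna_id=mid,
                mrna_id=mrna,
                cerna_score=score,
                lnc_mrna_pcc=corr.r,
                mir_lnc_pcc=mir_lnc_map[(mid, lnc)].pcc,
                mir_mrna_pcc=mir_mrna_map[(mid, mrna)].pcc,
            )
            triplets[t.key] = t
    return [triplets[k] for k in sorted(triplets)]


def restrict_to_genes(triplets: list[Triplet], key_genes: set[str]) -> list[Triplet]:
    """Keep only triplets whose mRNA is in a curated key-gene list."""
    kept = [t for t in triplets if t.mrna_id in key_genes]
    unused = key_genes - {t.mrna_id for t in kept}
    if unused:
        warnings.warn(
            f"{len(unused)} key genes absent from any triplet", stacklevel=2
        )
    return kept


def build_network(triplets: list[Triplet]) -> CeRNANetwork:
    """One node per molecule; 'targets' and 'competes' edges, deduplicated."""
    g = nx.Graph()
    for t in triplets:
        g.add_node(t.lncrna_id, node_type="lncRNA")
        g.add_node(t.mirna_id, node_type="miRNA")
        g.add_node(t.mrna_id, node_type="mRNA")
        g.add_edge(t.mirna_id, t.lncrna_id, relation="targets", pcc=t.mir_lnc_pcc)
        g.add_edge(t.mirna_id, t.mrna_id, relation="targets", pcc=t.mir_mrna_pcc)
        g.add_edge(
            t.lncrna_id,
            t.mrna_id,
            relation="competes",
            pcc=t.lnc_mrna_pcc,
            cerna_score=t.cerna_score,
        )
    return CeRNANetwork(g)


def triplet_table(triplets: list[Triplet]) -> pd.DataFrame:
    return pd.DataFrame(
        [t.__dict__ for t in triplets],
        columns=[
            "lncrna_id",
            "mirna_id",
            "mrna_id",
            "cerna_score",
            "lnc_mrna_pcc",
            "mir_lnc_pcc",
            "mir_mrna_pcc",
        ],
    )


def degree_table(network: CeRNANetwork) -> pd.DataFrame:
    deg = network.degree
    types = network.nodes
    hubs = network.hubs
    rows = [
        {
            "node_id": n,
            "node_type": types[n],
            "degree": deg[n],
            "is_hub": n in hubs,
        }
        for n in sorted(deg, key=lambda n: (-deg[n], n))
    ]
    return pd.DataFrame(rows, columns=["node_id", "node_type", "degree", "is_hub"])
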