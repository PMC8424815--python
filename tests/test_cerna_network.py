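import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.cerna_network import (
    Triplet,
    assemble_triplets,
    build_network,
    cerna_score,
    restrict_to_genes,
)
from cernet.coexpr import CorrelationResult, TargetInteraction
from cernet.io_formats import Transcript
from cernet.targeting import count_mres


def _interaction(m, t, kind, count=1, pcc=-0.9):
    return TargetInteraction(
        mirna_id=m, target_id=t, target_kind=kind, mre_count=count,
        pcc=pcc, pcc_pvalue=0.001,
    )


def _corr(a, b, r=0.9):
    return CorrelationResult(id_a=a, id_b=b, r=r, pvalue=0.001, n=12)


class TestCernaScore:
    def test_all_shared_gives_one(self):
        assert cerna_score({"m1": 2, "m2": 3}, {"m1", "m2"}) == 1.0

    def test_none_shared_gives_zero(self):
        assert cerna_score({"m1": 2, "m2": 3}, set()) == 0.0

    def test_toy_site_weighted_case(self):
        assert cerna_score({"m1": 2, "m2": 2, "m3": 1}, {"m1", "m3"}) == pytest.approx(0.6)

    def test_toy_case_from_actual_site_enumeration(self):
        """The {2,2,1} example built from real sequences: plant 2+2+1 perfect
        sites of three miRNAs on one lncRNA and count them with the scanner."""
        rng = np.random.default_rng(42)
        bases = list("ACGT")
        revcomp = str.maketrans("ACGT", "TGCA")
        mirs = ["".join(rng.choice(bases, 21)) for _ in range(3)]
        spacer = lambda: "".join(rng.choice(bases, 45))
        sites = [mirs[0], mirs[0], mirs[1], mirs[1], mirs[2]]
        lnc_seq = spacer()
        for s in sites:
            lnc_seq += s.translate(revcomp)[::-1] + spacer()
        lnc = Transcript(id="L", seq=lnc_seq, biotype="lncRNA")
        mirnas = [Transcript(id=f"m{i+1}", seq=s, biotype="miRNA") for i, s in enumerate(mirs)]
        counts = count_mres(mirnas, [lnc])
        lnc_counts = {m: c for (m, t), c in counts.items()}
        assert lnc_counts == {"m1": 2, "m2": 2, "m3": 1}
        assert cerna_score(lnc_counts, {"m1", "m3"}) == pytest.approx(0.6)

    def test_species_mode(self):
        assert cerna_score({"m1": 2, "m2": 2, "m3": 1}, {"m1", "m3"}, mode="species") == pytest.approx(2 / 3)

    def test_no_mres_rejected(self):
        with pytest.raises(ValueError, match="no MREs"):
            cerna_score({}, set())

    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.dictionaries(
            st.sampled_from([f"m{i}" for i in range(6)]),
            st.integers(min_value=1, max_value=5),
            min_size=1,
        ),
        data=st.data(),
    )
    def test_bounded_and_monotone_in_shared_set(self, counts, data):
        mirnas = sorted(counts)
        shared = set(data.draw(st.lists(st.sampled_from(mirnas), unique=True)))
        score = cerna_score(counts, shared)
        assert 0.0 <= score <= 1.0
        extra = set(mirnas) - shared
        if extra:
            grown = cerna_score(counts, shared | {sorted(extra)[0]})
            assert grown >= score


def _supported_inputs():
    """One fully supported (L, m, M) triplet."""
    mir_lnc = [_interaction("m1", "L1", "lncRNA", count=2)]
    mir_mrna = [_interaction("m1", "M1", "mRNA", count=1)]
    lnc_mrna = [_corr("L1", "M1")]
    counts = {("m1", "L1"): 2}
    return mir_lnc, mir_mrna, lnc_mrna, counts


class TestAssembleTriplets:
    def test_fully_supported_triplet_emitted(self):
        triplets = assemble_triplets(*_supported_inputs())
        assert [t.key for t in triplets] == [("L1", "m1", "M1")]
        assert triplets[0].cerna_score == 1.0

    def test_missing_positive_correlation_blocks(self):
        mir_lnc, mir_mrna, _, counts = _supported_inputs()
        assert assemble_triplets(mir_lnc, mir_mrna, [], counts) == []

    def test_score_below_threshold_blocks(self):
        mir_lnc, mir_mrna, lnc_mrna, _ = _supported_inputs()
        # the lncRNA carries mostly MREs of a non-shared miRNA
        counts = {("m1", "L1"): 1, ("m9", "L1"): 3}
        assert assemble_triplets(mir_lnc, mir_mrna, lnc_mrna, counts) == []

    def test_de_restriction(self):
        args = _supported_inputs()
        status = {"L1": "down", "M1": "down", "m1": "up"}
        assert len(assemble_triplets(*args, de_status=status)) == 1
        status["M1"] = "ns"
        assert assemble_triplets(*args, de_status=status) == []

    def _random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        mirnas = [f"m{i}" for i in range(4)]
        lncs = [f"L{i}" for i in range(4)]
        mrnas = [f"M{i}" for i in range(5)]
        mir_lnc = [
            _interaction(m, l, "lncRNA", count=int(rng.integers(1, 4)))
            for m in mirnas for l in lncs if rng.random() < 0.5
        ]
        mir_mrna = [
            _interaction(m, t, "mRNA", count=int(rng.integers(1, 4)))
            for m in mirnas for t in mrnas if rng.random() < 0.5
        ]
        lnc_mrna = [
            _corr(l, t) for l in lncs for t in mrnas if rng.random() < 0.6
        ]
        counts = {(i.mirna_id, i.target_id): i.mre_count for i in mir_lnc}
        return mir_lnc, mir_mrna, lnc_mrna, counts

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_exhaustive_combination_oracle(self, seed):
        mir_lnc, mir_mrna, lnc_mrna, counts = self._random_inputs(seed)
        got = {t.key for t in assemble_triplets(mir_lnc, mir_mrna, lnc_mrna, counts)}
        # brute force over all (L, m, M) combinations with the same predicates
        mir_lnc_set = {(i.mirna_id, i.target_id) for i in mir_lnc}
        mir_mrna_set = {(i.mirna_id, i.target_id) for i in mir_mrna}
        lnc_mrna_set = {(c.id_a, c.id_b) for c in lnc_mrna}
        lncs = {l for _, l in mir_lnc_set} | {c.id_a for c in lnc_mrna}
        mrnas = {t for _, t in mir_mrna_set} | {c.id_b for c in lnc_mrna}
        mirnas = {m for m, _ in mir_lnc_set | mir_mrna_set}
        expected = set()
        for L, m, M in itertools.product(sorted(lncs), sorted(mirnas), sorted(mrnas)):
            if (m, L) not in mir_lnc_set or (m, M) not in mir_mrna_set:
                continue
            if (L, M) not in lnc_mrna_set:
                continue
            lnc_counts = {mm: c for (mm, ll), c in counts.items() if ll == L}
            shared = {
                mm for mm, ll in mir_lnc_set if ll == L
            } & {mm for mm, tt in mir_mrna_set if tt == M}
            num = sum(lnc_counts[mm] for mm in shared)
            if num / sum(lnc_counts.values()) >= 0.5:
                expected.add((L, m, M))
        assert got == expected

    def test_invariant_to_input_ordering(self):
        mir_lnc, mir_mrna, lnc_mrna, counts = self._random_inputs(5)
        a = assemble_triplets(mir_lnc, mir_mrna, lnc_mrna, counts)
        b = assemble_triplets(mir_lnc[::-1], mir_mrna[::-1], lnc_mrna[::-1], counts)
        assert a == b


class TestRestrictToGenes:
    triplets = [
        Triplet(f"L{i}", f"m{i % 2}", f"M{i % 3}", 1.0, 0.9, -0.9, -0.9)
        for i in range(10)
    ]

    def test_all_genes_is_identity(self):
        all_genes = {t.mrna_id for t in self.triplets}
        assert restrict_to_genes(self.triplets, all_genes) == self.triplets

    def test_empty_list_removes_everything(self):
        with pytest.warns(UserWarning):
            assert restrict_to_genes(self.triplets, {"M99"}) == []
        assert restrict_to_genes(self.triplets, set()) == []

    def test_equals_brute_force_filter(self):
        keep = {"M0", "M2"}
        got = restrict_to_genes(self.triplets, keep)
        assert got == [t for t in self.triplets if t.mrna_id in keep]


class TestBuildNetwork:
    def test_single_triplet_geometry(self):
        net = build_network([Triplet("L1", "m1", "M1", 1.0, 0.9, -0.9, -0.9)])
        assert len(net.nodes) == 3
        assert net.n_edges == 3
        assert set(net.degree.values()) == {2}
        assert net.hubs == {"L1", "M1", "m1"}
        assert net.primary_hub == "L1"

    def test_shared_mirna_is_unique_hub(self):
        triplets = [
            Triplet("L1", "m1", "M1", 1.0, 0.9, -0.9, -0.9),
            Triplet("L2", "m1", "M2", 1.0, 0.9, -0.9, -0.9),
        ]
        net = build_network(triplets)
        assert net.degree["m1"] == 4
        assert net.hubs == {"m1"}
        assert net.primary_hub == "m1"

    def test_degree_sum_is_twice_edge_count(self):
        rng = np.random.default_rng(3)
        triplets = [
            Triplet(f"L{rng.integers(5)}", f"m{rng.integers(4)}", f"M{rng.integers(6)}",
                    1.0, 0.9, -0.9, -0.9)
            for _ in range(25)
        ]
        net = build_network(triplets)
        assert sum(net.degree.values()) == 2 * net.n_edges

    def test_degree_and_hub_match_brute_force_incidence(self):
        rng = np.random.default_rng(19)
        triplets = [
            Triplet(f"L{rng.integers(5)}", f"m{rng.integers(4)}", f"M{rng.integers(6)}",
                    1.0, 0.9, -0.9, -0.9)
            for _ in range(25)
        ]
        net = build_network(triplets)
        # brute force: dedupe edges as unordered pairs, count incidences
        edges = set()
        for t in triplets:
            edges.add(frozenset((t.mirna_id, t.lncrna_id)))
            edges.add(frozenset((t.mirna_id, t.mrna_id)))
            edges.add(frozenset((t.lncrna_id, t.mrna_id)))
        degree = {}
        for e in edges:
            for n in e:
                degree[n] = degree.get(n, 0) + 1
        assert net.degree == degree
        top = max(degree.values())
        assert net.hubs == {n for n, d in degree.items() if d == top}
        assert net.primary_hub == min(net.hubs)
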