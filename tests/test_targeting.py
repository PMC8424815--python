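import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.io_formats import Transcript
from cernet.targeting import (
    DuplexParams,
    count_mres,
    find_mre_sites,
    score_duplex,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(REVCOMP)[::-1]


def oracle_score(mirna, window, params):
    """Independent per-position recomputation of the duplex penalty."""
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    total = 0.0
    n = len(mirna)
    for i in range(n):  # miRNA position i+1 pairs window base n-1-i
        q, t = mirna[i], window[n - 1 - i]
        if comp.get(q) == t:
            pen = 0.0
        elif (q, t) in {("G", "T"), ("T", "G")}:
            pen = params.gu_penalty
        else:
            pen = params.mismatch_penalty
        if params.seed_range[0] <= i + 1 <= params.seed_range[1]:
            pen *= params.seed_multiplier
        total += pen
    return total


def oracle_sites(mirna, target, params):
    """Exhaustive window enumeration + the same greedy overlap resolution."""
    L = len(mirna)
    scored = [
        (oracle_score(mirna, target[i : i + L], params), i)
        for i in range(len(target) - L + 1)
    ]
    candidates = sorted((p, i) for p, i in scored if p <= params.max_penalty)
    kept = []
    min_diff = L + params.min_site_separation - 1
    for p, i in candidates:
        if all(abs(i - j) >= min_diff for _, j in kept):
            kept.append((p, i))
    return sorted((i + 1, p) for p, i in kept)  # 1-based starts


def _mirna(seq, name="mir"):
    return Transcript(id=name, seq=seq, biotype="miRNA")


def _target(seq, name="tgt"):
    return Transcript(id=name, seq=seq, biotype="mRNA")


MIR21 = "TGATTGAGCCGCGCCAATATC"  # arbitrary 21-mer


class TestScoreDuplex:
    def test_perfect_reverse_complement_scores_zero(self):
        penalty, pairing = score_duplex(MIR21, revcomp(MIR21))
        assert penalty == 0.0
        assert pairing == "|" * 21

    def test_single_mismatch_outside_seed(self):
        window = list(revcomp(MIR21))
        # miRNA position 1 pairs the window's last base; force a mismatch
        window[-1] = "C" if window[-1] != "C" else "A"
        penalty, pairing = score_duplex(MIR21, "".join(window))
        assert penalty == pytest.approx(1.0)
        assert pairing[0] == "x" and pairing[1:] == "|" * 20

    def test_gu_wobble_inside_seed_is_doubled(self):
        mirna = list(MIR21)
        mirna[4] = "G"  # position 5, inside the 2-13 seed
        mirna = "".join(mirna)
        window = list(revcomp(mirna))
        # the base pairing miRNA position 5 sits at window index 21-5=16
        window[16] = "T"  # G:U wobble
        penalty, pairing = score_duplex(mirna, "".join(window))
        assert pairing[4] == "o"
        assert penalty == pytest.approx(0.5 * 2.0)
        assert penalty == pytest.approx(oracle_score(mirna, "".join(window), DuplexParams()))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            score_duplex(MIR21, "ACGT")

    def test_t_u_representation_invariance(self):
        window = revcomp(MIR21)
        mutated = window[:5] + "T" + window[6:]
        base = score_duplex(MIR21, mutated)
        assert score_duplex(MIR21.replace("T", "U"), mutated) == base
        assert score_duplex(MIR21, mutated.replace("T", "U")) == base

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_per_position_oracle_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        mirna = "".join(rng.choice(bases, 21))
        window = "".join(rng.choice(bases, 21))
        params = DuplexParams()
        penalty, _ = score_duplex(mirna, window, params)
        assert penalty == pytest.approx(oracle_score(mirna, window, params))


class TestFindMreSites:
    def test_exact_complement_single_site(self):
        sites = find_mre_sites(_mirna(MIR21), _target(revcomp(MIR21)))
        assert len(sites) == 1
        assert sites[0].target_start == 1
        assert sites[0].penalty == 0.0

    def test_no_sites_above_threshold(self):
        rng = np.random.default_rng(13)
        target = "".join(rng.choice(list("ACGT"), 500))
        mirna = _mirna(MIR21)
        sites = find_mre_sites(mirna, _target(target))
        expected = oracle_sites(MIR21, target, DuplexParams())
        assert [(s.target_start, s.penalty) for s in sites] == expected

    def test_three_planted_sites_recovered(self):
        rng = np.random.default_rng(2)
        spacer = lambda n: "".join(rng.choice(list("ACGT"), n))
        site = revcomp(MIR21)
        target = spacer(40) + site + spacer(35) + site + spacer(50) + site + spacer(30)
        sites = find_mre_sites(_mirna(MIR21), _target(target))
        expected = oracle_sites(MIR21, target, DuplexParams())
        assert [(s.target_start, s.penalty) for s in sites] == expected
        assert sum(1 for s in sites if s.penalty == 0.0) == 3

    def test_retained_sites_never_overlap(self):
        # tandem perfect sites: greedy resolution must thin them to
        # non-overlapping starts
        site = revcomp(MIR21)
        target = site + site + site
        sites = find_mre_sites(_mirna(MIR21), _target(target))
        starts = [s.target_start for s in sites]
        assert starts == sorted(starts)
        assert all(b - a >= 21 for a, b in zip(starts, starts[1:]))
        assert [(s.target_start, s.penalty) for s in sites] == oracle_sites(
            MIR21, target, DuplexParams()
        )

    def test_short_target_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert find_mre_sites(_mirna(MIR21), _target("ACGTACGT")) == []

    def test_scan_is_strand_explicit(self):
        # a target carrying a site only on its reverse complement must not hit
        target_fwd = revcomp(MIR21) + "ACGTACGTACGTACGTACGTA"
        target_rev = revcomp(target_fwd)
        fwd_sites = find_mre_sites(_mirna(MIR21), _target(target_fwd))
        rev_sites = find_mre_sites(_mirna(MIR21), _target(target_rev))
        assert len(fwd_sites) == 1
        assert [(s.target_start, s.penalty) for s in rev_sites] != [
            (s.target_start, s.penalty) for s in fwd_sites
        ]

    @settings(derandomize=True, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        bases = list("ACGT")
        mirna = "".join(rng.choice(bases, 21))
        target = "".join(rng.choice(bases, 200))
        # loosen the cutoff so random windows sometimes qualify
        params = DuplexParams(max_penalty=12.0)
        sites = find_mre_sites(_mirna(mirna), _target(target), params)
        assert [(s.target_start, s.penalty) for s in sites] == oracle_sites(
            mirna, target, params
        )
        for s in sites:
            assert s.penalty <= params.max_penalty


class TestCountMres:
    def test_single_perfect_target(self):
        counts = count_mres([_mirna(MIR21)], [_target(revcomp(MIR21))])
        assert counts == {("mir", "tgt"): 1}

    def test_no_targets(self):
        assert count_mres([_mirna(MIR21)], []) == {}

    def test_zero_count_pairs_omitted(self):
        rng = np.random.default_rng(14)
        clean = "".join(rng.choice(list("ACGT"), 300))
        counts = count_mres([_mirna(MIR21)], [_target(clean)])
        assert ("mir", "tgt") not in counts

    def test_planted_fixture_counts_match_truth(self, small_dataset, small_params):
        transcripts, _, _, _, truth = small_dataset
        by_id = {t.id: t for t in transcripts}
        planted_counts = {}
        for s in truth.planted_sites:
            key = (s["mirna_id"], s["target_id"])
            planted_counts[key] = planted_counts.get(key, 0) + 1
        mirnas = [t for t in transcripts if t.biotype == "miRNA"]
        targets = [by_id[tid] for _, tid in planted_counts]
        counts = count_mres(mirnas, targets)
        for key, planted in planted_counts.items():
            assert counts.get(key, 0) >= planted
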