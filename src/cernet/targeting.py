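"""miRNA response element (MRE) detection by complementarity penalty scoring.

Plant miRNA:target duplexes are near-perfectly complementary, so targets are
found with an ungapped penalty scheme in the spirit of classical plant
target-prediction rules: each mismatch costs 1, each G:U wobble 0.5, and
penalties within the seed region (miRNA positions 2-13 from the 5' end) are
doubled; windows with total penalty <= 4.0 are candidate sites. The miRNA is
aligned antiparallel to the target window: miRNA position 1 (5' end) pairs
the window's 3'-most base.

Pairing strings use one character per miRNA position: '|' Watson-Crick match,
'o' G:U wobble, 'x' mismatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import Transcript, canonicalize_seq

__all__ = [
    "DuplexParams",
    "DuplexSite",
    "score_duplex",
    "find_mre_sites",
    "count_mres",
    "sites_table",
]

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# integer encoding for the vectorized scanner
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_MATCHES = {(0, 3), (3, 0), (2, 1), (1, 2)}  # A:T, T:A, G:C, C:G
_WOBBLES = {(2, 3), (3, 2)}  # G:U and U:G (U represented as T)


@dataclass(frozen=True)
class DuplexParams:
    """Scoring parameters for miRNA:target duplex evaluation.

    seed_range is 1-based inclusive on the miRNA, measured from its 5' end;
    penalties inside it are multiplied by seed_multiplier. min_site_separation
    is the minimum gap (nt) added to the site length when resolving overlaps;
    the default of 1 means retained sites may be adjacent but not overlap.
    """

    max_penalty: float = 4.0
    seed_range: tuple[int, int] = (2, 13)
    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    seed_multiplier: float = 2.0
    min_site_separation: int = 1

    def __post_init__(self) -> None:
        for name in ("max_penalty", "mismatch_penalty", "gu_penalty", "seed_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.seed_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid seed_range {self.seed_range}")
        if self.min_site_separation < 1:
            raise ValueError("min_site_separation must be >= 1")


@dataclass(frozen=True)
class DuplexSite:
    """One predicted MRE: the miRNA bound at target positions
    [target_start, target_start + len(miRNA) - 1] (1-based)."""

    mirna_id: str
    target_id: str
    target_start: int
    penalty: float
    pairing_string: str


def _check_seed(params: DuplexParams, mirna_len: int) -> None:
    if params.seed_range[1] > mirna_len:
        raise ValueError(
            f"seed_range {params.seed_range} extends past miRNA length {mirna_len}"
        )


def _position_weights(params: DuplexParams, mirna_len: int) -> np.ndarray:
    """Penalty multiplier per miRNA position (1-based positions 1..L)."""
    w = np.ones(mirna_len)
    lo, hi = params.seed_range
    w[lo - 1 : hi] = params.seed_multiplier
    return w


def score_duplex(
    mirna_seq: str, target_window: str, params: DuplexParams | None = None
) -> tuple[float, str]:
    """Score one miRNA against an equal-length target window.

    Returns (penalty, pairing_string); the pairing string is indexed by miRNA
    position (5' to 3'). Accepts RNA or DNA spelling of either sequence.
    """
    params = params or DuplexParams()
    q = canonicalize_seq(mirna_seq)
    t = canonicalize_seq(target_window)
    if len(q) != len(t):
        raise ValueError(
            f"length mismatch: miRNA {len(q)} nt vs window {len(t)} nt"
        )
    _check_seed(params, len(q))
    weights = _position_weights(params, len(q))
    penalty = 0.0
    tokens = []
    n = len(q)
    for i in range(n):  # miRNA position i+1 pairs window base n-1-i (antiparallel)
        qb, tb = q[i], t[n - 1 - i]
        if tb == _COMPLEMENT.get(qb):
            tokens.append("|")
        elif (qb, tb) in {("G", "T"), ("T", "G")}:
            tokens.append("o")
            penalty += params.gu_penalty * weights[i]
        else:
            tokens.append("x")
            penalty += params.mismatch_penalty * weights[i]
    return penalty, "".join(tokens)


def _window_penalties(mirna: str, target: str, params: DuplexParams) -> np.ndarray:
    """Penalty of every window of len(mirna) along the target (vectorized)."""
    L = len(mirna)
    q = np.array([_ENC[c] for c in mirna], dtype=np.int8)
    t = np.array([_ENC[c] for c in target], dtype=np.int8)
    windows = np.lib.stride_tricks.sliding_window_view(t, L)  # (n_win, L)
    # window column j pairs miRNA position L-j (0-based: reversed miRNA)
    q_rev = q[::-1]
    pair_pen = np.full((5, 5), params.mismatch_penalty)
    for a, b in _MATCHES:
        pair_pen[a, b] = 0.0
    for a, b in _WOBBLES:
        pair_pen[a, b] = params.gu_penalty
    per_pos = pair_pen[q_rev[None, :], windows]
    weights = _position_weights(params, L)[::-1]
    return (per_pos * weights[None, :]).sum(axis=1)


def find_mre_sites(
    mirna: Transcript, target: Transcript, params: DuplexParams | None = None
) -> list[DuplexSite]:
    """Scan a target transcript for MREs of one miRNA.

    Slides a window of miRNA length along the target sense strand (step 1),
    keeps windows with penalty <= max_penalty, resolves overlaps greedily by
    ascending penalty (ties: smaller target_start), and returns the retained
    sites sorted by target_start. Only the given target sense is scanned.
    """
    params = params or DuplexParams()
    L = len(mirna.seq)
    _check_seed(params, L)
    if len(target.seq) < L:
        warnings.warn(
            f"target {target.id!r} shorter than miRNA {mirna.id!r}; no sites",
            stacklevel=2,
        )
        return []
    penalties = _window_penalties(mirna.seq, target.seq, params)
    candidates = np.flatnonzero(penalties <= params.max_penalty)
    if candidates.size == 0:
        return []

    order = sorted(candidates, key=lambda i: (penalties[i], i))
    min_start_diff = L + params.min_site_separation - 1
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_start_diff for j in kept):
            kept.append(i)

    sites = []
    for i in sorted(kept):
        window = target.seq[i : i + L]
        penalty, pairing = score_duplex(mirna.seq, window, params)
        sites.append(
            DuplexSite(
                mirna_id=mirna.id,
                target_id=target.id,
                target_start=i + 1,
                penalty=penalty,
                pairing_string=pairing,
            )
        )
    return sites


def count_mres(
    mirnas: list[Transcript],
    targets: list[Transcript],
    params: DuplexParams | None = None,
) -> dict[tuple[str, str], int]:
    """Retained MRE count per (mirna_id, target_id); zero-count pairs omitted."""
    params = params or DuplexParams()
    counts: dict[tuple[str, str], int] = {}
    for m in mirnas:
        for t in targets:
            n = len(find_mre_sites(m, t, params))
            if n:
                counts[(m.id, t.id)] = n
    return counts


def sites_table(sites: list[DuplexSite]):
    import pandas as pd

    return pd.DataFrame(
        [s.__dict__ for s in sites],
        columns=["mirna_id", "target_id", "target_start", "penalty", "pairing_string"],
    )
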