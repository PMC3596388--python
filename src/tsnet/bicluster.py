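"""Maximal temporal bicluster extraction from a gene state matrix.

A temporal bicluster is a subset of genes together with a contiguous
window of time points over which every member gene follows exactly the
same discrete state profile.  Only *maximal* biclusters are reported:
the gene set contains every matching gene (row-maximal), and the window
cannot be extended one step left or right without losing a member gene
(column-maximal).

The extraction first time-stamps each state -- state ``s`` at time ``t``
becomes the token ``(t, s)``, so equal states at different time points
never compare equal -- then builds all suffixes of every gene's token
sequence, sorts them with an MSD (most-significant-digit-first) radix
sort, and computes longest-common-prefix (LCP) lengths between adjacent
sorted suffixes.  Runs of suffixes sharing a long prefix delimit the
candidate biclusters; the LCP-interval structure yields each maximal
run exactly once.  A brute-force window-enumeration oracle with the
same contract is provided for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import Bicluster, GeneStateMatrix

__all__ = [
    "TokenSequence",
    "SuffixIndex",
    "transform_states",
    "render_token",
    "build_suffix_index",
    "ql_biclustering",
    "enumerate_biclusters_oracle",
]


@dataclass
class TokenSequence:
    """A gene's state path as time-stamped tokens ``(time_point, state)``."""

    gene_id: str
    tokens: list  # [(t, s), ...] with consecutive 1-based t


def render_token(t: int, s: int) -> str:
    """Decimal display of a token: ``t*10 + s`` while both are single digits."""
    if t <= 9 and s <= 9:
        return str(t * 10 + s)
    return f"{t}_{s}"


def transform_states(state_matrix: GeneStateMatrix) -> list:
    """Time-stamp every gene state: state ``s`` at time ``t`` -> token ``(t, s)``."""
    return [
        TokenSequence(
            gene_id=g,
            tokens=[(int(t), int(s)) for t, s in zip(state_matrix.time_points, row)],
        )
        for g, row in zip(state_matrix.gene_ids, state_matrix.states)
    ]


@dataclass
class SuffixIndex:
    """All suffixes of the token sequences in lexicographic order.

    ``suffixes`` holds ``(gene_id, start_time)`` references;
    ``lcp_length[k]`` is the exact token-wise longest common prefix of
    sorted suffixes ``k-1`` and ``k`` (``lcp_length[0] = 0``).  ``blcp``
    is the processed-boundary marker used during extraction.
    """

    suffixes: list
    lcp_length: np.ndarray
    blcp: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.blcp is None:
            self.blcp = np.zeros(len(self.suffixes), dtype=bool)


def _msd_sort(order: list, states: np.ndarray, start: int, depth: int, length: int) -> list:
    """MSD radix sort of same-start suffixes by their state at each depth.

    ``order`` holds gene indices; all suffixes share start column
    ``start`` and length ``length``, so the time part of every token is
    identical at a given depth and only the state digit is bucketed.
    """
    if len(order) <= 1 or depth >= length:
        return order
    buckets: dict[int, list] = {}
    for g in order:
        buckets.setdefault(int(states[g, start + depth]), []).append(g)
    out: list = []
    for s in sorted(buckets):
        out.extend(_msd_sort(buckets[s], states, start, depth + 1, length))
    return out


def build_suffix_index(sequences: list) -> SuffixIndex:
    """Sort all n*T suffixes by MSD radix sort and compute adjacent LCPs.

    Suffixes are keyed by their token lists; the first token's time part
    groups suffixes by start time (suffixes starting at different times
    share no prefix, LCP 0), and within a start-time group the state
    digits are radix-sorted depth by depth.
    """
    if not sequences:
        return SuffixIndex([], np.zeros(0, dtype=int))
    T = len(sequences[0].tokens)
    times = [t for t, _ in sequences[0].tokens]
    states = np.array([[s for _, s in seq.tokens] for seq in sequences], dtype=int)
    gene_ids = [seq.gene_id for seq in sequences]

    suffixes: list = []
    for col, t in enumerate(times):  # MSD on the time digit: ascending start time
        order = _msd_sort(list(range(len(sequences))), states, col, 0, T - col)
        suffixes.extend((gene_ids[g], t, g, col) for g in order)

    lcp = np.zeros(len(suffixes), dtype=int)
    for k in range(1, len(suffixes)):
        _, t_prev, g_prev, c_prev = suffixes[k - 1]
        _, t_cur, g_cur, c_cur = suffixes[k]
        if c_prev != c_cur:
            continue  # different start times: first tokens differ, LCP 0
        length = T - c_cur
        same = states[g_prev, c_cur: c_cur + length] == states[g_cur, c_cur: c_cur + length]
        lcp[k] = int(same.argmin()) if not same.all() else length
    return SuffixIndex([(g, t) for g, t, _, _ in suffixes], lcp)


def _lcp_intervals(lcp: np.ndarray, lo: int, hi: int, depth: int):
    """Recursively yield maximal LCP runs ``(value, lo, hi)`` within a block.

    The suffixes ``lo..hi`` (inclusive) share a prefix of at least
    ``depth``; the interval's own value is the minimum internal LCP, and
    its children are the sub-runs strictly above that value.
    """
    if lo >= hi:
        return
    inner = lcp[lo + 1: hi + 1]
    d_min = int(inner.min())
    yield (d_min, lo, hi)
    cut_positions = [lo] + [lo + 1 + k for k in np.flatnonzero(inner == d_min)] + [hi + 1]
    for a, b in zip(cut_positions, cut_positions[1:]):
        yield from _lcp_intervals(lcp, a, b - 1, d_min)


def ql_biclustering(state_matrix: GeneStateMatrix, ml: int = 2, mo: int = 2) -> list:
    """Extract every maximal temporal bicluster via the suffix/LCP index.

    ``ml`` is the minimum window length (time points), ``mo`` the
    minimum number of genes.  Each maximal run of same-start suffixes
    sharing a prefix of length L corresponds to a candidate bicluster
    with window length L; the run's minimum internal LCP fixes the
    unique right-maximal window, and a candidate whose genes all agree
    at the time point just before the window is discarded as extensible
    to the left.  Output order is deterministic: by window start, then
    end, then gene set.
    """
    if ml < 1:
        raise ValueError("ml must be >= 1")
    if mo < 2:
        raise ValueError("mo must be >= 2")
    states = state_matrix.states
    gene_ids = list(state_matrix.gene_ids)
    gidx = {g: k for k, g in enumerate(gene_ids)}
    times = list(state_matrix.time_points)
    T = len(times)
    if ml > T or mo > len(gene_ids) or not gene_ids:
        return []

    index = build_suffix_index(transform_states(state_matrix))
    # contiguous blocks of equal start time in the sorted suffix order
    blocks: dict[int, tuple[int, int]] = {}
    for k, (_, t) in enumerate(index.suffixes):
        if t not in blocks:
            blocks[t] = (k, k)
        else:
            blocks[t] = (blocks[t][0], k)

    found: list[Bicluster] = []
    for t_start, (blo, bhi) in blocks.items():
        col = times.index(t_start)
        for L, lo, hi in _lcp_intervals(index.lcp_length, blo, bhi, 0):
            index.blcp[lo] = True  # run boundary bookkeeping
            if L < ml or hi - lo + 1 < mo:
                continue
            genes = sorted(index.suffixes[k][0] for k in range(lo, hi + 1))
            rows = [gidx[g] for g in genes]
            # left-maximality: all member genes sharing a state at col-1
            # means the window extends left with the same gene set
            if col > 0 and np.unique(states[rows, col - 1]).size == 1:
                continue
            profile = tuple(int(s) for s in states[rows[0], col: col + L])
            found.append(
                Bicluster(
                    genes=tuple(genes),
                    t_start=t_start,
                    t_end=times[col + L - 1],
                    profile=profile,
                )
            )
    found.sort(key=lambda b: (b.t_start, b.t_end, b.genes))
    return found


def enumerate_biclusters_oracle(
    state_matrix: GeneStateMatrix, ml: int = 2, mo: int = 2
) -> list:
    """Brute-force maximal bicluster enumeration (verification oracle).

    For every window of length >= ``ml``, genes are grouped by their
    exact state subsequence; groups of at least ``mo`` genes survive,
    and a group is kept only if it cannot be extended one column left or
    right with all members agreeing (column-maximality).  Row
    maximality holds by construction of the grouping.  Intended for
    small instances only.
    """
    if ml < 1:
        raise ValueError("ml must be >= 1")
    if mo < 2:
        raise ValueError("mo must be >= 2")
    states = state_matrix.states
    gene_ids = list(state_matrix.gene_ids)
    times = list(state_matrix.time_points)
    G, T = states.shape
    found: list[Bicluster] = []
    for a in range(T):
        for b in range(a + ml - 1, T):
            groups: dict[tuple, list[int]] = {}
            for g in range(G):
                groups.setdefault(tuple(states[g, a: b + 1]), []).append(g)
            for profile, rows in groups.items():
                if len(rows) < mo:
                    continue
                if a > 0 and np.unique(states[rows, a - 1]).size == 1:
                    continue  # extensible left
                if b < T - 1 and np.unique(states[rows, b + 1]).size == 1:
                    continue  # extensible right
                found.append(
                    Bicluster(
                        genes=tuple(sorted(gene_ids[g] for g in rows)),
                        t_start=times[a],
                        t_end=times[b],
                        profile=profile,
                    )
                )
    found.sort(key=lambda bc: (bc.t_start, bc.t_end, bc.genes))
    return found
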