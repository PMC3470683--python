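"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's computational routes: the alignment
oracle enumerates every monotone column matching between two sequences
(exponential, fine for short inputs), and the ordering oracle counts
distinct sequential arrangements of a multiset by explicit enumeration.
"""

from __future__ import annotations

import itertools
from math import inf

from permutome.alignment import AlignmentParams


def _gap_cost(length: int, p: AlignmentParams) -> float:
    if length == 0:
        return 0.0
    return p.gap_open + (length - 1) * p.gap_extend


def brute_force_identity(a: str, b: str, p: AlignmentParams) -> tuple[float, float]:
    """(optimal score, max percent identity among optimal matchings).

    A matching pairs positions of ``a`` with positions of ``b``
    monotonically; unmatched characters between consecutive pairs sit in
    internal gap columns (one contiguous run per sequence per segment is
    always optimal under affine costs), unmatched end characters sit in
    end gaps.  Identity counts compatible pairs over paired plus internal
    gap columns, excluding end gaps when they are free.
    """
    n, m = len(a), len(b)
    best_score = -inf
    best_identity = 0.0
    for k in range(min(n, m) + 1):
        for ii in itertools.combinations(range(n), k):
            for jj in itertools.combinations(range(m), k):
                pair_score = 0.0
                matches = 0
                for i, j in zip(ii, jj):
                    if p.compatible(a[i], b[j]):
                        pair_score += p.match_score
                        matches += 1
                    else:
                        pair_score += p.mismatch_score
                internal_cols = 0
                score = pair_score
                for t in range(k - 1):
                    ga = ii[t + 1] - ii[t] - 1
                    gb = jj[t + 1] - jj[t] - 1
                    internal_cols += ga + gb
                    score += _gap_cost(ga, p) + _gap_cost(gb, p)
                lead_a = ii[0] if k else n
                lead_b = jj[0] if k else m
                trail_a = n - 1 - ii[-1] if k else 0
                trail_b = m - 1 - jj[-1] if k else 0
                cols = k + internal_cols
                if p.end_gaps_free:
                    # When both sequences have unmatched characters at the
                    # same end, one of the two flanking gap runs lies between
                    # letters of the other sequence and is therefore internal
                    # (penalized); the cheaper arrangement wins.  With no
                    # paired columns at all both runs are true end gaps.
                    if k:
                        if lead_a and lead_b:
                            score += max(_gap_cost(lead_a, p), _gap_cost(lead_b, p))
                        if trail_a and trail_b:
                            score += max(_gap_cost(trail_a, p), _gap_cost(trail_b, p))
                else:
                    score += (
                        _gap_cost(lead_a, p)
                        + _gap_cost(lead_b, p)
                        + _gap_cost(trail_a, p)
                        + _gap_cost(trail_b, p)
                    )
                    cols += lead_a + lead_b + trail_a + trail_b
                identity = 100.0 * matches / cols if cols else 0.0
                if score > best_score:
                    best_score, best_identity = score, identity
                elif score == best_score and identity > best_identity:
                    best_identity = identity
    return best_score, best_identity


def brute_force_arrangements(items) -> int:
    """Number of distinct sequential orderings of a multiset, by enumeration."""
    return len(set(itertools.permutations(items)))
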