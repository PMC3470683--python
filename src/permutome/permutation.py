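"""The combinatorial core: multinomial counting of metabolic permutations.

A treatment partitions the 10 regulatory pathways into downregulation
states.  The number of *metabolic permutations* available to the plant is
the number of distinct sequential arrangements of that pathway multiset —
the multinomial coefficient

    n! / (a! b! c!)

for state-group sizes (a, b, c), a + b + c = n.  The model generalizes to
any number of state classes.  This module computes the counts exactly,
inverts a count back to its candidate state multiplicities by exhaustive
search, and summarizes the across-treatment count distribution (arithmetic
mean, adjusted Fisher-Pearson sample skewness, treatments right of the
mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import scipy.stats

from .silencing import TreatmentStateVector

__all__ = [
    "permutation_count",
    "recover_state_multiplicities",
    "PermutationSummary",
    "summarize_distribution",
    "DERIVED_TREATMENT_MULTIPLICITIES",
]

#: Per-treatment state-group sizes reconstructed from the published counts
#: (control 210, NPKS 3,150, NS/PS/K/PN 1,260, Pi/S/N 2,520, PK 4,200).
#: These triples are derived metadata, not measured ground truth; 1,260 is
#: ambiguous ((5,4,1) or (6,2,2)) and (5,4,1) is used here.
DERIVED_TREATMENT_MULTIPLICITIES: Mapping[str, tuple[int, int, int]] = {
    "control": (6, 4, 0),
    "N": (5, 3, 2),
    "Pi": (5, 3, 2),
    "S": (5, 3, 2),
    "K": (5, 4, 1),
    "NPKS": (4, 4, 2),
    "PK": (4, 3, 3),
    "NS": (5, 4, 1),
    "PN": (5, 4, 1),
    "PS": (5, 4, 1),
}


def permutation_count(v: TreatmentStateVector | Iterable[int]) -> int:
    """Number of distinct sequential arrangements of a state multiset.

    Accepts a :class:`TreatmentStateVector` or the state-group sizes
    directly; returns ``n! / prod(k_i!)`` in exact integer arithmetic.
    Invariant under permuting the roles of the states.
    """
    if isinstance(v, TreatmentStateVector):
        sizes = v.multiplicities()
    else:
        sizes = tuple(int(k) for k in v)
    if any(k < 0 for k in sizes):
        raise ValueError(f"negative multiplicity in {sizes}")
    n = sum(sizes)
    count = math.factorial(n)
    for k in sizes:
        count //= math.factorial(k)
    return count


def _compositions(n: int, k: int) -> Iterator[tuple[int, ...]]:
    """Non-increasing k-part compositions of n (parts may be zero)."""
    if k == 1:
        yield (n,)
        return
    for first in range(n, -1, -1):
        for rest in _compositions(n - first, k - 1):
            if rest[0] <= first:
                yield (first,) + rest


def recover_state_multiplicities(
    n: int, target: int, n_states: int = 3
) -> set[tuple[int, ...]]:
    """All non-increasing multiplicity tuples whose count equals ``target``.

    Exhaustive search over every ``n_states``-part composition of ``n``;
    returns the empty set when no composition attains the target (e.g. no
    triple of 10 gives 7).  Several triples may share a count — 1,260 on
    ten pathways is attained by both (6, 2, 2) and (5, 4, 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return {
        c for c in _compositions(n, n_states) if permutation_count(c) == target
    }


@dataclass(frozen=True)
class PermutationSummary:
    """Across-treatment distribution summary of permutation counts."""

    counts: Mapping[str, int]
    mean: float
    skewness: float
    right_of_mean: frozenset[str]


def summarize_distribution(counts: Mapping[str, int]) -> PermutationSummary:
    """Arithmetic mean, sample skewness and right-of-mean treatments.

    Skewness is the adjusted Fisher-Pearson sample coefficient (G1); it is
    defined as 0 when all counts are equal.  ``right_of_mean`` holds the
    treatments whose count strictly exceeds the arithmetic mean of the
    supplied counts (no externally printed mean is used).
    """
    if len(counts) < 2:
        raise ValueError("need counts for at least two treatments")
    values = [int(v) for v in counts.values()]
    if any(v < 1 for v in values):
        raise ValueError("permutation counts must be positive integers")
    mean = sum(values) / len(values)
    if len(set(values)) == 1:
        skew = 0.0
    else:
        skew = float(scipy.stats.skew(values, bias=False))
    right = frozenset(t for t, v in counts.items() if v > mean)
    return PermutationSummary(
        counts=dict(counts), mean=mean, skewness=skew, right_of_mean=right
    )
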