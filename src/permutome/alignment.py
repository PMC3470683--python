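"""IUPAC-aware pairwise nucleotide identity and the cross-talk network.

The silencing agents in this system are isomeric RNAs synthesized by
glutamate dehydrogenase (GDH).  A GDH-synthesized RNA knocks down mRNAs
homologous to it, but mRNAs that share only *imperfect* (roughly 70-80 %)
homology with another silencing RNA are partially cross-recognized and
thereby protected from complete knockout.  This module quantifies those
homologies as percent identities from optimal pairwise alignments and turns
them into an undirected "protection" (cross-talk) network between pathways.

Alignment is semi-global (free end gaps) with affine gap costs, computed
with :class:`Bio.Align.PairwiseAligner` over a substitution matrix in which
two IUPAC codes match whenever their base sets intersect (so ``N`` is a
wildcard).  Percent identity is ``100 x compatible columns / aligned
columns``, where end-gap columns are excluded whenever end gaps are free
and internal gap columns count in the denominator but never as matches.
Among co-optimal alignments the maximum achievable identity is reported.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement as _revcomp

__all__ = [
    "AlphabetError",
    "ProbeSequence",
    "AlignmentParams",
    "CrossTalkParams",
    "CrossTalkNetwork",
    "percent_identity",
    "identity_matrix",
    "build_crosstalk_network",
]

#: IUPAC nucleotide alphabet accepted on ingest.
IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"

#: IUPAC code -> set of concrete bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    c: frozenset(ambiguous_dna_values[c]) for c in IUPAC_ALPHABET
}


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


@dataclass(frozen=True)
class ProbeSequence:
    """A probe/mRNA cDNA sequence labelled with the pathway it reports on.

    Parameters
    ----------
    id : str
        Short unique label.
    pathway : str
        Pathway-catalogue label (e.g. ``"arachin_biosynthesis"``).
    bases : str
        Nucleotide sequence over the IUPAC alphabet; upper-cased on ingest.
    """

    id: str
    pathway: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if not bases:
            raise ValueError(f"probe {self.id!r}: empty sequence")
        for pos, sym in enumerate(bases):
            if sym not in IUPAC_SETS:
                raise AlphabetError(
                    f"probe {self.id!r}: illegal symbol {sym!r} at position {pos}"
                )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self) -> "ProbeSequence":
        return replace(self, bases=_revcomp(self.bases))


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme for the semi-global pairwise aligner.

    The study reported BLASTn "plus/plus" similarities without naming the
    tool's parameters, so the scheme is configurable; the defaults
    (match +1, mismatch -1, gap open -2, gap extend -1, end gaps free)
    approximate BLASTn-style local identity on near-full-length homologs
    while staying deterministic.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.
    """

    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    end_gaps_free: bool = True
    ambiguity_is_match: bool = True

    def __post_init__(self) -> None:
        if not self.match_score > self.mismatch_score:
            raise ValueError("match_score must exceed mismatch_score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")

    def compatible(self, x: str, y: str) -> bool:
        """True when a column pairing ``x`` with ``y`` counts as a match."""
        if self.ambiguity_is_match:
            return bool(IUPAC_SETS[x] & IUPAC_SETS[y])
        return x == y


def _make_aligner(p: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(IUPAC_ALPHABET, dims=2)
    for x in IUPAC_ALPHABET:
        for y in IUPAC_ALPHABET:
            matrix[x, y] = p.match_score if p.compatible(x, y) else p.mismatch_score
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = p.gap_open
    aligner.extend_gap_score = p.gap_extend
    if p.end_gaps_free:
        aligner.end_gap_score = 0.0
    return aligner


def _alignment_identity(aln, p: AlignmentParams) -> float:
    """Percent identity of one alignment under the column rules above."""
    sa, sb = str(aln[0]), str(aln[1])
    lo, hi = 0, len(sa)
    if p.end_gaps_free:
        while lo < hi and (sa[lo] == "-" or sb[lo] == "-"):
            lo += 1
        while hi > lo and (sa[hi - 1] == "-" or sb[hi - 1] == "-"):
            hi -= 1
    cols = hi - lo
    if cols == 0:  # degenerate: nothing aligned (mutually incompatible ends)
        return 0.0
    matches = sum(
        1
        for x, y in zip(sa[lo:hi], sb[lo:hi])
        if x != "-" and y != "-" and p.compatible(x, y)
    )
    return 100.0 * matches / cols


def percent_identity(
    a: ProbeSequence | str,
    b: ProbeSequence | str,
    params: AlignmentParams | None = None,
    *,
    reverse_complement: bool = False,
    max_alignments: int = 1000,
) -> float:
    """Percent identity between two sequences under an optimal alignment.

    Computes the optimal semi-global alignment score under ``params`` and
    reports the maximum percent identity achievable among co-optimal
    alignments (at most ``max_alignments`` are inspected).  Symmetric in
    its arguments; the result lies in [0, 100].

    Parameters
    ----------
    a, b : ProbeSequence or str
        Sequences to compare (plus strand by default).
    reverse_complement : bool
        Align ``a`` against the reverse complement of ``b`` ("plus/minus").
    """
    p = params or AlignmentParams()
    sa = a.bases if isinstance(a, ProbeSequence) else ProbeSequence("a", "", a).bases
    sb = b.bases if isinstance(b, ProbeSequence) else ProbeSequence("b", "", b).bases
    if reverse_complement:
        sb = _revcomp(sb)
    aligner = _make_aligner(p)
    alignments = aligner.align(sa, sb)
    best = max(
        _alignment_identity(aln, p)
        for aln in itertools.islice(alignments, max_alignments)
    )
    return float(np.clip(best, 0.0, 100.0))


def identity_matrix(
    probes: list[ProbeSequence],
    params: AlignmentParams | None = None,
    *,
    decimals: int = 1,
) -> pd.DataFrame:
    """Symmetric matrix of pairwise percent identities (diagonal = 100)."""
    _check_unique_ids(probes)
    ids = [pr.id for pr in probes]
    mat = pd.DataFrame(100.0, index=ids, columns=ids, dtype=float)
    for x, y in itertools.combinations(probes, 2):
        pid = round(percent_identity(x, y, params), decimals)
        mat.loc[x.id, y.id] = pid
        mat.loc[y.id, x.id] = pid
    return mat


@dataclass(frozen=True)
class CrossTalkParams:
    """Identity window, in percent, within which imperfect homology protects.

    The upper bound is exclusive so that perfect (100 %) homology — the
    silencing trigger itself — never counts as protection.
    """

    protection_low: float = 70.0
    protection_high: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.protection_low < self.protection_high <= 100.0):
            raise ValueError("require 0 <= protection_low < protection_high <= 100")

    def contains(self, identity: float) -> bool:
        return self.protection_low <= identity < self.protection_high


@dataclass(frozen=True)
class CrossTalkNetwork:
    """Pairwise identity matrix plus the protection (cross-talk) edges.

    ``edges`` holds unordered probe-id pairs whose identity lies in the
    protection window and whose pathways differ; a pathway is *protected*
    when at least one protection edge touches one of its probes.
    """

    probes: tuple[ProbeSequence, ...]
    identity: pd.DataFrame
    edges: frozenset[frozenset[str]]
    window: CrossTalkParams = field(default_factory=CrossTalkParams)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(pr.id for pr in self.probes)

    def pathway_of(self, probe_id: str) -> str:
        for pr in self.probes:
            if pr.id == probe_id:
                return pr.pathway
        raise KeyError(probe_id)

    def protected_pathways(self) -> frozenset[str]:
        """Pathways touched by at least one protection edge."""
        out: set[str] = set()
        for edge in self.edges:
            for pid in edge:
                out.add(self.pathway_of(pid))
        return frozenset(out)

    def to_json(self) -> str:
        doc = {
            "nodes": [
                {"id": pr.id, "pathway": pr.pathway, "length": len(pr)}
                for pr in self.probes
            ],
            "identity": {
                x: {y: float(self.identity.loc[x, y]) for y in self.identity.columns}
                for x in self.identity.index
            },
            "edges": sorted(sorted(e) for e in self.edges),
            "window": [self.window.protection_low, self.window.protection_high],
        }
        return json.dumps(doc, indent=2)


def _check_unique_ids(probes: list[ProbeSequence]) -> None:
    seen: set[str] = set()
    for pr in probes:
        if pr.id in seen:
            raise ValueError(f"duplicate probe id {pr.id!r}")
        seen.add(pr.id)


def build_crosstalk_network(
    probes: list[ProbeSequence],
    params: AlignmentParams | None = None,
    window: CrossTalkParams | None = None,
) -> CrossTalkNetwork:
    """Compute all pairwise identities and threshold them into edges.

    An edge joins probes *i* and *j* iff their identity lies in the
    protection window and their pathways differ (a probe cannot protect
    its own pathway).  The edge set is invariant under input order.
    """
    if len(probes) < 2:
        raise ValueError("need at least two probes to build a network")
    _check_unique_ids(probes)
    window = window or CrossTalkParams()
    mat = identity_matrix(probes, params)
    edges: set[frozenset[str]] = set()
    for x, y in itertools.combinations(probes, 2):
        if x.pathway == y.pathway:
            continue
        if window.contains(float(mat.loc[x.id, y.id])):
            edges.add(frozenset({x.id, y.id}))
    return CrossTalkNetwork(
        probes=tuple(sorted(probes, key=lambda pr: pr.id)),
        identity=mat,
        edges=frozenset(edges),
        window=window,
    )
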