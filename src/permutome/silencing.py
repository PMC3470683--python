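"""Downregulation-state classification from Northern band intensities.

Each (treatment, pathway) pair carries two densitometry readings: the
abundance of GDH-synthesized RNA homologous to the pathway's mRNA, and the
abundance of the target mRNA itself.  A minimum 2:1 ratio of silencing RNA
to target mRNA is the threshold for a silencing call.  A silenced mRNA
whose pathway is *protected* by an imperfect homolog (a cross-talk edge)
is only knocked down — PARTIAL, with ~50 % residual mRNA — whereas an
unprotected silenced mRNA is knocked out (FULL).  Below threshold, or when
no homologous silencing RNA was synthesized at all, the mRNA is
NOT_DOWNREGULATED.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .alignment import CrossTalkNetwork
from .catalogues import PATHWAYS

__all__ = [
    "DownregulationState",
    "BandObservation",
    "SilencingParams",
    "TreatmentStateVector",
    "classify_state",
    "residual_mrna_fraction",
    "classify_treatment",
]


class DownregulationState(str, enum.Enum):
    """Three-way per-pathway silencing call."""

    NOT_DOWNREGULATED = "NOT_DOWNREGULATED"
    PARTIAL = "PARTIAL"
    FULL = "FULL"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class BandObservation:
    """Digitized Northern band intensities for one (treatment, pathway).

    Intensities are in arbitrary densitometry units and are used raw; the
    study's protocol rejects housekeeping normalization because the
    housekeeping mRNAs were themselves reprogrammed.
    """

    treatment: str
    pathway: str
    gdh_rna_intensity: float
    mrna_intensity: float

    def __post_init__(self) -> None:
        for name in ("gdh_rna_intensity", "mrna_intensity"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.treatment}/{self.pathway}: {name} must be a "
                    f"finite non-negative number, got {v!r}"
                )


@dataclass(frozen=True)
class SilencingParams:
    """Thresholds of the silencing call.

    silencing_ratio_threshold
        Minimum GDH-RNA : mRNA intensity ratio for a silencing call
        (default 2.0, inclusive).
    detection_floor
        GDH-RNA intensity at or below which the band counts as absent.
    partial_residual_fraction
        Residual fraction of the target mRNA surviving a PARTIAL knockdown
        (default 0.5).
    """

    silencing_ratio_threshold: float = 2.0
    detection_floor: float = 0.0
    partial_residual_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.silencing_ratio_threshold <= 0:
            raise ValueError("silencing_ratio_threshold must be > 0")
        if not (0.0 < self.partial_residual_fraction < 1.0):
            raise ValueError("partial_residual_fraction must be in (0, 1)")


def classify_state(
    obs: BandObservation,
    protected: bool,
    params: SilencingParams | None = None,
) -> DownregulationState:
    """Classify one observation.

    NOT_DOWNREGULATED when the silencing RNA is absent (at or below the
    detection floor) or below the ratio threshold; otherwise PARTIAL when
    the pathway is protected and FULL when it is not.  A zero mRNA
    intensity with silencing RNA present is treated as an infinite ratio
    (above any threshold); :func:`classify_treatment` flags such pathways.
    """
    p = params or SilencingParams()
    if obs.gdh_rna_intensity <= p.detection_floor:
        return DownregulationState.NOT_DOWNREGULATED
    if obs.mrna_intensity > 0 and (
        obs.gdh_rna_intensity < p.silencing_ratio_threshold * obs.mrna_intensity
    ):
        return DownregulationState.NOT_DOWNREGULATED
    return DownregulationState.PARTIAL if protected else DownregulationState.FULL


def residual_mrna_fraction(
    state: DownregulationState, params: SilencingParams | None = None
) -> float:
    """Fraction of the target mRNA surviving in a given state."""
    p = params or SilencingParams()
    return {
        DownregulationState.NOT_DOWNREGULATED: 1.0,
        DownregulationState.PARTIAL: p.partial_residual_fraction,
        DownregulationState.FULL: 0.0,
    }[DownregulationState(state)]


@dataclass(frozen=True)
class TreatmentStateVector:
    """Pathway -> state map for one treatment over the pathway catalogue."""

    treatment: str
    states: Mapping[str, DownregulationState]
    flags: frozenset[str] = field(default_factory=frozenset)

    def multiplicities(self, n_states: int = 3) -> tuple[int, ...]:
        """State-group sizes, descending, padded with zeros to ``n_states``."""
        counts: dict[DownregulationState, int] = {}
        for s in self.states.values():
            counts[s] = counts.get(s, 0) + 1
        sizes = sorted(counts.values(), reverse=True)
        if len(sizes) > n_states:
            raise ValueError("more distinct states than n_states")
        return tuple(sizes) + (0,) * (n_states - len(sizes))

    def residual_fractions(
        self, params: SilencingParams | None = None
    ) -> dict[str, float]:
        return {
            pw: residual_mrna_fraction(s, params) for pw, s in self.states.items()
        }


def _protected_set(
    network: CrossTalkNetwork | Iterable[str] | None,
) -> frozenset[str]:
    if network is None:
        return frozenset()
    if isinstance(network, CrossTalkNetwork):
        return network.protected_pathways()
    return frozenset(network)


def classify_treatment(
    observations: Iterable[BandObservation],
    network: CrossTalkNetwork | Iterable[str] | None = None,
    params: SilencingParams | None = None,
    pathways: tuple[str, ...] = PATHWAYS,
) -> TreatmentStateVector:
    """Classify every pathway of one treatment into a state vector.

    ``network`` supplies the protection information — either a
    :class:`CrossTalkNetwork` (a pathway is protected iff it has at least
    one protection edge) or, as an expert override, an explicit collection
    of protected pathway labels.  Deterministic and independent of the
    input row order.
    """
    obs_list = list(observations)
    if not obs_list:
        raise ValueError("no observations supplied")
    treatments = {o.treatment for o in obs_list}
    if len(treatments) != 1:
        raise ValueError(f"observations span several treatments: {sorted(treatments)}")
    (treatment,) = treatments
    by_pathway: dict[str, BandObservation] = {}
    for o in obs_list:
        if o.pathway in by_pathway:
            raise ValueError(f"duplicate observation for pathway {o.pathway!r}")
        by_pathway[o.pathway] = o
    missing = [pw for pw in pathways if pw not in by_pathway]
    if missing:
        raise ValueError(f"missing pathway(s) for {treatment!r}: {', '.join(missing)}")

    protected = _protected_set(network)
    p = params or SilencingParams()
    states: dict[str, DownregulationState] = {}
    flags: set[str] = set()
    for pw in pathways:
        o = by_pathway[pw]
        states[pw] = classify_state(o, pw in protected, p)
        if o.mrna_intensity == 0 and o.gdh_rna_intensity > p.detection_floor:
            flags.add(pw)  # ratio was +inf; state decided by protection alone
    return TreatmentStateVector(
        treatment=treatment, states=states, flags=frozenset(flags)
    )
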