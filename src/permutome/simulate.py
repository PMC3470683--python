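"""Seeded generators for every input the pipeline consumes.

The study's densitometry tables were never deposited, so parameter-recovery
testing runs on synthetic data: sequence pairs mutated to a controlled
identity, band-intensity matrices generated from known true states with
multiplicative lognormal noise, and fatty-acid profiles coupled to residual
desaturase activity through a linear knockdown model.  All generators take
an explicit integer seed and never touch global random state; a fixed
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import math
import itertools

import numpy as np

from .alignment import IUPAC_SETS, ProbeSequence
from .catalogues import PATHWAYS, TREATMENT_LABELS
from .fattyacids import FattyAcidProfile
from .silencing import (
    BandObservation,
    DownregulationState,
    SilencingParams,
    TreatmentStateVector,
    residual_mrna_fraction,
)

__all__ = [
    "SimulationConfig",
    "mutate_to_identity",
    "random_probe",
    "simulate_bands",
    "random_state_vectors",
    "simulate_fatty_acids",
    "hexamer_composition_table",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generators.

    silenced_ratio / unsilenced_ratio are the mean GDH-RNA : baseline-mRNA
    intensity ratios for silenced (3.0, comfortably above the 2:1 call
    threshold) and unsilenced (0.5) pathways; noise_cv is the coefficient
    of variation of the multiplicative lognormal densitometry noise.
    ``wild_profile`` seeds the fatty-acid model (defaults to the untreated
    control composition when left None).
    """

    seed: int = 0
    pathways: tuple[str, ...] = PATHWAYS
    treatments: tuple[str, ...] = TREATMENT_LABELS
    noise_cv: float = 0.1
    silenced_ratio: float = 3.0
    unsilenced_ratio: float = 0.5
    baseline_intensity: float = 100.0
    wild_profile: FattyAcidProfile | None = None
    silencing: SilencingParams = field(default_factory=SilencingParams)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.silenced_ratio <= 0 or self.unsilenced_ratio <= 0:
            raise ValueError("intensity ratios must be positive")

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)


def random_probe(
    length: int, seed: int, *, id: str = "synthetic", pathway: str = ""
) -> ProbeSequence:
    """A uniform random A/C/G/T sequence of the given length."""
    rng = np.random.default_rng(seed)
    bases = "".join(rng.choice(list(_BASES), size=length))
    return ProbeSequence(id=id, pathway=pathway, bases=bases)


def mutate_to_identity(
    template: ProbeSequence, target_identity: float, seed: int
) -> ProbeSequence:
    """Substitute random positions until ungapped identity hits the target.

    Exactly ``round(L * (1 - target/100))`` unambiguous positions are
    replaced with a different concrete base, giving an ungapped identity of
    ``100 * (L - k) / L`` — within one percentage point of the target for
    templates of length >= 50.  Deterministic per seed.
    """
    if not (0.0 < target_identity <= 100.0):
        raise ValueError("target identity must be in (0, 100]")
    length = len(template)
    n_sub = round(length * (1.0 - target_identity / 100.0))
    achieved = 100.0 * (length - n_sub) / length
    if abs(achieved - target_identity) > 1.0:
        raise ValueError(
            f"target {target_identity} not attainable within 1 point on a "
            f"length-{length} sequence (closest: {achieved:.2f})"
        )
    if n_sub == 0:
        return template
    candidates = [
        i for i, sym in enumerate(template.bases) if len(IUPAC_SETS[sym]) == 1
    ]
    if n_sub > len(candidates):
        raise ValueError(
            f"need {n_sub} substitutable positions, template has {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(candidates), size=n_sub, replace=False)
    bases = list(template.bases)
    for idx in positions:
        pos = candidates[idx]
        alternatives = [b for b in _BASES if b != bases[pos]]
        bases[pos] = alternatives[rng.integers(len(alternatives))]
    return replace(template, id=f"{template.id}_mut", bases="".join(bases))


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=n)


def _as_state_map(
    true_states: Mapping, pathways: Iterable[str]
) -> dict[tuple[str, str], DownregulationState]:
    flat: dict[tuple[str, str], DownregulationState] = {}
    for key, value in true_states.items():
        if isinstance(value, TreatmentStateVector):
            for pw, s in value.states.items():
                flat[(value.treatment, pw)] = DownregulationState(s)
        else:
            flat[tuple(key)] = DownregulationState(value)
    missing = [
        (t, pw)
        for t in sorted({k[0] for k in flat})
        for pw in pathways
        if (t, pw) not in flat
    ]
    if missing:
        raise ValueError(f"true states missing for {missing[:5]}")
    return flat


def simulate_bands(
    true_states: Mapping,
    cfg: SimulationConfig | None = None,
) -> list[BandObservation]:
    """Band-intensity observations generated from known true states.

    ``true_states`` maps ``(treatment, pathway) -> DownregulationState``
    (or ``treatment -> TreatmentStateVector``).  The mRNA intensity is the
    baseline scaled by the residual fraction of the true state; the
    GDH-RNA intensity is the baseline times ``silenced_ratio`` (PARTIAL or
    FULL) or ``unsilenced_ratio`` (NOT_DOWNREGULATED); both carry
    independent multiplicative lognormal noise of CV ``noise_cv``.  With
    zero noise, classification recovers the true states exactly.
    """
    cfg = cfg or SimulationConfig()
    flat = _as_state_map(true_states, cfg.pathways)
    keys = sorted(flat)  # deterministic draw order
    rng = np.random.default_rng(cfg.seed)
    gdh_noise = _lognormal_factors(rng, cfg.noise_cv, len(keys))
    mrna_noise = _lognormal_factors(rng, cfg.noise_cv, len(keys))
    out: list[BandObservation] = []
    for i, (t, pw) in enumerate(keys):
        state = flat[(t, pw)]
        silenced = state is not DownregulationState.NOT_DOWNREGULATED
        ratio = cfg.silenced_ratio if silenced else cfg.unsilenced_ratio
        residual = residual_mrna_fraction(state, cfg.silencing)
        out.append(
            BandObservation(
                treatment=t,
                pathway=pw,
                gdh_rna_intensity=ratio * cfg.baseline_intensity * gdh_noise[i],
                mrna_intensity=residual * cfg.baseline_intensity * mrna_noise[i],
            )
        )
    return out


def random_state_vectors(
    protected: Iterable[str],
    cfg: SimulationConfig | None = None,
    *,
    p_silenced: float = 0.5,
) -> dict[str, TreatmentStateVector]:
    """Random true states consistent with a protection set.

    Protected pathways are drawn from {NOT_DOWNREGULATED, PARTIAL} and
    unprotected ones from {NOT_DOWNREGULATED, FULL} (each silenced with
    probability ``p_silenced``), so that classification against the same
    protection set can in principle recover them exactly.
    """
    cfg = cfg or SimulationConfig()
    protected = frozenset(protected)
    rng = np.random.default_rng(cfg.seed)
    out: dict[str, TreatmentStateVector] = {}
    for t in cfg.treatments:
        states: dict[str, DownregulationState] = {}
        for pw in cfg.pathways:
            if rng.random() >= p_silenced:
                states[pw] = DownregulationState.NOT_DOWNREGULATED
            elif pw in protected:
                states[pw] = DownregulationState.PARTIAL
            else:
                states[pw] = DownregulationState.FULL
        out[t] = TreatmentStateVector(treatment=t, states=states)
    return out


def simulate_fatty_acids(
    residual_desaturase: float,
    cfg: SimulationConfig | None = None,
    wild_profile: FattyAcidProfile | None = None,
) -> FattyAcidProfile:
    """Fatty-acid profile under a linear desaturase-knockdown model.

    Linoleate (C18:2) scales with the residual desaturase mRNA fraction;
    the mass removed from linoleate is added to oleate (C18:1), conserving
    their pooled sum — and hence total unsaturation — for every residual
    value.  All other codes are copied from the wild profile.  The linear
    response is the simplest model consistent with knockdown lowering
    linoleate from its wild-type level; it is a modeling assumption, not a
    measured dose-response.
    """
    if not (0.0 <= residual_desaturase <= 1.0):
        raise ValueError("residual_desaturase must be in [0, 1]")
    cfg = cfg or SimulationConfig()
    wild = wild_profile or cfg.wild_profile
    if wild is None:
        from .io import load_table2_profiles

        wild = next(p for p in load_table2_profiles() if p.treatment == "control")
    oleate = wild.value("C18:1")
    linoleate = wild.value("C18:2")
    new_linoleate = linoleate * residual_desaturase
    composition = dict(wild.composition)
    composition["C18:1"] = oleate + (linoleate - new_linoleate)
    composition["C18:2"] = new_linoleate
    censored = set(wild.censored) - {"C18:1", "C18:2"}
    if new_linoleate == 0.0:
        censored.add("C18:2")
        composition["C18:2"] = 0.0
    return FattyAcidProfile(
        treatment=f"synthetic_residual_{residual_desaturase:g}",
        composition=composition,
        censored=frozenset(censored),
        imputed_value=wild.imputed_value,
    )


def hexamer_composition_table(
    n_subunit_types: int = 3,
    subunit_freqs: Iterable[float] | None = None,
):
    """Hexamer subunit-composition classes with multinomial probabilities.

    GDH assembles its hexameric isoenzymes binomially from (by default)
    three subunit polypeptides.  Enumerates every multiset of size 6 over
    the subunit types and its multinomial probability; probabilities sum
    to 1.  Returns a :class:`pandas.DataFrame` sorted by descending
    probability, columns ``counts`` (one per subunit type) and
    ``probability``.
    """
    import pandas as pd

    if n_subunit_types < 1:
        raise ValueError("need at least one subunit type")
    if subunit_freqs is None:
        freqs = [1.0 / n_subunit_types] * n_subunit_types
    else:
        freqs = [float(f) for f in subunit_freqs]
        if len(freqs) != n_subunit_types:
            raise ValueError("one frequency per subunit type required")
        if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must be non-negative and sum to 1")
    rows = []
    for counts in itertools.combinations_with_replacement(
        range(n_subunit_types), 6
    ):
        k = [counts.count(i) for i in range(n_subunit_types)]
        coeff = math.factorial(6)
        for ki in k:
            coeff //= math.factorial(ki)
        prob = coeff * math.prod(f**ki for f, ki in zip(freqs, k))
        rows.append({"counts": tuple(k), "probability": prob})
    table = pd.DataFrame(rows).sort_values(
        "probability", ascending=False, kind="stable", ignore_index=True
    )
    return table
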