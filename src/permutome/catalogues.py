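"""Catalogues of the regulatory pathways and mineral-salt treatments.

The study system is Virginia-type peanut (*Arachis hypogaea*) grown under
ten mineral-salt regimens chosen to mimic the binomial subunit compositions
of the hexameric glutamate dehydrogenase (GDH) isoenzymes.  Ten regulatory
metabolic pathways are tracked at the mRNA level; their per-treatment
downregulation states are the raw material of the permutation model.
"""

from __future__ import annotations

from types import MappingProxyType

#: The ten regulatory pathways tracked at the mRNA level, in canonical order.
PATHWAYS: tuple[str, ...] = (
    "Pi_translocator",
    "GBSS",
    "PGM",
    "glucosyltransferase",
    "ACCase",
    "GAR_synthase_transformylase",
    "nitrate_reductase",
    "NADH_GOGAT",
    "fatty_acid_desaturase",
    "arachin_biosynthesis",
)

#: Mineral salts applied to the plots, with the molarity (mM) of each stock.
SALTS: MappingProxyType[str, float] = MappingProxyType(
    {
        "NH4Cl": 25.0,
        "Na3PO4": 20.0,
        "Na2SO4": 50.0,
        "KCl": 4.0,
    }
)

#: Treatment label -> the salts applied.  The untreated box is the control;
#: NPKS (all four salts) is the positive control.
TREATMENTS: MappingProxyType[str, tuple[str, ...]] = MappingProxyType(
    {
        "control": (),
        "N": ("NH4Cl",),
        "Pi": ("Na3PO4",),
        "S": ("Na2SO4",),
        "K": ("KCl",),
        "NPKS": ("NH4Cl", "Na3PO4", "Na2SO4", "KCl"),
        "PK": ("Na3PO4", "KCl"),
        "NS": ("NH4Cl", "Na2SO4"),
        "PN": ("Na3PO4", "NH4Cl"),
        "PS": ("Na3PO4", "Na2SO4"),
    }
)

TREATMENT_LABELS: tuple[str, ...] = tuple(TREATMENTS)


def validate_pathways(labels, catalogue: tuple[str, ...] = PATHWAYS) -> None:
    """Raise ``ValueError`` naming any label absent from the catalogue."""
    unknown = [p for p in labels if p not in catalogue]
    if unknown:
        raise ValueError(f"unknown pathway label(s): {', '.join(sorted(unknown))}")
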