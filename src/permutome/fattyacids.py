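"""Fatty-acid phenotype metrics: O/L ratio, unsaturation, band classes.

Peanut oil quality is summarized by the oleate-to-linoleate (O/L)
percentage ratio — the two acids are metabolically linked through the
delta-12 desaturases (FAD2A/FAD2B), so knocking down desaturase mRNA
shifts mass from linoleate (C18:2) into oleate (C18:1) and raises O/L.
Observed O/L bands mimic desaturase genotypes: low-normal ratios look like
the OL1OL1OL2OL2 wild type, mid-normal like mixtures of single-homozygous
mutants, and high-normal ratios progress toward the ol1ol1ol2ol2 double
mutant.

Composition tables report percent of total fatty acids per treatment;
trace entries are censored as "<0.1" and contribute zero to sums by
default (a half-bound 0.05 imputation is available).  Rounding of reported
metrics is decimal round-half-to-even at the table's printed precision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Mapping, NamedTuple

__all__ = [
    "FATTY_ACID_CODES",
    "UNSATURATED_CODES",
    "FattyAcidProfile",
    "OLRatio",
    "OLBand",
    "OLBands",
    "UndefinedRatioError",
    "ol_ratio",
    "percent_unsaturated",
    "percent_saturated",
    "classify_ol",
]

#: The eleven fatty-acid codes of the composition table, in table order.
FATTY_ACID_CODES: tuple[str, ...] = (
    "C16:0",
    "C16:1",
    "C18:0",
    "C18:1",
    "C18:2",
    "C18:3",
    "C20:0",
    "C20:1",
    "C22:0",
    "C22:1",
    "C24:0",
)

#: Codes with at least one double bond.
UNSATURATED_CODES: tuple[str, ...] = (
    "C16:1",
    "C18:1",
    "C18:2",
    "C18:3",
    "C20:1",
    "C22:1",
)


class UndefinedRatioError(ValueError):
    """O/L is undefined: the linoleate term is zero or censored."""


def _round_half_even(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class FattyAcidProfile:
    """Fatty-acid composition (percent of total) of one treatment.

    Censored "<0.1" cells carry value 0 with their code in ``censored``;
    ``imputed_value`` optionally replaces censored zeros in sums (e.g.
    0.05 for a half-bound imputation).
    """

    treatment: str
    composition: Mapping[str, float]
    censored: frozenset[str] = frozenset()
    oil_wt_percent: float | None = None
    imputed_value: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.composition) - set(FATTY_ACID_CODES)
        if unknown:
            raise ValueError(f"unknown fatty-acid code(s): {sorted(unknown)}")
        for code, v in self.composition.items():
            if v < 0:
                raise ValueError(f"{self.treatment}/{code}: negative percent {v}")
        for code in self.censored:
            if self.composition.get(code, 0.0) != 0.0:
                raise ValueError(
                    f"{self.treatment}/{code}: censored code must carry value 0"
                )

    def value(self, code: str) -> float:
        """Composition value with censored-cell imputation applied."""
        if code in self.censored:
            return self.imputed_value
        return float(self.composition.get(code, 0.0))

    def total(self) -> float:
        return sum(self.value(c) for c in FATTY_ACID_CODES)


class OLRatio(NamedTuple):
    """Unrounded O/L ratio and its half-to-even 2-decimal rounding."""

    value: float
    rounded: float


def ol_ratio(profile: FattyAcidProfile) -> OLRatio:
    """Oleate / linoleate percentage ratio (C18:1 / C18:2).

    Scale-invariant in the composition.  Raises
    :class:`UndefinedRatioError` when linoleate is zero or censored.
    """
    if "C18:2" in profile.censored:
        raise UndefinedRatioError(f"{profile.treatment}: linoleate censored")
    oleate = profile.value("C18:1")
    linoleate = profile.value("C18:2")
    if linoleate <= 0:
        raise UndefinedRatioError(f"{profile.treatment}: linoleate is {linoleate}")
    ratio = oleate / linoleate
    rounded = float(
        (Decimal(repr(oleate)) / Decimal(repr(linoleate))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_EVEN
        )
    )
    return OLRatio(value=ratio, rounded=rounded)


def percent_unsaturated(profile: FattyAcidProfile) -> float:
    """Sum of the unsaturated codes, rounded half-to-even to 1 decimal."""
    total = sum(profile.value(c) for c in UNSATURATED_CODES)
    return _round_half_even(total, 1)


def percent_saturated(profile: FattyAcidProfile) -> float:
    """Sum of the saturated codes, rounded half-to-even to 1 decimal."""
    total = sum(
        profile.value(c) for c in FATTY_ACID_CODES if c not in UNSATURATED_CODES
    )
    return _round_half_even(total, 1)


class OLBand(enum.Enum):
    """O/L band with the desaturase genotype it phenotypically mimics."""

    LOW_NORMAL = "OL1OL1OL2OL2-like wild type"
    MID_NORMAL = "mixture of single-homozygous-mutant-like variants"
    HIGH_NORMAL = "toward ol1ol1ol2ol2-like"

    @property
    def genotype_label(self) -> str:
        return self.value


@dataclass(frozen=True)
class OLBands:
    """Band boundaries for O/L classification.

    The observed bands (low-normal 1.26-1.38, mid-normal 1.60-1.81,
    high-normal 3.31) leave gaps, so the defaults cut at midpoints: below
    ``low_upper`` (1.50) is LOW_NORMAL, below ``mid_upper`` (2.50) is
    MID_NORMAL, and anything higher is HIGH_NORMAL.
    """

    low_upper: float = 1.50
    mid_upper: float = 2.50

    def __post_init__(self) -> None:
        if not (0 < self.low_upper < self.mid_upper):
            raise ValueError("require 0 < low_upper < mid_upper")


def classify_ol(ratio: float, bands: OLBands | None = None) -> OLBand:
    """Assign an O/L ratio to its band (monotone non-decreasing in ratio)."""
    if ratio <= 0:
        raise ValueError(f"O/L ratio must be positive, got {ratio}")
    b = bands or OLBands()
    if ratio < b.low_upper:
        return OLBand.LOW_NORMAL
    if ratio < b.mid_upper:
        return OLBand.MID_NORMAL
    return OLBand.HIGH_NORMAL
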