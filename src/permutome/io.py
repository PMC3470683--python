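"""Readers and writers for the package's plain-text formats, plus fixtures.

Canonical formats: FASTA for probe sequences (the description line carries
machine-readable ``key=value`` pairs, notably ``pathway=``), TSV for band
intensities, fatty-acid composition tables, identity matrices, and state
vectors, JSON for networks and permutation results.  TSV is UTF-8 with a
'.' decimal separator.  The packaged fixtures transcribe the published
composition table, probe sequences, and a derived per-treatment state
table; a manifest records the published tables' internal inconsistencies
so they can be excluded from exact checks rather than silently
"corrected".
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment import ProbeSequence
from .catalogues import PATHWAYS
from .fattyacids import FATTY_ACID_CODES, FattyAcidProfile
from .silencing import (
    BandObservation,
    DownregulationState,
    SilencingParams,
    TreatmentStateVector,
)

__all__ = [
    "read_probes_fasta",
    "write_probes_fasta",
    "read_band_table",
    "write_band_table",
    "read_fatty_acid_table",
    "read_state_table",
    "write_state_table",
    "load_table3_probes",
    "load_table2_profiles",
    "load_printed_metrics",
    "load_derived_states",
    "load_manifest",
]

_DATA = resources.files("permutome") / "data"


def _parse_description(description: str) -> dict[str, str]:
    out = {}
    for token in description.split()[1:]:
        if "=" in token:
            key, _, value = token.partition("=")
            out[key] = value.strip('"')
    return out


def read_probes_fasta(path) -> list[ProbeSequence]:
    """Read probes from FASTA; ``pathway=`` in the description is honoured."""
    probes = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            meta = _parse_description(rec.description)
            probes.append(
                ProbeSequence(
                    id=rec.id, pathway=meta.get("pathway", ""), bases=str(rec.seq)
                )
            )
    if not probes:
        raise ValueError(f"no sequences found in {path}")
    return probes


def write_probes_fasta(probes: Iterable[ProbeSequence], path) -> None:
    records = [
        SeqRecord(Seq(p.bases), id=p.id, description=f"pathway={p.pathway}")
        for p in probes
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


_BAND_COLUMNS = ["treatment", "pathway", "gdh_rna_intensity", "mrna_intensity"]


def read_band_table(path) -> list[BandObservation]:
    """Read a band-intensity TSV with the four canonical columns."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _BAND_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        BandObservation(
            treatment=str(row.treatment),
            pathway=str(row.pathway),
            gdh_rna_intensity=float(row.gdh_rna_intensity),
            mrna_intensity=float(row.mrna_intensity),
        )
        for row in frame.itertuples()
    ]


def write_band_table(observations: Iterable[BandObservation], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "treatment": o.treatment,
                "pathway": o.pathway,
                "gdh_rna_intensity": o.gdh_rna_intensity,
                "mrna_intensity": o.mrna_intensity,
            }
            for o in observations
        ],
        columns=_BAND_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_fatty_acid_table(path) -> list[FattyAcidProfile]:
    """Parse a composition TSV (rows = fatty-acid codes, columns = treatments).

    Numeric cells are percents of total; the literal cell ``<0.1`` marks a
    censored trace value (stored as 0 with a flag).  An optional ``oil_wt``
    row carries oil weight percent.  Unknown row codes and unparseable
    cells raise errors naming the offending cell.
    """
    text = Path(path).read_text() if not hasattr(path, "read") else path.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty fatty-acid table")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: no treatment columns")
    treatments = header[1:]
    composition: dict[str, dict[str, float]] = {t: {} for t in treatments}
    censored: dict[str, set[str]] = {t: set() for t in treatments}
    oil: dict[str, float] = {}
    for line in lines[1:]:
        cells = line.split("\t")
        code = cells[0]
        if code != "oil_wt" and code not in FATTY_ACID_CODES:
            raise ValueError(f"{path}: unknown fatty-acid code {code!r}")
        if len(cells) != len(header):
            raise ValueError(f"{path}: row {code!r} has {len(cells) - 1} cells, "
                             f"expected {len(treatments)}")
        for treatment, cell in zip(treatments, cells[1:]):
            cell = cell.strip()
            if cell == "<0.1":
                if code == "oil_wt":
                    raise ValueError(f"{path}: oil_wt cannot be censored")
                composition[treatment][code] = 0.0
                censored[treatment].add(code)
                continue
            try:
                value = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: unparseable cell {cell!r} at row {code!r}, "
                    f"column {treatment!r}"
                ) from None
            if code == "oil_wt":
                oil[treatment] = value
            else:
                composition[treatment][code] = value
    return [
        FattyAcidProfile(
            treatment=t,
            composition=composition[t],
            censored=frozenset(censored[t]),
            oil_wt_percent=oil.get(t),
        )
        for t in treatments
    ]


def read_state_table(path) -> dict[str, TreatmentStateVector]:
    """Read a states TSV (treatment, pathway, state) into state vectors."""
    frame = pd.read_csv(path, sep="\t")
    for col in ("treatment", "pathway", "state"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out: dict[str, TreatmentStateVector] = {}
    for treatment, group in frame.groupby("treatment", sort=False):
        states = {
            str(row.pathway): DownregulationState(str(row.state))
            for row in group.itertuples()
        }
        out[str(treatment)] = TreatmentStateVector(
            treatment=str(treatment), states=states
        )
    return out


def write_state_table(
    vectors: Iterable[TreatmentStateVector],
    path,
    params: SilencingParams | None = None,
) -> None:
    """Write states with residual mRNA fractions and infinite-ratio flags."""
    rows = []
    for v in vectors:
        residuals = v.residual_fractions(params)
        for pw, state in v.states.items():
            rows.append(
                {
                    "treatment": v.treatment,
                    "pathway": pw,
                    "state": str(state),
                    "residual_mrna_fraction": residuals[pw],
                    "flagged_infinite_ratio": pw in v.flags,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures


def load_table3_probes() -> list[ProbeSequence]:
    """The two probe cDNA sequences (arachin h1, fatty-acid desaturase)."""
    with resources.as_file(_DATA / "probes_table3.fa") as path:
        return read_probes_fasta(path)


def load_table2_profiles() -> list[FattyAcidProfile]:
    """The ten published fatty-acid composition columns."""
    with resources.as_file(_DATA / "fatty_acids_table2.tsv") as path:
        return read_fatty_acid_table(path)


def load_printed_metrics() -> pd.DataFrame:
    """The O/L and % unsaturated rows exactly as printed (metric x treatment)."""
    with resources.as_file(_DATA / "table2_printed_metrics.tsv") as path:
        return pd.read_csv(path, sep="\t", index_col="metric")


def load_derived_states() -> dict[str, TreatmentStateVector]:
    """Derived per-treatment state vectors reproducing the published counts."""
    with resources.as_file(_DATA / "treatment_states_derived.tsv") as path:
        vectors = read_state_table(path)
    for v in vectors.values():
        missing = [pw for pw in PATHWAYS if pw not in v.states]
        if missing:
            raise ValueError(f"fixture misses pathways for {v.treatment}: {missing}")
    return vectors


def load_manifest() -> dict:
    """Fixture manifest, including recorded table inconsistencies."""
    return json.loads((_DATA / "manifest.json").read_text())
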