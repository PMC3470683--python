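"""End-to-end report reproducing the study's numbers from packaged fixtures.

Runs the whole pipeline on the packaged fixtures — probe identity and the
protection network, per-treatment permutation counts with inverse
multiplicity search, the across-treatment distribution summary, and the
fatty-acid metrics — and checks each computed quantity against the
published expectation where one exists (on internally consistent table
columns only).  Returns a structured result; the CLI exits non-zero when
any check fails.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

from . import io as pio
from .alignment import build_crosstalk_network
from .fattyacids import classify_ol, ol_ratio, percent_unsaturated
from .permutation import (
    permutation_count,
    recover_state_multiplicities,
    summarize_distribution,
)

__all__ = ["Check", "Report", "run_report"]

#: Identity tolerance (percentage points) around the printed 77 % pair
#: similarity: the original BLAST parameterization is unknown.
IDENTITY_TOLERANCE = 2.0
PRINTED_PAIR_IDENTITY = 77.0


@dataclass
class Check:
    name: str
    expected: object
    observed: object
    passed: bool


@dataclass
class Report:
    sections: dict = field(default_factory=dict)
    checks: list[Check] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def add_check(self, name, expected, observed, passed=None) -> None:
        if passed is None:
            passed = expected == observed
        self.checks.append(Check(name, expected, observed, passed))

    def render(self) -> str:
        buf = _io.StringIO()
        for title, body in self.sections.items():
            buf.write(f"== {title} ==\n{body}\n\n")
        buf.write("== checks ==\n")
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            buf.write(f"[{status}] {c.name}: expected {c.expected}, "
                      f"observed {c.observed}\n")
        buf.write(f"\noverall: {'PASS' if self.passed else 'FAIL'}\n")
        return buf.getvalue()


def run_report(skip: tuple[str, ...] = ()) -> Report:
    """Compute every fixture-derived quantity and check it.

    ``skip`` may contain section names ("similarity", "permutation",
    "fattyacids") to omit; skipped sections contribute no checks.
    """
    report = Report()

    if "similarity" not in skip:
        probes = pio.load_table3_probes()
        network = build_crosstalk_network(probes)
        pair_identity = float(
            network.identity.loc["arachin_h1_probe", "fad_probe"]
        )
        report.sections["similarity"] = network.identity.to_string()
        report.add_check(
            "probe pair identity within +/-2 of printed 77 %",
            PRINTED_PAIR_IDENTITY,
            round(pair_identity, 1),
            abs(pair_identity - PRINTED_PAIR_IDENTITY) <= IDENTITY_TOLERANCE,
        )
        report.add_check(
            "arachin<->desaturase protection edge in [70,100) window",
            True,
            frozenset({"arachin_h1_probe", "fad_probe"}) in network.edges,
        )

    if "permutation" not in skip:
        vectors = pio.load_derived_states()
        expected = pio.load_manifest()["treatment_states_derived"][
            "expected_permutation_counts"
        ]
        counts = {t: permutation_count(v) for t, v in vectors.items()}
        lines = []
        for t, count in counts.items():
            triples = sorted(recover_state_multiplicities(10, count))
            lines.append(f"{t}: count={count} candidate multiplicities={triples}")
            report.add_check(
                f"permutation count for {t}", int(expected[t]), count
            )
        summary = summarize_distribution(counts)
        lines.append(
            f"mean={summary.mean:.0f} skewness={summary.skewness:.3f} "
            f"right_of_mean={sorted(summary.right_of_mean)}"
        )
        report.sections["permutation"] = "\n".join(lines)
        report.add_check(
            "across-treatment count distribution positively skewed",
            "skewness > 0",
            f"skewness = {summary.skewness:.3f}",
            summary.skewness > 0,
        )

    if "fattyacids" not in skip:
        profiles = {p.treatment: p for p in pio.load_table2_profiles()}
        printed = pio.load_printed_metrics()
        manifest = pio.load_manifest()["fatty_acids_table2"]
        lines = []
        for t, p in profiles.items():
            ratio = ol_ratio(p)
            unsat = percent_unsaturated(p)
            band = classify_ol(ratio.value)
            lines.append(
                f"{t}: O/L={ratio.rounded:.2f} %unsat={unsat:.1f} "
                f"band={band.name}"
            )
            if t in manifest["ol_consistent_columns"]:
                report.add_check(
                    f"O/L ratio for {t}",
                    float(printed.loc["ol_ratio", t]),
                    ratio.rounded,
                )
            if t in manifest["unsaturated_consistent_columns"]:
                report.add_check(
                    f"% unsaturated for {t}",
                    float(printed.loc["percent_unsaturated", t]),
                    unsat,
                )
        report.sections["fattyacids"] = "\n".join(lines)

    return report
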