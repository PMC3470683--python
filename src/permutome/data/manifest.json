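{
  "fatty_acids_table2": {
    "description": "Virginia-type peanut fatty acid composition (% of total) per mineral treatment; trace cells censored as <0.1; oil_wt row is oil weight percent.",
    "provenance": "transcribed from the published composition table",
    "ol_consistent_columns": ["control", "N", "Pi", "NPKS", "PK"],
    "unsaturated_consistent_columns": ["control", "N", "Pi", "S", "K", "PN", "PS"],
    "inconsistencies": [
      "Printed O/L for PN (1.29), PS (1.59), S (1.80), K (1.80) differ from round-half-even of the printed components (1.30, 1.60, 1.81, 1.81): printed cells appear truncated.",
      "Printed NS O/L (1.26) is irreconcilable with the printed NS oleate/linoleate cells (44.5/25.2 = 1.77); the NS linoleate cell is internally inconsistent.",
      "Printed % unsaturated for PK (82.4) and NPKS (84.0) differ from the sum of printed components (83.0, 83.9); the NS column (82.0) is inconsistent via its linoleate cell (sum 71.9).",
      "No correction is applied; inconsistent columns are excluded from exact checks."
    ]
  },
  "table2_printed_metrics": {
    "description": "The O/L and % unsaturated rows exactly as printed, for cross-checking recomputed metrics on consistent columns only."
  },
  "probes_table3": {
    "description": "The two probe cDNA sequences printed in the source table: arachin h1 probe (279 nt) and fatty-acid desaturase probe (284 nt, with IUPAC N calls).",
    "provenance": "transcribed verbatim"
  },
  "treatment_states_derived": {
    "description": "Per-treatment 10-pathway downregulation states.",
    "provenance": "derived completion, not measured data: arachin and desaturase states follow the published qualitative statements; the remaining pathways are filled so each treatment's state multiset reproduces its published permutation count.",
    "expected_permutation_counts": {
      "control": 210, "N": 2520, "Pi": 2520, "S": 2520, "K": 1260,
      "NPKS": 3150, "PK": 4200, "NS": 1260, "PN": 1260, "PS": 1260
    },
    "notes": [
      "1,260 inverts ambiguously to (5,4,1) or (6,2,2); the (5,4,1) split is used.",
      "The published mean permutation count (2,520) is not the arithmetic mean of the ten counts (2,016); summaries use the arithmetic mean."
    ]
  }
}
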