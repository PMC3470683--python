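"""Classify downregulation states from band intensities (PK-like pattern).

A pathway is silenced when its GDH-synthesized RNA reaches at least twice
the target mRNA's band intensity; protection by an imperfect homolog turns
the call from FULL (knockout) into PARTIAL (knockdown, ~50 % residual mRNA).
"""

from permutome import BandObservation, PATHWAYS, build_crosstalk_network, classify_treatment
from permutome.io import load_table3_probes

network = build_crosstalk_network(load_table3_probes())

signal = {"arachin_biosynthesis": 30.0, "fatty_acid_desaturase": 25.0}
bands = [
    BandObservation("PK", pw, signal.get(pw, 0.0), 10.0) for pw in PATHWAYS
]
vector = classify_treatment(bands, network)
for pathway, state in vector.states.items():
    print(f"{pathway:28s} {state}")
print("-> arachin and desaturase mRNAs are PARTIALLY downregulated (their")
print("   silencing RNAs exceed 2:1 but both pathways are cross-protected);")
print("   pathways without silencing RNA stay NOT_DOWNREGULATED.")
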