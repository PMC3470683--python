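"""Cross-homology of the two probe cDNAs and the protection network.

The arachin-h1 and fatty-acid-desaturase probes are cDNAs of GDH-synthesized
silencing RNAs.  Their mutual identity falls in the 70-80 % window in which
a silencing RNA cross-recognizes the other pathway's mRNA imperfectly,
protecting it from knockout.
"""

from permutome import build_crosstalk_network, percent_identity
from permutome.io import load_table3_probes

arachin, fad = load_table3_probes()
identity = percent_identity(arachin, fad)
print(f"{arachin.id} ({len(arachin)} nt) vs {fad.id} ({len(fad)} nt): "
      f"{identity:.1f} % identity")

network = build_crosstalk_network([arachin, fad])
print("protection edges:", sorted(sorted(e) for e in network.edges))
print("protected pathways:", sorted(network.protected_pathways()))
print("-> both pathways can only be knocked down, never knocked out,")
print("   because each silencing RNA imperfectly shields the other's target.")
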