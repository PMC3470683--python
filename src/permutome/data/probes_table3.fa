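>arachin_h1_probe pathway=arachin_biosynthesis source=table3a note="cDNA probe for mRNAs encoding Ara h1 isoforms (gb|AAB00861.1|)"
GGGGCACCATACGCGCGATTCCCCTTAGGAGTCTGAACGAAGCGAACCCGATGTAGGAGG
CGGGAAAACACGGAATGAGCGTCAACCAGGCGGTGAATGTTGGCCAGTTTTTGTATTGCC
ACCCGATGGAGATTATCTGCGGGGTGATGTTTCACCAGAACTTACTGCAGCGGGATTTCT
GGACGAGACTTTTTCCACACGAACAGCCCCCAAAACAACCGCCCCCACAACTATAAGAAA
GTTGAGGGAGGCAATGGTTCAAGACTCGTAAGGACGAAT
>fad_probe pathway=fatty_acid_desaturase source=table3b note="cDNA probe for mRNAs encoding fatty acid desaturase (gb|AF248739.1|, FAD2A, FAD2B)"
GGAANCGGCGCNAATANGCANCTTGACGGTTCTNGTAATNCTGAGTTANCCGAATGNAGA
NNGCGGGCAAAACATGTGAANGTAGCGTNCAANCCAGGCCGTTAAAGGTTGCCGAGCTTT
TGAAGTGCAACCCGATGGAGGTTATCTGCNGGGTGATGTTTCACCAGGACNTAATGGAGC
GGGATTTCTGGACGGACATTTTCCAGCAGACNGTCACCGAAAACTACCGCCGCCACTACT
TCAAGAAGGTTTAGGCAGGCTATCGGTCATGACTCANAAGGGCG
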