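>T1_gRNA guide RNA spacer plus scaffold|Anopheles gambiae; synthetic
GTTTAACACAGGTCAAGCGGGTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTC
CGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
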