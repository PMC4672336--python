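>OAS1_-340_-301 OAS1 promoter -340..-301, contains the duplicated GGAA motif
TTAGAATCATAGATGATCTTTCCACTTCCTGGTTTTTCTG
>OAS1_-379_-331 OAS1 promoter -379..-331, adjacent non-specific region
AGCTCTATATCAAAACGTTTATAGAGGCAATTTTGTAGTGTTAGAATCAT
>OAS1_-330_-301 OAS1 promoter -330..-301, contains the duplicated GGAA motif
AGATGATCTTTCCACTTCCTGGTTTTTCTG
>mtTTCC1 OAS1 -330..-301 with the first TTCC core mutated
AGATGATCTAAGGACTTCCTGGTTTTTCTG
>mtTTCC2 OAS1 -330..-301 with the second TTCC core mutated
AGATGATCTTTCCACAAGGTGGTTTTTCTG
>dupGGAA_competitor synthetic duplicated GGAA motif competitor
GAGCTCGCTAGCCTCGAGGGAAGCGGGAACCGCCGAGGCCAGATCT
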