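>five_prime_primer synthetic stand-in
TTTTTGATGTACACGAGTCGCGCT
>three_prime_primer synthetic stand-in
TTGAACTAGCTTTCGGCGGGTGCT
>body synthetic stand-in reporter CDS
ATGTAGGTACATGACAGGATACAAAAGGTAGCCTGATATGTAGCTTAAAGCTCACCCTGAGCTGAACTCTGCCTTTATTGCGGTGGTCGCTACCAACCCGTACACGACGCACAAATTAACAACTGGTCTTTAACGATCGGAACTCGATGATGGAGCATAGTTTACCAAGACCCGACCAGCGCGCAGGTCAAGATAAGATGTACCGGCCCACGGCGATCCGTTTCCCCAGCATGATGCTAG
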