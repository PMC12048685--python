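>Hoxa9_3UTR_ISH_probe_target length=514 coords=2078-2591 transcript=Hoxa9_isoform_A
AGTGAGCCTTTTAGGGGCTCATTTAAAAAGAGAGCAAGCTAGAAAGAAAAAGAAAGGACTGTCCGTCTCC
CTCTGTCTCCTCTCCCCCAAACCCAGCCTCCACCCGCACAAAGGGGCTCTAAATCCCAGGCCTCATCTCC
CCACTGGCAGTCCGTGCTCAGGCTGGCTCTTAGGCCTGCGGCTTTGATGGAGGAGGTATTGTAAGCTTTC
CATTTTATAGAAGGCACACACACACACAAGGGAGGGCATTAGCGCTATTGGCTGTATGTGCTAGCTTGTA
TATATATATATATATTTAAAAAAAATCTACCTGCTTCTGACTTTAAGCAAAAGGAAAGAAAACTACCTTT
TTATATAATGCACAACTGTTGATGACTGGCTGTATAGTTTTTAGTCTCTGTAGCTAATTTAATTTGCTCT
TCGTGTGGCAGATCATTCTGCCAAAATACTTGAACACTGTGTTTTATTGTGGTAATTATGTTTTGTGACT
CAAACTTCTGTGCTGGGTGAAGTA
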