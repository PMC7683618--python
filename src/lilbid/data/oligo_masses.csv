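oligo,sequence,mass_da
9_Amer,CATAATCAA,2700
10_Amer,TACTAAAAAC,3004
11_Amer,CATAATCAACT,3284
15_Amer,TACTAAAAACATAAT,4552
15b_Amer,CTCAAAAAAACTACA,4522
20_Amer,TCAACTCAAAAAAACTACAA,6055
9_Bmer,CCGTAATCT,2674
10_Bmer,CGTAATCTCA,2987
12_Bmer,CCGTAATCTCAC,3565
8_Cmer,GAAGAGCC,2444
10_Cmer,AGAAGAGCCG,3086
12_Cmer,TGAGAAGAGCCG,3720
35_Amer,ATTGTAGTTTTTTTGAGTTGATTATGTTTTTAGTA,10823
35_Bmer,TTTTGTGAGATTACGGAACCTTTTTTTTTTTTTGT,10735
35_Cmer,TTTTATCGGCTCTTCTCATTTTATTTTATTTTGTT,10621
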