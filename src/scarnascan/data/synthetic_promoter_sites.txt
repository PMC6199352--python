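# Synthetic aligned sigma-70 promoter element sites (bundled fixture).
# Generated once from fixed per-column base distributions, seed 731259.
# These are NOT experimentally curated promoters; import your own
# aligned site collection via build_pwm() for real scans.
>minus35
TAGTAT
TTGCCT
TTGTCA
TTGACT
TTGACA
TTGAAA
TTGGCC
TTCGTG
TTCACA
CAGGCA
TAGACA
TTAACT
TTGATA
TTGGGA
TTCACA
TTGGCA
TTGCCA
TTGACT
ATGACA
TTGACC
TTGACG
TTGACA
TTGACT
TTGATA
TGGACA
TCCACG
TTGAAA
TTAACA
CGGGCC
TTAACA
TCGGCT
TGGACC
CTAGCG
TTTACA
GTGACA
TTGGCA
TTGACA
TTGAGT
CTGACA
TTTACA
TTGACG
TTAAAA
TGGACA
TTGACG
TTGATA
TTGAAG
TTGCCA
TTGTCC
TACACA
CTGACA
>extended_minus10
AATAGTTGTTATATT
GAGAATTGATATAAT
AACGTTTGGTATAAT
CATATCGGTTATGAG
CAACGGTGATAGAAT
AATGCGAGCTATGAT
TACGCCTGATATATT
GATAATCGATATAAT
ACAGTCCGTTAGAAT
GGCTAGCGTTATAAG
TTTTTTTGATATCAT
TCTTAGTGGTATAAT
AGATCTTGATTCAAT
GCAAGGTTCTAGCTT
AACAGTGTGTAGAAA
CTTACCTGATTTCAT
ATGGGATGATACTAT
ACAGATTGGAATAAT
ATTTGATCCGATAAT
GAAACAATATCTATG
ACGATCCGCTCTGAT
AAGGCAGACTAACCT
GGAGTTTGATATCAT
ACACGCTAAAAAAAT
TTGCGCCAATACAAT
AGCATGTGATAGCGT
ACCATCGGTTATAGT
ACACTGTGATCTAAT
TCATTATGAAATAAT
AGTAGGGGTTACTAT
GTCTGCCGGTACAAT
CCTCTATGATATAAT
TGCTAGCGATATACA
GCAATCTGTTATAAT
CTTAATTGTTATTAT
TTTCAATGGTATAAT
TAAGTGTGGTATAAT
ACCTACGGTTATAAT
ATTGAGAGATATTCT
CAACTGTATAATAAT
AACGAATGAGATAAT
TATTTGTGATAAACT
CGTAAATGATAATAT
TTCCACTGTTATACT
GAGCGAAGATATAAG
GTTTTGTGATACAAT
CCTAGTTGACAGAAT
TGATATTGGTATTAT
AGTAATCGAAATAAT
GTCATCCCGTATAAA
>spacer_lengths
16
17
18
18
18
19
17
17
16
17
19
15
17
16
18
16
16
18
17
16
18
16
17
17
18
19
17
18
19
17
16
18
16
16
18
16
17
17
16
17
16
16
17
17
16
17
18
18
18
17
>default_threshold
13.63
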