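species	target_sequence
Agaricus bisporus	TTTCAGAGGAGCTGACCCCAAGTAA
Alternaria alternata	TTTGCTGATAGAGAGTGCGACTTGT
Apiotrichum laibachii	TTTGAACGCAACTTGCGCTCTCTGG
Aspergillus flavus	TTTCGGAGTTCACCGGCATCAGTGC
Auricularia heimuer	TTTCAAGACGAGCCGATTACCGGCA
Botrytis cinerea	TTTAGAGCCTGCCATTACTGACATA
Fusarium oxysporum	TTTGCTGCGTTCTTCATCGATGCCA
Ganoderma lucidum	TTTGTAGGCTTGGACTTGGAGGCTT
Lentinula edodes	TTTCTCCAATGAATAGAACAGATTGA
Ophiocordyceps sinensis	TTTGGGAGTGGTGACTCGATAATGA
Rhodotorula mucilaginosa	TTTACGGTCTAGCTCGTTCGTAATG
Saccharomyces cerevisiae	TTTAAGAACATTGTTCGCCTAGACG
Wolfiporia cocos	TTTCTAGGGTTCCCGTTCAACGGCG
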