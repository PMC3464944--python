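name	species	forward_name	forward_seq	forward_tm	reverse_name	reverse_seq	reverse_tm	expected_length	selected
Hand.1	Hypericum androsaemum	Hand.F.1.2	ACATCGTCGCCCCAAACC	67.0	Hand.R.1.2	CCATTATCCGCCCCATCCTC	66.5	65	0
Hand.2	Hypericum androsaemum	Hand.F.1.3	AAATGTGATACTTGGTGTGAATTGC	64.7	Hand.R.1.3	CGAGGTGTTGGGTTTGGG	64.8	135	0
Hand.3	Hypericum androsaemum	Hand.F.1.4	CACATCGTCGCCCCAAAC	65.6	Hand.R.1.4	ACCATTATCCGCCCCATCC	65.9	67	1
Hand.4	Hypericum androsaemum	Hand.F.1.4	CACATCGTCGCCCCAAAC	65.6	Hand.R.1.5	TTATCCGCCCCATCCTCTTC	65.4	63	0
Hand.5	Hypericum androsaemum	Hand.F.1.5	CGGCTGTCCTCCTGTTCATAAC	67.1	Hand.R.1.6	TCACACCAAGTATCACATTTCGCTAC	67.3	98	0
Hand.6	Hypericum androsaemum	Hand.F.2.1	CGAAATGTGATACTTGGTGTGAATTG	65.1	Hand.R.1.3	CGAGGTGTTGGGTTTGGG	64.8	137	0
Hasc.1	Hypericum ascyron	Hasc.F.1.2	TTCCTTCGGTTCATAACTAAAAC	60.9	Hasc.R.1.2	ACCCAATGAACTCGAAAGAG	61.7	225	0
Hasc.2	Hypericum ascyron	Hasc.F.1.4	GTGGCTTTCCTTCGGTTC	62.5	Hasc.R.1.2	ACCCAATGAACTCGAAAGAG	61.7	231	1
Hasc.3	Hypericum ascyron	Hasc.F.1.3	TTTCCTTCGGTTCATAACTAAAAC	61.5	Hasc.R.1.1	GAACTCGAAAGAGGCATTG	60.4	219	0
Hasc.4	Hypericum ascyron	Hasc.F.1.5	TCCTTCGGTTCATAACTAAAAC	60.2	Hasc.R.1.1	GAACTCGAAAGAGGCATTG	60.4	217	0
Hath.1	Hypericum athoum	Hath.F.1.1	CCCCGAAATTCCGATATCTC	61.8	Hath.R.1.1	CTTACAACCACCGCTAGTC	61.7	137	0
Hath.2	Hypericum athoum	Hath.F.1.1	CCCCGAAATTCCGATATCTC	61.8	Hath.R.1.3	CAACCACCGCTAGTCGTG	64.6	133	0
Hath.3	Hypericum athoum	Hath.F.1.1	CCCCGAAATTCCGATATCTC	61.8	Hath.R.1.4	CCGCTAGTCGTGGCTTTG	64.9	127	0
Hath.4	Hypericum athoum	Hath.F.1.3	GTGTCACACATCGTTGCC	63.2	Hath.R.1.3	CAACCACCGCTAGTCGTG	64.6	151	1
Hper.1	Hypericum perforatum	Hper.F.1.1	TGTAACGCTCCCGGCTGTG	69.0	Hper.R.1.1	CCGATTGTCTCTTGCGAGATATC	65.0	273	0
Hper.2	Hypericum perforatum	Hper.F.4.1	GGGGCTTCCTTCTGTTCATAAC	65.1	Hper.R.4.1	TCTTGCGAGATATCGGGATTTTG	64.9	222	1
Hper.3	Hypericum perforatum	Hper.F.1.2	ATAAGAAGTGTAACGCTCCCGGCTGTG	72.5	Hper.R.1.1	CCGATTGTCTCTTGCGAGATATC	65.0	281	0
Hper.4	Hypericum perforatum	Hper.F.1.3	GAAGTGTAACGCTCCCGGCTGTG	71.9	Hper.R.1.1	CCGATTGTCTCTTGCGAGATATC	65.0	277	0
Hper.5	Hypericum perforatum	Hper.F.1.4	AGTGTAACGCTCCCGGCTGTG	71.2	Hper.R.1.1	CCGATTGTCTCTTGCGAGATATC	65.0	275	0
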