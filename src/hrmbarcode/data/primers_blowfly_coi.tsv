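Name	Direction	Sequence	Ta	Amplicon_size
HRM_82F	Forward	AGTAGAAAATGGGGCTGGAA	54	82
HRM_82R	Reverse	ATCAACTGATGCTCCTCCAT
HRM_124F	Forward	AATGTAATTGTAACAGCTCACG	56	124
HRM_124R	Reverse	GTGGGAAAGCTATATCTGGAG
LCO-1490	Forward	GGTCAACAAATCATAAAGATATTGG	51	658
HCO-1490	Reverse	TAAACTTCAGGGTGACCAAAAAAT
C1-J-2495	Forward	CAGCTACTTTATGAGCTTTAGG	51	304
C1-N-2800	Reverse	CATTTCAAGCTGTGTAAGCATC
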