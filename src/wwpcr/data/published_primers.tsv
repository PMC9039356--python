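name	sequence	role	tier
WWP1	CGTCTCCAGTCTCCATGTGTTCGTC	WWP	1
WWP2	CGTCTCCAGTCTTAGGCACAGTGTC	WWP	2
WWP3	CGTCTCCAGTCTAGTCAGTCAGGTC	WWP	3
gadAGSP1	TCCATACCCTCATCTCCATTTCCAT	GSP	1
gadAGSP2	AACTATCACCCCACAACGTCATCTC	GSP	2
gadAGSP3	ACCGTTCATAGGCGAAATTGTTTGT	GSP	3
hygGSP1	CGGCAATTTCGATGATGCAGCTTGG	GSP	1
hygGSP2	CGGGACTGTCGGGCGTACACAAATC	GSP	2
hygGSP3	GACCGATGGCTGTGTAGAAGTACTC	GSP	3
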