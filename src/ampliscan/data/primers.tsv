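# Shipped primer definitions: published 16S primer pairs commonly used for
# vaginal-microbiome profiling.  Pools are repeated rows sharing a name.
# expected_position is the approximate E. coli 16S coordinate of the
# binding locus (used by the 5'-truncation heuristic).
name	orientation	sequence	expected_position
27f	forward	AGAGTTTGATCCTGGCTCAG	8
27f-pool	forward	AGAGTTTGATYMTGGCTCAG	8
27f-pool	forward	AGGGTTCGATTCTGGCTCAG	8
27f-pool	forward	AGAATTTGATCTTGGTTCAG	8
319f	forward	ACTCCTRCGGGAGGCAGCAG	319
341f	forward	CCTACGGGNGGCWGCAG	341
357f	forward	CCTACGGGAGGCAGCAG	357
515f	forward	GTGCCAGCMGCCGCGGTAA	515
967f	forward	CAACGCGARGAACCTTACC	967
338r	reverse	GCTGCCTCCCGTAGGAGT	338
515r	reverse	TTACCGCGGCKGCTGVCAC	515
534r	reverse	ATTACCGCGGCTGCTGG	534
805r	reverse	GACTACHVGGGTATCTAATCC	805
806r	reverse	GGACTACHVGGGTWTCTAAT	806
907r	reverse	CCGTCAATTCMTTTRAGT	907
926r	reverse	CCGTCAATTCMTTTRAGT	926
1061r	reverse	ACAACACGAGCTGACGAC	1061
515r-ext	reverse	GTGBCAGCMGCCGCGGTAA	515
515r-ext	reverse	GTGCCAGCAGCTGCGGTAA	515
534r-ext	reverse	GTGCCAGCAGCYGCGGTAA	534
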