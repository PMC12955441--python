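>synthetic_beta_spec_template | constructed stand-in template embedding the beta-spectrin assay primers and probe at the declared 107 bp amplicon spacing; not a natural sequence
ATGCATCTGTTACCCAGAGGTGCTCCTCACTACAGCCAGGTCATGGACTTCTTCTCAGGATATATTTGCG
CTGCGGAAAAATGACGACGGACATTTCGATTGATGCCTAGAAGTGTGTGATCGGTCCTGGCAACGAGTAC
ATCGATGCATTGCTGCCAAGTATTCGCAACTCCAGTTCCCGACTGTTCGGCTGATGGGGAGTCGACCTAC
CTTAATATCTCCGAGGTTGCCCTCACAAATGGCGATGTACGCCACACGGGCTACACT
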