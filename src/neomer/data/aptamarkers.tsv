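name	contrast	full_seq	reverse_primer
HAM_2753	HAM	CCAGATACAGACTCGAGGACTGAATCGGAACCATCGGCGCCAACAAGACATTCATACAGAAACAGTAGACAGC	TTTCTGTATGAATGTCT
HAM_6700	HAM	CCAGATACAGACTCGAGGTAAGAATGGGAACCATCGGCGCCAACACAGCATTCAATCAGAGACAGTAGACAGC	TCTCTGATTGAATGCTG
HAM_6968	HAM	CCAGATACAGACCAGAGGCGTGAATTTCAACCATCGGCGCCAACACCCCATTCCTGCAGATACAGTAGACAGC	TATCTGCAGGAATGGGG
HAM_8505	HAM	CCAGATACAGACAGGAGGGCGGAATTCCAACCATCGGCGCCAACATTTCATTCTAACAGACACAGTAGACAGC	TGTCTGTTAGAATGAAA
C-LAM_1	LAM	CCAGATACAGACTAGAGGTATGAATAGAAACCATCGGCGCCAACAATTCATTCATTCAGATGCAGTAGACAGC	CATCTGAATGAATGAAT
C-LAM_168	LAM	CCAGATACAGACAAGAGGACCGAATGTCAACCATCGGCGCCAACATTACATTCATTCAGATTCAGTAGACAGC	AATCTGAATGAATGTAA
C-LAM_262	LAM	CCAGATACAGACCAGAGGTTTGAATTCCAACCATCGGCGCCAACATTACATTCCTCCAGAATCAGTAGACAGC	ATTCTGGAGGAATGTAA
C-LAM_2709	LAM	CCAGATACAGACTTGAGGTTCGAATCTCAACCATCGGCGCCAACATGACATTCCTTCAGATTCAGTAGACAGC	AATCTGAAGGAATGTCA
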