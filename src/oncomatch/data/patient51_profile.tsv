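# Hormone-positive metastatic breast cancer case used as the worked example.
# Six pathogenic scoreable biomarkers; the ERBB2-negative finding is retained
# for reporting but excluded from the score denominator.
patient_id	gene	alteration_class	pathogenic	detail
P51	ER	expression_positive	true	hormone receptor positive
P51	PR	expression_positive	true	hormone receptor positive
P51	PTEN	copy_loss	true	gene-copy loss
P51	CCND1	amplification	true	gene-copy amplification
P51	FGFR1	amplification	true	gene-copy amplification
P51	PRKDC	amplification	true	gene-copy amplification
P51	ERBB2	expression_negative	true	Her2 negative
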