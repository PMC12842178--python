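label	value
male	61
female	33
age_at_onset_months_median	24
family_history	25
term_birth	83
premature_birth	11
ASD	36
ID	39
GDD	13
SLD	6
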