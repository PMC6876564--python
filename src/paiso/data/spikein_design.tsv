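design_id	barcode	designed_tail
PSI-10	GCTTGGAA	10
PSI-30	ACTAGATG	30
PSI-50	GCGGCCCC	50
PSI-70	TAGCTCCT	70
PSI-100	ACCGTGTA	100
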