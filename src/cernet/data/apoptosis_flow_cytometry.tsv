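group	late_pct	early_pct	viable_pct
TN	7.29	6.58	84.63
TL	15.40	16.50	66.47
LN	19.78	4.45	72.95
LL	29.98	6.89	60.68
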