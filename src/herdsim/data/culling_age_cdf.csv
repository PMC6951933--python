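age_days,cumulative_probability
730,0.05
1095,0.15
1460,0.33
1825,0.52
2190,0.68
2555,0.8
2920,0.89
3285,0.95
3650,1.0
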