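year,total
2000,65.53
2005,65.91
2010,65.83
2015,65.75
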