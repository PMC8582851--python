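group,2000,2005,2010,2015
natural,0.5708,0.4806,0.4284,0.4179
humanistic,0.2190,0.3783,0.4581,0.5004
location,0.2102,0.1411,0.1134,0.0817
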