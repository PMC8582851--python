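quantity,unit,value_2000,value_2015
gdp,billion yuan,17.376,133.061
urban_population_density,persons,614300,886600
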