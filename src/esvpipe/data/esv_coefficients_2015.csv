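category,service,cropland,forestland,grassland,water,unused
provisioning,food_production,1324.5,437.1,569.5,702.0,26.5
provisioning,raw_material_production,516.5,3947.0,476.8,463.6,53.0
regulating,gas_regulation,953.6,5721.8,1986.7,675.5,79.5
regulating,climate_regulation,1284.8,5390.7,2066.2,2728.4,172.2
regulating,hydrological_regulation,1019.9,5417.1,2013.2,24860.6,92.7
regulating,waste_treatment,1841.0,2278.1,1748.3,19668.6,344.4
supporting,soil_conservation,1947.0,5324.4,2966.8,543.0,225.2
supporting,biodiversity_maintenance,1351.0,5973.4,2476.8,4543.0,529.8
cultural,aesthetic_landscape,225.2,2754.9,1152.3,5880.7,317.9
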