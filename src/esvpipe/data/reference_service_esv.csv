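category,service,2000,2005,2010,2015
provisioning,food_production,1.71,1.70,1.69,1.68
provisioning,raw_material_production,5.87,5.86,5.86,5.86
regulating,gas_regulation,8.95,8.95,8.95,8.94
regulating,climate_regulation,8.89,8.90,8.90,8.88
regulating,hydrological_regulation,10.18,10.34,10.35,10.35
regulating,waste_treatment,6.10,6.23,6.20,6.20
supporting,soil_conservation,9.34,9.32,9.32,9.30
supporting,biodiversity_maintenance,9.95,9.97,9.96,9.95
cultural,aesthetic_landscape,4.56,4.60,4.60,4.60
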