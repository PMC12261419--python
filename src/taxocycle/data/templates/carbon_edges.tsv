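function_name	anchor_id	substrate	product
organic_carbon_oxidation	label_organic_carbon_oxidation	organic carbon	CO2
methanogenesis	label_methanogenesis	CO2+H2	CH4
acetogenesis_wood_ljungdahl	label_acetogenesis_wood_ljungdahl	CO2+H2	acetate
acetate_oxidation	label_acetate_oxidation	acetate	CO2
fermentation	label_fermentation	organic carbon	acetate
ethanol_oxidation	label_ethanol_oxidation	ethanol	acetate
hydrogen_generation	label_hydrogen_generation	organic carbon	H2
hydrogen_oxidation	label_hydrogen_oxidation	H2	H2O
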