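# Coarse-grained metabolic functions: cycle membership and Boolean formula
# over marker-profile identifiers (AND binds tighter than OR).
# Editable packaged data: edit or replace this file to change the call set
# without touching code.
function_name	cycle	formula
fermentation	carbon	ackA AND pta OR ldh OR adhE
organic_carbon_oxidation	carbon	gapA OR ldh
ethanol_oxidation	carbon	adhE AND aldB
acetogenesis_wood_ljungdahl	carbon	acsB AND fthfs
acetate_oxidation	carbon	acsA
methanogenesis	carbon	mcrA OR mtaB AND mtbA
hydrogen_generation	carbon	hycE OR hydA
hydrogen_oxidation	carbon	hyaB OR hydB AND hydG
sulfate_reduction	sulfur	dsrA AND dsrB
sulfur_oxidation	sulfur	soxB OR sqr
denitrification	nitrogen	narG AND (nirK OR nirS)
nitrate_reduction	nitrogen	narG OR napA
nitrification	nitrogen	amoA AND hao
iron_reduction	other	mtrB OR omcB
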