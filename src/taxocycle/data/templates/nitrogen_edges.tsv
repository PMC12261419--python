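function_name	anchor_id	substrate	product
nitrification	label_nitrification	NH4+	NO3-
nitrate_reduction	label_nitrate_reduction	NO3-	NO2-
denitrification	label_denitrification	NO3-	N2
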