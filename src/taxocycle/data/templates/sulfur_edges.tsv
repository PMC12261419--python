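function_name	anchor_id	substrate	product
sulfate_reduction	label_sulfate_reduction	SO4 2-	H2S
sulfur_oxidation	label_sulfur_oxidation	H2S	SO4 2-
iron_reduction	label_iron_reduction	Fe(III)	Fe(II)
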