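# Synthetic marker-profile inventory (stand-ins for curated enzyme HMMs).
# Each consensus is an alternating two-letter 10-mer; the letter pairs are
# pairwise distinct and never mutual reverses, so any two profiles share at
# most one alignable match position and cross-profile scores stay at or
# below one match emission (~4.32 bits), far under 0.5x the 20-bit cutoff.
profile_name	consensus	cutoff_bits
ackA	ACACACACAC	20.0
pta	ADADADADAD	20.0
ldh	AEAEAEAEAE	20.0
adhE	AFAFAFAFAF	20.0
gapA	AGAGAGAGAG	20.0
aldB	AHAHAHAHAH	20.0
acsA	AIAIAIAIAI	20.0
acsB	AKAKAKAKAK	20.0
fthfs	ALALALALAL	20.0
mcrA	AMAMAMAMAM	20.0
mtaB	ANANANANAN	20.0
mtbA	APAPAPAPAP	20.0
hycE	AQAQAQAQAQ	20.0
hydA	ARARARARAR	20.0
hyaB	ASASASASAS	20.0
hydB	ATATATATAT	20.0
hydG	AVAVAVAVAV	20.0
dsrA	AWAWAWAWAW	20.0
dsrB	AYAYAYAYAY	20.0
soxB	CDCDCDCDCD	20.0
sqr	CECECECECE	20.0
narG	CFCFCFCFCF	20.0
napA	CGCGCGCGCG	20.0
nirK	CHCHCHCHCH	20.0
nirS	CICICICICI	20.0
amoA	CKCKCKCKCK	20.0
hao	CLCLCLCLCL	20.0
mtrB	CMCMCMCMCM	20.0
omcB	CNCNCNCNCN	20.0
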