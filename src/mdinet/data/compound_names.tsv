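formula	name
C5H7NO3	5-Oxoproline
C7H8O4S	p-cresol sulfate
C7H10N2O4	S-AMPA
C7H12O6	Quinic acid
C6H12O9S	D-Glucose-6-sulfate
C10H13NO	N-Acetylphenyl-ethylamine
C7H14O7	Sedoheptulose
C9H16O9	alpha-mannosylglycerate
C10H20O2	Decanoic acid
C10H20O3	10-Hydroxydecanoic acid
C15H22O2	Valerenic acid
C20H32O2	Arachidonic acid
C20H34O2	Dihomo-gamma-linolenic acid
C39H74O5	DG (36:1)
C42H86NO7P	PC/PE
C6H12O6	D-Glucose
C3H6O3	Lactic acid
C6H8O7	Citric acid
C5H9NO4	Glutamic acid
C5H10N2O3	Glutamine
C6H14N4O2	Arginine
C9H11NO3	Tyrosine
C5H4N4O3	Uric acid
C4H6O5	Malic acid
C3H4O3	Pyruvic acid
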