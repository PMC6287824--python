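label	formula	description
CH2	CH2	methylene / alkyl chain extension
H2	H2	hydrogenation / saturation
O	O	oxidation / hydroxylation
H2O	H2O	hydration / condensation
CO	CO	carbonylation
CO2	CO2	carboxylation / decarboxylation
NH3	NH3	amination / deamination
NH	NH	imine formation
CH2O	CH2O	formaldehyde unit / hydroxymethylation
C2H2O	C2H2O	acetylation (ketene unit)
C2H4	C2H4	ethylene / double chain extension
S	S	thiolation
SO3	SO3	sulfation
HPO3	HPO3	phosphorylation
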