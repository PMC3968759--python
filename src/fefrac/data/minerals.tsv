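# Mineral registry: Fe phases relevant to anoxic clay tailings / sediments.
# Columns: name, formula (hydrate-dot notation allowed), fe_oxidation_state
# {II, III, mixed}, crystallinity {amorphous, crystalline}, fe2_fraction
# (fraction of the mineral's Fe that is ferrous).
# "fes" stands for amorphous monosulfide sensu lato (mackinawite FeS0.94 +
# amorphous FeS), registered with the ideal FeS formula.
# "phyllosilicate_fe" is a placeholder for structural clay iron (illite,
# chlorite, smectite); its formula is elemental Fe and its mixed valence is
# split 50:50 by convention.
name	formula	fe_oxidation_state	crystallinity	fe2_fraction
ferrihydrite	5Fe2O3.9H2O	III	amorphous	0.0
goethite	FeOOH	III	crystalline	0.0
lepidocrocite	FeOOH	III	crystalline	0.0
akaganeite	FeOOH	III	crystalline	0.0
hematite	Fe2O3	III	crystalline	0.0
magnetite	Fe3O4	mixed	crystalline	0.3333333333333333
green_rust	Fe3(OH)8	mixed	amorphous	0.6666666666666666
siderite	FeCO3	II	crystalline	1.0
pyrite	FeS2	II	crystalline	1.0
fes	FeS	II	amorphous	1.0
vivianite	Fe3(PO4)2.8H2O	II	crystalline	1.0
phyllosilicate_fe	Fe	mixed	crystalline	0.5
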