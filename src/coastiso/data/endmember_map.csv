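raw_label,endmember_class
POM,pPOM
particulate organic matter,pPOM
pPOM,pPOM
phytoplankton,pPOM
sediment,sPOM
sediment organic matter,sPOM
sPOM,sPOM
ice POM,iPOM
iPOM,iPOM
ice algae,iPOM
benthic microalgae,benthic_microalgae
microphytobenthos,benthic_microalgae
macroalgae,macroalgae
red algae,macroalgae
brown algae,macroalgae
kelp,macroalgae
Laminaria,macroalgae
Saccharina,macroalgae
Fucus,macroalgae
Desmarestia,macroalgae
Pylaiella,macroalgae
Ectocarpus,macroalgae
Phycodrys,macroalgae
Polysiphonia,macroalgae
Odonthalia,macroalgae
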