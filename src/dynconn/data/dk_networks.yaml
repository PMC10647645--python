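# Default whole-cortex ROI -> network mapping (34 regions x 2 hemispheres).
# Coarse editable default used by the synthetic cohort generator; supply
# your own mapping for real data.
DMN:
- medialorbitofrontal_lh
- medialorbitofrontal_rh
- rostralanteriorcingulate_lh
- rostralanteriorcingulate_rh
- posteriorcingulate_lh
- posteriorcingulate_rh
- isthmuscingulate_lh
- isthmuscingulate_rh
- precuneus_lh
- precuneus_rh
- inferiorparietal_lh
- inferiorparietal_rh
- middletemporal_lh
- middletemporal_rh
- parahippocampal_lh
- parahippocampal_rh
- entorhinal_lh
- entorhinal_rh
- temporalpole_lh
- temporalpole_rh
- frontalpole_lh
- frontalpole_rh
- superiorfrontal_lh
- superiorfrontal_rh
DAN:
- superiorparietal_lh
- superiorparietal_rh
- caudalmiddlefrontal_lh
- caudalmiddlefrontal_rh
- precentral_lh
- precentral_rh
- postcentral_lh
- postcentral_rh
- paracentral_lh
- paracentral_rh
- supramarginal_lh
- supramarginal_rh
SAN:
- insula_lh
- insula_rh
- caudalanteriorcingulate_lh
- caudalanteriorcingulate_rh
- rostralmiddlefrontal_lh
- rostralmiddlefrontal_rh
- parsopercularis_lh
- parsopercularis_rh
- parstriangularis_lh
- parstriangularis_rh
- parsorbitalis_lh
- parsorbitalis_rh
- lateralorbitofrontal_lh
- lateralorbitofrontal_rh
- superiortemporal_lh
- superiortemporal_rh
- inferiortemporal_lh
- inferiortemporal_rh
- transversetemporal_lh
- transversetemporal_rh
- bankssts_lh
- bankssts_rh
- fusiform_lh
- fusiform_rh
VIS:
- lateraloccipital_lh
- lateraloccipital_rh
- cuneus_lh
- cuneus_rh
- pericalcarine_lh
- pericalcarine_rh
- lingual_lh
- lingual_rh
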