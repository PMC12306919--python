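# 16 a priori stress-processing ROIs (6-mm spheres at MNI mm coordinates),
# as published. Stored verbatim, including two apparent inconsistencies:
#  - rows 3-4: the left/right labels disagree with the sign of x (printed so);
#  - "Left amygdala" z = +14 while the right amygdala has z = -14 (possible
#    sign typo in the source); kept as printed, not "fixed".
label,x,y,z,diameter,note
Right insula/BA 13,36,22,0,6,Brodmann area 13
Left insula/BA 13,-36,22,0,6,Brodmann area 13
Right insula/BA 13,-32,20,4,6,Brodmann area 13; label/sign as printed
Left insula/BA 13,32,20,4,6,Brodmann area 13; label/sign as printed
Right basal ganglia,14,0,-2,6,
Left basal ganglia,-14,0,-2,6,
Right parahippocampal gyrus,18,-6,-18,6,
Right amygdala,20,-4,-14,6,
Left amygdala,-20,-4,14,6,z sign as printed; right homologue is -14
Left superior frontal gyrus/BA 25,-8,52,38,6,Brodmann area 25
Left precuneus/BA 7,-22,-48,50,6,Brodmann area 7
Left putamen,-14,12,-10,6,
Left thalamus,-10,2,4,6,
Left insula/BA 13,-46,4,-4,6,Brodmann area 13
Left inferior frontal gyrus/BA 9,-44,14,22,6,Brodmann area 9
Left parahippocampal gyrus/BA 28,-18,-4,-16,6,Brodmann area 28
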