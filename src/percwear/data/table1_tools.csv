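tool_id,tool_type,raw_material,nut_species,max_length_mm,max_breadth_mm,max_thickness_mm,volume_cm3,mass_g
CGG23,hammer,GD,coula,264,189,61.8,1169.6,3275.0
CQQ34-18,hammer,Q,coula,136,87.8,71.9,329.2,855.8
M Granite Hammer,hammer,MG,panda,315,257,189,7282.4,18934.2
CTD1,hammer,Q,coula,93.1,90,50.7,158.8,412.9
PPGd,hammer,GD,panda,234,185,118,2771.3,7759.6
PGQ18,hammer,Q,panda,296,211,139,4513.4,11734.8
PPQ1003,hammer,Q,panda,185,140,123,1425.5,3706.3
PrGG1017,hammer,MG,parinari,164,163,90.4,1420.4,3693.1
PrPrQ 3015,hammer,Q,parinari,243,227,219,4646.9,12082.0
PWS5,hammer,GD,panda,284,172,100,1987.6,5565.3
PWS7,hammer,GD,panda,254,235,121,4281.1,11987.1
PGG3005-Ex,anvil,MG,panda,210,172,,,
PGQ18-A,anvil,MG,panda,299,274,,,
PGQ18-B,anvil,MG,panda,589,260,,,
PGU3012,anvil,MG,panda,614,364,,,
PGU3013,anvil,MG,panda,1504,621,,,
PRGU3014,anvil,MG,parinari,838,485,,,
SGdGd-A,anvil,GD,sacaglottis,453,237,,,
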