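# Synthetic demonstration list of mining-contaminant genera.
# The published contaminant database (206 sequences / 70 genera compiled from
# earlier South African mine-water and mine-air surveys) is not deposited;
# this stand-in list exists so the screening procedure can be exercised.
Rheinheimera
Blastomonas
Novosphingobium
Meiothermus
Pseudomonas
Acinetobacter
Sphingomonas
Ralstonia
Stenotrophomonas
Delftia
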