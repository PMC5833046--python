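node	community
SLC3A2	amino_acid
SLC7A1	amino_acid
SLC7A5	amino_acid
SLC7A6	amino_acid
SLC7A7	amino_acid
SLC7A8	amino_acid
SLC7A11	amino_acid
SLC38A1	amino_acid
SLC38A2	amino_acid
SLC38A5	amino_acid
SLC12A8	amino_acid
SLC6A2	amino_acid
SLC19A1	vitamin
SLC19A2	vitamin
SLC19A3	vitamin
SLC46A1	vitamin
SLC5A6	vitamin
LMBRD1	vitamin
SLC22A15	vitamin
SLC23A1	vitamin
SLC23A2	vitamin
SLC23A3	vitamin
SLC30A1	ion
SLC30A2	ion
SLC30A4	ion
SLC39A1	ion
SLC39A8	ion
TRPV6	ion
SLC4A1	ion
SLC26A2	ion
SLC26A6	ion
SLC9A1	ion
SLC9B2	ion
SLC5A5	ion
SLC26A4	ion
SLC11A2	ion
ABCA1	lipid_carb
ABCG1	lipid_carb
ABCG2	lipid_carb
SLC47A1	lipid_carb
SLC27A2	lipid_carb
SLC27A4	lipid_carb
SLC2A1	lipid_carb
SLC16A1	lipid_carb
SLC16A3	lipid_carb
SLC16A4	lipid_carb
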