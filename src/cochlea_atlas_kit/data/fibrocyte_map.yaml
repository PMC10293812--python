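# Editable mapping from the high/low combination over the fibrocyte
# marker triplet (Slc12a2, Gjb2, Car2), written as an H/L string in that
# order, to one of the five spiral-ligament fibrocyte subtypes.
# Combinations missing from this table are labeled fibrocyte-unresolved.
HHH: fibrocyte-I
HLH: fibrocyte-II
LLH: fibrocyte-III
HLL: fibrocyte-IV
LHL: fibrocyte-V
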