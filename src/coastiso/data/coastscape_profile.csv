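feature,fjord,lagoon,shelf,strait
barrier_islands,--,++,--,--
land_3_sides_sill,++,--,--,--
two_land_two_outlets,--,-,--,++
distant_from_land,--,--,+,+
glacial_input,+,--,--,-
riverine_input,-,++,+,--
salinity_fluctuation,--,++,-,--
macroalgal_endmember,+,-,-,+
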