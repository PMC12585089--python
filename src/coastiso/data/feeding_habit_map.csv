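raw_habit,feeding_habit
grazer,deposit_feeder
surface deposit feeder,deposit_feeder
subsurface deposit feeder,deposit_feeder
deposit feeder,deposit_feeder
filter feeder,suspension_feeder
suspension feeder,suspension_feeder
parasite,predator
predator,predator
fish,predator
mammal,predator
scavenger,opportunist_scavenger
omnivore,opportunist_scavenger
opportunist/scavenger,opportunist_scavenger
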