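# Study-like simulation: the 16 consumer coastscape x habit cells and
# the pPOM/sPOM cells per coastscape, parameterized from published
# per-cell mean +/- sd summaries, at ~1/10 of each cell's sample size.
default_corr: 0.0

coastscape_defaults:
  fjord:
    depth_range: [5, 300]
    lon_range: [10, 25]        # Svalbard sector
    lat_range: [76, 80]
  lagoon:
    depth_range: [1, 10]
    lon_range: [-150, -141]    # Beaufort Sea sector
    lat_range: [69, 71]
  shelf:
    depth_range: [5, 45]
    lon_range: [-168, -158]    # Northern Bering/Chukchi sector
    lat_range: [64, 72]
  strait:
    depth_range: [17, 300]
    lon_range: [-100, -85]     # Canadian Arctic Archipelago sector
    lat_range: [68, 75]

habit_pools:
  POM: [["", ""]]
  sediment organic matter: [["", ""]]
  suspension feeder:
    [[Serripes, Mollusca], [Astarte, Mollusca],
     [Balanus, Arthropoda], [Halichondria, Porifera]]
  deposit feeder:
    [[Macoma, Mollusca], [Ctenodiscus, Echinodermata],
     [Maldane, Annelida]]
  omnivore:
    [[Onisimus, Arthropoda], [Buccinum, Mollusca],
     [Ophiura, Echinodermata]]
  predator:
    [[Boreogadus, Chordata], [Urticina, Cnidaria], [Hyas, Arthropoda]]

groups:
  # pelagic POM
  - {coastscape: fjord,  category: end-member, habit: POM, mean: [-25.7, 4.6], sd: [2.0, 2.4], n: 24}
  - {coastscape: lagoon, category: end-member, habit: POM, mean: [-26.7, 6.7], sd: [1.5, 2.2], n: 20}
  - {coastscape: shelf,  category: end-member, habit: POM, mean: [-24.1, 7.1], sd: [2.0, 2.4], n: 20}
  - {coastscape: strait, category: end-member, habit: POM, mean: [-25.9, 6.4], sd: [2.1, 1.4], n: 20}
  # sediment POM
  - {coastscape: fjord,  category: end-member, habit: sediment organic matter, mean: [-23.2, 5.1], sd: [1.7, 1.7], n: 20}
  - {coastscape: lagoon, category: end-member, habit: sediment organic matter, mean: [-25.8, 3.2], sd: [0.9, 1.2], n: 20}
  - {coastscape: shelf,  category: end-member, habit: sediment organic matter, mean: [-24.2, 6.0], sd: [1.5, 2.2], n: 20}
  - {coastscape: strait, category: end-member, habit: sediment organic matter, mean: [-23.1, 7.2], sd: [0.5, 1.3], n: 20}
  # suspension feeders
  - {coastscape: fjord,  category: consumer, habit: suspension feeder, mean: [-22.1, 8.0],  sd: [2.1, 2.0], n: 63}
  - {coastscape: lagoon, category: consumer, habit: suspension feeder, mean: [-21.9, 9.8],  sd: [2.2, 1.9], n: 25}
  - {coastscape: shelf,  category: consumer, habit: suspension feeder, mean: [-20.6, 10.5], sd: [2.0, 2.1], n: 95}
  - {coastscape: strait, category: consumer, habit: suspension feeder, mean: [-20.4, 11.9], sd: [2.6, 3.1], n: 20}
  # deposit feeders
  - {coastscape: fjord,  category: consumer, habit: deposit feeder, mean: [-20.8, 8.9],  sd: [1.7, 2.4], n: 40}
  - {coastscape: lagoon, category: consumer, habit: deposit feeder, mean: [-20.2, 9.7],  sd: [2.2, 1.5], n: 20}
  - {coastscape: shelf,  category: consumer, habit: deposit feeder, mean: [-19.6, 10.9], sd: [1.9, 2.5], n: 64}
  - {coastscape: strait, category: consumer, habit: deposit feeder, mean: [-19.0, 11.7], sd: [2.1, 2.4], n: 20}
  # opportunists / scavengers (raw habit term: omnivore)
  - {coastscape: fjord,  category: consumer, habit: omnivore, mean: [-20.5, 10.3], sd: [2.4, 1.9], n: 29}
  - {coastscape: lagoon, category: consumer, habit: omnivore, mean: [-20.4, 10.4], sd: [2.0, 2.8], n: 20}
  - {coastscape: shelf,  category: consumer, habit: omnivore, mean: [-19.2, 13.5], sd: [1.7, 2.1], n: 85}
  - {coastscape: strait, category: consumer, habit: omnivore, mean: [-19.0, 10.6], sd: [2.6, 2.7], n: 20}
  # predators
  - {coastscape: fjord,  category: consumer, habit: predator, mean: [-20.9, 11.1], sd: [2.5, 2.4], n: 86}
  - {coastscape: lagoon, category: consumer, habit: predator, mean: [-20.6, 12.3], sd: [2.5, 2.2], n: 32}
  - {coastscape: shelf,  category: consumer, habit: predator, mean: [-20.0, 13.8], sd: [2.6, 2.0], n: 182}
  - {coastscape: strait, category: consumer, habit: predator, mean: [-19.6, 13.2], sd: [2.6, 3.1], n: 20}
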