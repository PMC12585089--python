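genus,taxon_key
Gammarus,Arthropoda
Onisimus,Arthropoda
Saduria,Arthropoda
Pagurus,Arthropoda
Hyas,Arthropoda
Chionoecetes,Arthropoda
Balanus,Arthropoda
Alcyonidium,Bryozoa
Flustra,Bryozoa
Calanus,Calanus
Boreogadus,Chordata
Myoxocephalus,Chordata
Lumpenus,Chordata
Gersemia,Cnidaria
Urticina,Cnidaria
Ophiura,Echinodermata
Strongylocentrotus,Echinodermata
Ctenodiscus,Echinodermata
Psolus,Echinodermata
Macoma,Mollusca
Astarte,Mollusca
Mya,Mollusca
Serripes,Mollusca
Hiatella,Mollusca
Buccinum,Mollusca
Halichondria,Porifera
Haliclona,Porifera
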