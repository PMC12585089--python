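taxon_key,isotope,treatment,slope,intercept
Arthropoda,d13C,HCl+lipid_extraction,0.76,-3.9
Arthropoda,d15N,lipid_extraction,1.02,0.04
Bryozoa,d13C,HCl+lipid_extraction,0.92,-1.3
Bryozoa,d15N,HCl+lipid_extraction,0.96,0.08
Calanus,d13C,lipid_extraction,1.2,7.6
Chordata,d13C,lipid_extraction,0.74,-4.4
Chordata,d15N,lipid_extraction,0.66,5.0
Cnidaria,d13C,HCl+lipid_extraction,1.07,2.5
Echinodermata,d13C,HCl+lipid_extraction,0.82,-2.3
Echinodermata,d15N,lipid_extraction,1.21,-0.91
Mollusca,d13C,lipid_extraction,0.89,-1.7
Porifera,d13C,lipid_extraction,0.86,-2.0
Porifera,d15N,lipid_extraction,1.36,-1.79
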