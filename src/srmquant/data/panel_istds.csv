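# Isotope-labeled internal standards with their working concentration in the ISTD MIX.
abbreviation,mix_concentration_ng_per_ml
d5-Gln,30000
d10-Leu,5000
2H4-HCit,5000
13C-d2-Gly,5000
d4-Ala,5000
d5-Glu,5000
d10-Ile,5000
d5-Phe,500
d8-Trp,5000
d7-Tyr,5000
d4-Cit,500
d3-AADA,10000
d7-ADMA,5000
13C6-Kynu,30000
d4-Taurine,500
d4-DCA,500
d4-GCA,250
d4-CDCA,500
d4-GUDCA,5000
d4-CA,500
d4-UDCA,250
d4-GCDCA,5000
d6-GDCA,30000
d9-TCDCA,500
d4-TCA,500
d4-TUDCA,250
d5-Crea,10000
d4-N-MNA,250
d9-GBB,500
d4-IndS,5000
d14-AzelA,5000
d4-b-OHB,100000
d3-a-OHB,100000
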