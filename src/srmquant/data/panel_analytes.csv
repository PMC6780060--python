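# Diabetes biomarker panel: 34 plasma metabolites measured by UHPLC-MS/MS in SRM mode.
# One row per SRM transition. Co-quantified (chromatographically unresolved) isomer pairs
# share a co_quantified_group label and a single quantifier transition and ISTD.
# Voltages are acquisition metadata and play no computational role.
abbreviation,name,group,precursor_mz,product_mz,polarity,role,istd_abbreviation,co_quantified_group,fragmentor_v,collision_energy_v,cell_accelerator_v
Gln,L-Glutamine,amino_acid_related,315.3,145.1,negative,quantifier,d5-Gln,,100,9,6
Gly,Glycine,amino_acid_related,244.1,74.1,negative,quantifier,13C-d2-Gly,,200,7,4
Ala,L-Alanine,amino_acid_related,258.1,88.1,negative,quantifier,d4-Ala,,100,15,3
Leu,L-Leucine,amino_acid_related,300.2,130.2,negative,quantifier,d10-Leu,Leu and Ile,100,10,1
Ile,L-Isoleucine,amino_acid_related,300.2,130.2,negative,quantifier,d10-Leu,Leu and Ile,100,10,1
Phe,L-Phenylalanine,amino_acid_related,334.2,164.0,negative,quantifier,d5-Phe,,100,10,1
Trp,L-Tryptophan,amino_acid_related,373.2,203.1,negative,quantifier,d8-Trp,,150,7,2
Tyr,L-Tyrosine,amino_acid_related,350.2,180.1,negative,quantifier,d7-Tyr,,100,7,5
Glu,L-Glutamic Acid,amino_acid_related,316.1,146.1,negative,quantifier,d5-Glu,,100,6,6
Cit,L-Citrulline,amino_acid_related,344.4,174.2,negative,quantifier,d4-Cit,,150,4,7
HCit,L-Homocitrulline,amino_acid_related,358.3,145.0,negative,quantifier,2H4-HCit,,150,25,2
HCit,L-Homocitrulline,amino_acid_related,358.3,188.1,negative,qualifier,2H4-HCit,,200,10,1
ADMA,Asymmetric dimethylarginine,amino_acid_related,371.2,201.2,negative,quantifier,d7-ADMA,ADMA and SDMA,150,5,5
ADMA,Asymmetric dimethylarginine,amino_acid_related,371.2,156.1,negative,qualifier,d7-ADMA,ADMA and SDMA,150,20,1
SDMA,Symmetric dimethylarginine,amino_acid_related,371.2,201.2,negative,quantifier,d7-ADMA,ADMA and SDMA,150,5,5
AADA,DL-2-Aminoadipic Acid,amino_acid_related,330.2,160.1,negative,quantifier,d3-AADA,,150,10,1
Kynu,L-Kynurenine,amino_acid_related,377.0,207.0,negative,quantifier,13C6-Kynu,,150,5,5
Kynu,L-Kynurenine,amino_acid_related,377.0,316.1,negative,qualifier,13C6-Kynu,,150,5,2
Taurine,Taurine,amino_acid_related,294.1,124.1,negative,quantifier,d4-Taurine,,100,10,2
Taurine,Taurine,amino_acid_related,294.1,80.1,negative,qualifier,d4-Taurine,,100,55,2
DCA,Deoxycholic Acid,bile_acid,391.2,345.3,negative,quantifier,d4-DCA,,200,35,4
DCA,Deoxycholic Acid,bile_acid,391.2,327.2,negative,qualifier,d4-DCA,,200,40,4
GCDCA,Glycochenodeoxycholic Acid,bile_acid,448.3,74.2,negative,quantifier,d6-GDCA,GCDCA and GDCA,200,55,2
GCDCA,Glycochenodeoxycholic Acid,bile_acid,448.3,386.3,negative,qualifier,d6-GDCA,GCDCA and GDCA,150,40,2
GDCA,Glycodeoxycholic Acid,bile_acid,448.3,74.2,negative,quantifier,d6-GDCA,GCDCA and GDCA,200,55,2
GDCA,Glycodeoxycholic Acid,bile_acid,448.3,402.1,negative,qualifier,d6-GDCA,GCDCA and GDCA,250,40,2
GCA,Glycocholic Acid,bile_acid,464.3,74.1,negative,quantifier,d4-GCA,,250,45,7
GCA,Glycocholic Acid,bile_acid,464.3,402.1,negative,qualifier,d4-GCA,,250,40,4
TDCA,Taurodeoxycholic Acid,bile_acid,498.3,80.1,negative,quantifier,d9-TCDCA,TDCA and TCDCA,300,90,1
TDCA,Taurodeoxycholic Acid,bile_acid,498.3,107.1,negative,qualifier,d9-TCDCA,TDCA and TCDCA,250,80,1
TCDCA,Taurochenodeoxycholic Acid,bile_acid,498.3,80.1,negative,quantifier,d9-TCDCA,TDCA and TCDCA,300,90,1
CDCA,Deoxychenocholic Acid,bile_acid,391.3,391.3,negative,quantifier,d4-CDCA,,250,0,3
CA,Cholic Acid,bile_acid,407.3,407.3,negative,quantifier,d4-CA,,250,0,1
CA,Cholic Acid,bile_acid,407.3,343.3,negative,qualifier,d4-CA,,250,35,3
TCA,Taurocholic Acid,bile_acid,514.3,80.2,negative,quantifier,d4-TCA,,300,95,1
TCA,Taurocholic Acid,bile_acid,514.3,123.8,negative,qualifier,d4-TCA,,300,65,5
GUDCA,Glycoursodeoxycholic Acid,bile_acid,448.3,74.1,negative,quantifier,d4-GUDCA,,250,45,2
GUDCA,Glycoursodeoxycholic Acid,bile_acid,448.3,386.0,negative,qualifier,d4-GUDCA,,250,40,2
UDCA,Ursodeoxycholic Acid,bile_acid,391.3,391.3,negative,quantifier,d4-UDCA,,250,0,4
TUDCA,Tauroursodeoxycholic Acid,bile_acid,498.3,80.1,negative,quantifier,d4-TUDCA,,300,85,1
TUDCA,Tauroursodeoxycholic Acid,bile_acid,498.3,107.1,negative,qualifier,d4-TUDCA,,300,65,5
Crea,Creatinine,other,114.1,44.1,positive,quantifier,,,150,15,4
Crea,Creatinine,other,114.1,86.2,positive,qualifier,,,150,11,4
IndS,Indoxyl Sulfate,other,212.0,132.0,negative,quantifier,d4-IndS,,100,15,2
IndS,Indoxyl Sulfate,other,212.0,80.0,negative,qualifier,d4-IndS,,100,20,2
N-MNA,N-methyl-nicotinamide,other,137.1,80.2,positive,quantifier,d4-N-MNA,,100,26,2
N-MNA,N-methyl-nicotinamide,other,137.1,108.1,positive,qualifier,d4-N-MNA,,100,15,2
GBB,Gamma-butyrobetaine,other,147.2,88.1,positive,quantifier,,,100,16,1
GBB,Gamma-butyrobetaine,other,147.2,60.2,positive,qualifier,,,100,13,1
AzelA,Azelaic Acid,small_organic_acid,187.2,125.2,negative,quantifier,d14-AzelA,,150,15,1
AzelA,Azelaic Acid,small_organic_acid,187.2,169.0,negative,qualifier,d14-AzelA,,150,10,1
b-OHB,L-3-hydroxybutyric Acid,small_organic_acid,103.2,59.2,negative,quantifier,,,100,5,1
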