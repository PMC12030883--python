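alert_id,smiles,endpoint,n_tot,n_true,chemical_class,toolbox_alerts
1,NCCO,sensitization,36,33,Ethanolamines,Respiratory sensitization
2,NCCN,sensitization,28,27,Ethylenediamines,Respiratory sensitization
3,C(C(C)C)C(=O)O,sensitization,24,24,Aliphatic acids,Skin irritation
4,C(=O)C(CN),sensitization,23,23,Aldehydes,"Skin sensitization, skin irritation"
5,CCCCC(C(=O)O),sensitization,18,18,Aliphatic acids,Skin irritation
6,COC(=O)C(=C),sensitization,17,17,Acrylates,"Respiratory sensitization, skin sensitization"
7,CN=C=O,sensitization,16,16,Isocyanates,Skin sensitization
8,Cc1ccc(c(c1)O),sensitization,15,13,Phenols,Skin irritation
9,C=Nc1ccccc1,sensitization,14,14,Primary aromatic amines,N/A
10,CCNc1ccccc1,sensitization,13,12,Aromatic amines,Skin irritation
11,CNCNC,sensitization,10,8,Aminals,N/A
12,S(=O)(=O)N,sensitization,9,9,Sulfonamides,N/A
13,c1cc(C)c(c(c1))Cl,sensitization,9,8,Halogenated benzenes,N/A
14,c1ncnc(n1),sensitization,8,8,Triazines,N/A
15,NCCc1ccc(c(c1))O,sensitization,8,8,Phenols,Skin irritation
16,Nc1ccc(c(c1)C(=O)),sensitization,7,7,Aldehydes,"Skin sensitization, skin irritation"
17,C(=O)OCc1ccccc1,sensitization,7,6,Esters,N/A
18,c1ncc(c(n1)),sensitization,6,6,Pyrimidines,N/A
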