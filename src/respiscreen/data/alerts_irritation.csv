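alert_id,smiles,endpoint,n_tot,n_true,chemical_class,toolbox_alerts
1,C(=O)OC(=O),irritation,13,12,Anhydrides,Skin sensitization
2,O=C=Nc1ccc(cc1),irritation,13,12,Isocyanates,Skin sensitization
3,OCC1OC1,irritation,13,11,Epoxides,Respiratory/Skin sensitization
4,ClCC(Cl),irritation,12,12,Halogenated alkanes,Skin irritation
5,COC(=O)c1ccccc1C(=O)OC,irritation,12,8,Phthalate diesters,N/A
6,CCCCCCCCN(C)C,irritation,11,10,Tertiary aliphatic amines,Skin irritation
7,CN=C=O,irritation,9,9,Isocyanates,Skin sensitization
8,Clc1ccc(c(c1)Cl)O,irritation,9,9,Phenols,Skin irritation
9,[O-][N+](=O)C,irritation,7,7,Nitroparrafins,N/A
10,CN(C(=S)S),irritation,6,6,Thiols,Skin sensitization
11,ClC=C(C),irritation,6,6,Halogenated polarized alkenes,N/A
12,CN1CCCC1,irritation,5,5,Aliphatic amines,N/A
13,C[Si](Cl)(Cl),irritation,4,4,Chlorosilanes,N/A
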