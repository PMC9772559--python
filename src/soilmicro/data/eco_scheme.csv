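well,substrate,group
A1,Water,control
A2,beta-Methyl-D-glucoside,carbohydrates
A3,D-Galactonic acid gamma-lactone,carbohydrates
A4,L-Arginine,amino acids
A5,Water,control
A6,beta-Methyl-D-glucoside,carbohydrates
A7,D-Galactonic acid gamma-lactone,carbohydrates
A8,L-Arginine,amino acids
A9,Water,control
A10,beta-Methyl-D-glucoside,carbohydrates
A11,D-Galactonic acid gamma-lactone,carbohydrates
A12,L-Arginine,amino acids
B1,Pyruvic acid methyl ester,carbohydrates
B2,D-Xylose,carbohydrates
B3,D-Galacturonic acid,carbohydrates
B4,L-Asparagine,amino acids
B5,Pyruvic acid methyl ester,carbohydrates
B6,D-Xylose,carbohydrates
B7,D-Galacturonic acid,carbohydrates
B8,L-Asparagine,amino acids
B9,Pyruvic acid methyl ester,carbohydrates
B10,D-Xylose,carbohydrates
B11,D-Galacturonic acid,carbohydrates
B12,L-Asparagine,amino acids
C1,Tween 40,polymers
C2,i-Erythritol,carbohydrates
C3,2-Hydroxybenzoic acid,phenolic compounds
C4,L-Phenylalanine,amino acids
C5,Tween 40,polymers
C6,i-Erythritol,carbohydrates
C7,2-Hydroxybenzoic acid,phenolic compounds
C8,L-Phenylalanine,amino acids
C9,Tween 40,polymers
C10,i-Erythritol,carbohydrates
C11,2-Hydroxybenzoic acid,phenolic compounds
C12,L-Phenylalanine,amino acids
D1,Tween 80,polymers
D2,D-Mannitol,carbohydrates
D3,4-Hydroxybenzoic acid,phenolic compounds
D4,L-Serine,amino acids
D5,Tween 80,polymers
D6,D-Mannitol,carbohydrates
D7,4-Hydroxybenzoic acid,phenolic compounds
D8,L-Serine,amino acids
D9,Tween 80,polymers
D10,D-Mannitol,carbohydrates
D11,4-Hydroxybenzoic acid,phenolic compounds
D12,L-Serine,amino acids
E1,alpha-Cyclodextrin,polymers
E2,N-Acetyl-D-glucosamine,carbohydrates
E3,gamma-Hydroxybutyric acid,carboxylic acids
E4,L-Threonine,amino acids
E5,alpha-Cyclodextrin,polymers
E6,N-Acetyl-D-glucosamine,carbohydrates
E7,gamma-Hydroxybutyric acid,carboxylic acids
E8,L-Threonine,amino acids
E9,alpha-Cyclodextrin,polymers
E10,N-Acetyl-D-glucosamine,carbohydrates
E11,gamma-Hydroxybutyric acid,carboxylic acids
E12,L-Threonine,amino acids
F1,Glycogen,polymers
F2,D-Glucosaminic acid,carboxylic acids
F3,Itaconic acid,carboxylic acids
F4,Glycyl-L-glutamic acid,amino acids
F5,Glycogen,polymers
F6,D-Glucosaminic acid,carboxylic acids
F7,Itaconic acid,carboxylic acids
F8,Glycyl-L-glutamic acid,amino acids
F9,Glycogen,polymers
F10,D-Glucosaminic acid,carboxylic acids
F11,Itaconic acid,carboxylic acids
F12,Glycyl-L-glutamic acid,amino acids
G1,D-Cellobiose,carbohydrates
G2,Glucose-1-phosphate,carbohydrates
G3,alpha-Ketobutyric acid,carboxylic acids
G4,Phenylethylamine,amines
G5,D-Cellobiose,carbohydrates
G6,Glucose-1-phosphate,carbohydrates
G7,alpha-Ketobutyric acid,carboxylic acids
G8,Phenylethylamine,amines
G9,D-Cellobiose,carbohydrates
G10,Glucose-1-phosphate,carbohydrates
G11,alpha-Ketobutyric acid,carboxylic acids
G12,Phenylethylamine,amines
H1,alpha-D-Lactose,carbohydrates
H2,"D,L-alpha-Glycerol phosphate",carbohydrates
H3,D-Malic acid,carboxylic acids
H4,Putrescine,amines
H5,alpha-D-Lactose,carbohydrates
H6,"D,L-alpha-Glycerol phosphate",carbohydrates
H7,D-Malic acid,carboxylic acids
H8,Putrescine,amines
H9,alpha-D-Lactose,carbohydrates
H10,"D,L-alpha-Glycerol phosphate",carbohydrates
H11,D-Malic acid,carboxylic acids
H12,Putrescine,amines
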