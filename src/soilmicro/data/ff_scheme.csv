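well,substrate,group
A1,Water,control
A2,D-Arabinose,carbohydrates
A3,L-Arabinose,carbohydrates
A4,D-Cellobiose,carbohydrates
A5,D-Fructose,carbohydrates
A6,L-Fucose,carbohydrates
A7,D-Galactose,carbohydrates
A8,Gentiobiose,carbohydrates
A9,alpha-D-Glucose,carbohydrates
A10,alpha-D-Lactose,carbohydrates
A11,Lactulose,carbohydrates
A12,Maltose,carbohydrates
B1,Maltotriose,carbohydrates
B2,D-Mannose,carbohydrates
B3,D-Melezitose,carbohydrates
B4,D-Melibiose,carbohydrates
B5,Palatinose,carbohydrates
B6,D-Psicose,carbohydrates
B7,D-Raffinose,carbohydrates
B8,L-Rhamnose,carbohydrates
B9,D-Ribose,carbohydrates
B10,L-Sorbose,carbohydrates
B11,Stachyose,carbohydrates
B12,Sucrose,carbohydrates
C1,D-Tagatose,carbohydrates
C2,D-Trehalose,carbohydrates
C3,Turanose,carbohydrates
C4,D-Xylose,carbohydrates
C5,Sedoheptulosan,carbohydrates
C6,Glucose-1-phosphate,carbohydrates
C7,Bromosuccinic acid,carboxylic acids
C8,Fumaric acid,carboxylic acids
C9,beta-Hydroxybutyric acid,carboxylic acids
C10,gamma-Hydroxybutyric acid,carboxylic acids
C11,p-Hydroxyphenylacetic acid,carboxylic acids
C12,alpha-Ketobutyric acid,carboxylic acids
D1,alpha-Ketoglutaric acid,carboxylic acids
D2,L-Lactic acid,carboxylic acids
D3,D-Malic acid,carboxylic acids
D4,L-Malic acid,carboxylic acids
D5,Quinic acid,carboxylic acids
D6,D-Saccharic acid,carboxylic acids
D7,Sebacic acid,carboxylic acids
D8,Succinic acid,carboxylic acids
D9,Succinic acid mono-methyl ester,carboxylic acids
D10,D-Gluconic acid,carboxylic acids
D11,D-Glucuronic acid,carboxylic acids
D12,D-Galacturonic acid,carboxylic acids
E1,2-Keto-D-gluconic acid,carboxylic acids
E2,D-Lactic acid methyl ester,carboxylic acids
E3,L-Alanine,amino acids
E4,L-Alanyl-glycine,amino acids
E5,L-Asparagine,amino acids
E6,L-Aspartic acid,amino acids
E7,L-Glutamic acid,amino acids
E8,L-Ornithine,amino acids
E9,L-Phenylalanine,amino acids
E10,L-Proline,amino acids
E11,L-Serine,amino acids
E12,L-Threonine,amino acids
F1,Amygdalin,glycosides
F2,Arbutin,glycosides
F3,Salicin,glycosides
F4,beta-Methyl-D-glucoside,glycosides
F5,Tween 80,polymers
F6,Dextrin,polymers
F7,Glycogen,polymers
F8,alpha-Cyclodextrin,polymers
F9,beta-Cyclodextrin,polymers
F10,Adonitol,polyols
F11,D-Arabitol,polyols
F12,i-Erythritol,polyols
G1,Glycerol,polyols
G2,m-Inositol,polyols
G3,Maltitol,polyols
G4,D-Mannitol,polyols
G5,D-Sorbitol,polyols
G6,Xylitol,polyols
G7,D-Threitol,polyols
G8,Glucuronamide,amines and amides
G9,Succinamic acid,amines and amides
G10,L-Alaninamide,amines and amides
G11,2-Aminoethanol,amines and amides
G12,Putrescine,amines and amides
H1,N-Acetyl-D-galactosamine,amines and amides
H2,N-Acetyl-D-glucosamine,amines and amides
H3,N-Acetyl-D-mannosamine,amines and amides
H4,D-Glucosamine,amines and amides
H5,Adenosine,miscellaneous
H6,Uridine,miscellaneous
H7,Adenosine-5'-monophosphate,miscellaneous
H8,Inosine,miscellaneous
H9,gamma-Aminobutyric acid,miscellaneous
H10,Glycyl-L-glutamic acid,miscellaneous
H11,L-Pyroglutamic acid,miscellaneous
H12,"D,L-alpha-Glycerol phosphate",miscellaneous
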