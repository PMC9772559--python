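gene,category
amyA,C
apu,C
sga,C
amyX,C
xylA,C
xynA,C
abfA,C
manB,C
cex,C
cbhI,C
naglu,C
chiA,C
cda,C
lig,C
mnp,C
glx,C
cbbL,C
cbbM,C
aclB,C
accA,C
mct,C
frdA,C
korA,C
acsA,C
acsB,C
acsE,C
pccA,C
fhs,C
mcrA,C
pmoA,C
mmoX,C
mxaF,C
mtbC,C
mttB,C
mtaB,C
fae,C
amoA_AOA,N
amoA_AOB,N
hao,N
nxrA,N
narG,N
napA,N
nirK,N
nirS,N
norB,N
nosZ,N
nifH,N
nrfA,N
gdh,N
ureC,N
hzsB,N
hzo,N
nasA,N
nirB,N
nirA,N
nosZII,N
glnA,N
napB,N
phoD,P
phoX,P
phoN,P
ppx,P
ppk1,P
pqqC,P
gcd,P
phnK,P
pitA,P
dsrA,S
dsrB,S
soxB,S
aprA,S
sqr,S
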