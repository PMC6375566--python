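# Synthetic screening-library table (46 chemicals). Chemical identities,
# categories, solvents and screen doses follow the published library
# description (default 100 uM; ten-fold diluted set at 10 uM;
# chlorpyrifos-methyl 1 uM; TCDD 0.1 uM; two water-soluble polymers);
# formulas are taken from standard references.
name,category,formula,dose_uM,solvent
mercury,crude-oil,Hg,10,DMSO
TCMTB,pesticide,C9H6N2S3,10,DMSO
benzene,crude-oil,C6H6,100,DMSO
thiabendazole,pesticide,C10H7N3S,100,DMSO
permethrin,pesticide,C21H20Cl2O3,100,DMSO
DBP,phthalate,C16H22O4,100,DMSO
xylene,crude-oil,C8H10,100,DMSO
triasulfuron,pesticide,C14H16ClN5O5S,100,DMSO
pendimethalin,pesticide,C13H19N3O4,100,DMSO
piperonyl butoxide,pesticide,C19H30O5,100,DMSO
DEHP,phthalate,C24H38O4,100,DMSO
BBP,phthalate,C19H20O4,100,DMSO
DEP,phthalate,C12H14O4,100,DMSO
dicofol,pesticide,C14H9Cl5O,10,DMSO
parathion-methyl,pesticide,C8H10NO5PS,10,DMSO
isopropanol,hydraulic-fracturing,C3H8O,100,DMSO
ethylene glycol,hydraulic-fracturing,C2H6O2,100,DMSO
phosalone,pesticide,C12H15ClNO4PS2,10,DMSO
glutaraldehyde,hydraulic-fracturing,C5H8O2,100,DMSO
BPA,plasticizer,C15H16O2,100,DMSO
pyridaben,pesticide,C19H25ClN2OS,10,DMSO
mancozeb,pesticide,C8H12MnN4S8Zn,10,DMSO
arsenic oxide,pesticide,As2O3,10,DMSO
chlorpyrifos-methyl,pesticide,C7H7Cl3NO3PS,1,DMSO
TCDD,dioxin,C12H4Cl4O2,0.1,DMSO
atrazine,pesticide,C8H14ClN5,100,DMSO
malathion,pesticide,C10H19O6PS2,100,DMSO
carbaryl,pesticide,C12H11NO2,100,DMSO
diazinon,pesticide,C12H21N2O3PS,100,DMSO
acephate,pesticide,C4H10NO3PS,100,DMSO
imidacloprid,pesticide,C9H10ClN5O2,100,DMSO
chlorothalonil,pesticide,C8Cl4N2,100,DMSO
fipronil,pesticide,C12H4Cl2F6N4OS,100,DMSO
DMP,phthalate,C10H10O4,100,DMSO
DiNP,phthalate,C26H42O4,100,DMSO
toluene,crude-oil,C7H8,100,DMSO
naphthalene,crude-oil,C10H8,100,DMSO
ethylbenzene,crude-oil,C8H10,100,DMSO
hexane,crude-oil,C6H14,100,DMSO
methanol,hydraulic-fracturing,CH4O,100,DMSO
formaldehyde,hydraulic-fracturing,CH2O,100,DMSO
boric acid,hydraulic-fracturing,BH3O3,100,DMSO
citric acid,hydraulic-fracturing,C6H8O7,100,DMSO
polyacrylamide,hydraulic-fracturing,C3H5NO,100,water
hydroxyethyl cellulose,hydraulic-fracturing,C8H16O5,100,water
isobutanol,hydraulic-fracturing,C4H10O,100,DMSO
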