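# Synthetic per-replicate GFP+ fold-increase table standing in for the
# published screen readout, which is only available as a figure image.
# The values are constructed, not transcribed: they are consistent with
# every printed qualitative statement (46 chemicals; mercury ranks
# first; nineteen chemicals exceed the BPA benchmark; the hits comprise
# three crude-oil chemicals (mercury, benzene, xylene), nine pesticides,
# the four phthalates DEP/BBP/DBP/DEHP, and hydraulic-fracturing
# chemicals including isopropanol and ethylene glycol).
name,category,fold_rep1,fold_rep2,fold_rep3
mercury,crude-oil,7.38,7.51,7.61
TCMTB,pesticide,5.68,5.81,5.91
benzene,crude-oil,5.08,5.21,5.31
thiabendazole,pesticide,4.78,4.91,5.01
permethrin,pesticide,4.48,4.61,4.71
DBP,phthalate,4.18,4.31,4.41
xylene,crude-oil,3.98,4.11,4.21
triasulfuron,pesticide,3.68,3.81,3.91
pendimethalin,pesticide,3.48,3.61,3.71
piperonyl butoxide,pesticide,3.28,3.41,3.51
DEHP,phthalate,3.08,3.21,3.31
BBP,phthalate,2.88,3.01,3.11
DEP,phthalate,2.78,2.91,3.01
dicofol,pesticide,2.58,2.71,2.81
parathion-methyl,pesticide,2.48,2.61,2.71
isopropanol,hydraulic-fracturing,2.38,2.51,2.61
ethylene glycol,hydraulic-fracturing,2.28,2.41,2.51
phosalone,pesticide,2.18,2.31,2.41
glutaraldehyde,hydraulic-fracturing,1.98,2.11,2.21
BPA,plasticizer,1.88,2.01,2.11
pyridaben,pesticide,1.78,1.91,2.01
mancozeb,pesticide,1.76,1.89,1.99
arsenic oxide,pesticide,1.68,1.81,1.91
chlorpyrifos-methyl,pesticide,1.66,1.79,1.89
TCDD,dioxin,1.58,1.71,1.81
atrazine,pesticide,1.56,1.69,1.79
malathion,pesticide,1.48,1.61,1.71
carbaryl,pesticide,1.46,1.59,1.69
diazinon,pesticide,1.38,1.51,1.61
acephate,pesticide,1.36,1.49,1.59
imidacloprid,pesticide,1.28,1.41,1.51
chlorothalonil,pesticide,1.26,1.39,1.49
fipronil,pesticide,1.18,1.31,1.41
DMP,phthalate,1.16,1.29,1.39
DiNP,phthalate,1.08,1.21,1.31
toluene,crude-oil,1.06,1.19,1.29
naphthalene,crude-oil,0.98,1.11,1.21
ethylbenzene,crude-oil,0.96,1.09,1.19
hexane,crude-oil,0.88,1.01,1.11
methanol,hydraulic-fracturing,0.86,0.99,1.09
formaldehyde,hydraulic-fracturing,0.81,0.94,1.04
boric acid,hydraulic-fracturing,0.78,0.91,1.01
citric acid,hydraulic-fracturing,0.76,0.89,0.99
polyacrylamide,hydraulic-fracturing,0.71,0.84,0.94
hydroxyethyl cellulose,hydraulic-fracturing,0.68,0.81,0.91
isobutanol,hydraulic-fracturing,0.66,0.79,0.89
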