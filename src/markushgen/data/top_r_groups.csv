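table,rank,name,printed_name,smiles,percent
library,1,Methyl,Methyl,*C,19.9
library,2,Fluoro,Fluoro,*F,8.4
library,3,Methoxy,Methoxy,*OC,7.0
library,4,Hydroxy,Hydroxy,*O,6.3
library,5,Sulfamoyl,Sulfamoyl,*S(=O)(=O)N,5.6
library,6,Chloro,Chloro,*Cl,5.1
library,7,Hydrogen,Hydrogen,*H,3.8
library,8,Ethynyl,Ethynyl,*C#C,2.8
library,9,Trifluoromethyl,Trifluoromethyl,*C(F)(F)F,2.2
library,10,Carboxy,Carboxy,*C(=O)O,1.9
drugs,1,Methyl,Methyl,*C,23.6
drugs,2,Hydroxy,Hydroxy,*O,18.2
drugs,3,Chloro,Chloro,*Cl,6.4
drugs,4,Amino,Amino,*N,5.1
drugs,5,Methoxy,Methoxy,*OC,5.0
drugs,6,Carboxy,Carboxy,*C(=O)O,3.9
drugs,7,Fluoro,Fluoro,*F,2.9
drugs,8,Ethyl,Ethyl,*CC,2.2
drugs,9,Hydroxymethyl,Hydroxymethyl,*CO,1.7
drugs,10,Trifluoromethyl,Trifulromethyl,*C(F)(F)F,1.0
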