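order,superfamily,BMxBD,BMxIV,BMxIC,BMxLT,BDxIV,BDxIC,BDxLT,IVxIC,IVxLT,ICxLT
LTR,BEL,0,3,0,2,4,0,2,0,3,1
LTR,Copia,1,3,0,1,5,3,5,2,0,2
LTR,Gypsy,0,5,2,1,16,4,9,11,2,34
LINE,R1,0,0,0,0,0,0,0,0,0,2
LINE,RTE,0,0,0,0,1,0,0,0,0,0
LINE,Jockey,0,0,1,0,0,1,3,0,0,0
LINE,I2,0,0,0,0,0,1,1,0,0,1
TIR,Mariner,0,0,0,0,1,4,0,5,2,4
TIR,hAT,0,0,0,0,0,1,1,3,0,4
TIR,Transib,0,0,0,1,0,2,0,0,0,4
TIR,PiggyBAC,0,0,0,0,0,3,1,3,0,2
TIR,Harbinger,0,0,0,0,0,1,1,2,0,1
Helitron,Helitron,0,0,1,0,7,5,3,7,2,5
Maverick,Polinton,0,0,0,0,0,0,0,0,0,1
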