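classified\reference,P.rig,P.kor,L.lep,Q.mon,Q.var,Q.acu,C.cre,grass,nonforest
P.rig,19,5,0,0,0,1,0,2,0
P.kor,1,28,0,4,0,0,0,0,3
L.lep,1,9,44,3,3,5,0,0,1
Q.mon,0,4,7,40,0,4,1,0,0
Q.var,0,1,0,1,37,1,0,0,0
Q.acu,1,0,1,9,9,44,0,2,3
C.cre,0,1,0,0,0,0,18,0,0
grass,0,2,1,0,2,1,0,21,4
nonforest,0,0,0,0,0,0,1,1,63
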