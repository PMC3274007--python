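classified\reference,P.rig,P.kor,L.lep,Q.mon,Q.var,Q.acu,C.cre,grass,nonforest
P.rig,13,13,2,2,0,1,1,1,0
P.kor,3,25,3,3,0,1,1,0,0
L.lep,2,6,40,5,0,3,0,0,1
Q.mon,0,0,3,34,1,10,0,0,1
Q.var,1,1,1,2,33,5,1,4,5
Q.acu,1,1,2,8,7,27,1,2,3
C.cre,1,2,0,1,3,3,14,2,2
grass,1,1,2,1,5,4,2,16,3
nonforest,0,1,0,1,2,2,0,1,59
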