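id,abbreviation,common_name,group
1,P.rig,Pitch pine,forest
2,P.kor,Korean pine,forest
3,L.lep,Japanese larch,forest
4,Q.mon,Mongolian oak,forest
5,Q.var,Cork oak,forest
6,Q.acu,Sawtooth oak,forest
7,C.cre,Chestnut,forest
8,grass,Grass land,forest
9,nonforest,Non-forest,non-forest
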