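# Controlled vocabulary of coronary segment names (AHA-style 17-name list)
# code	full name
pRCA	proximal right coronary artery
mRCA	mid right coronary artery
dRCA	distal right coronary artery
RMA	right marginal artery
PDA	posterior descending artery
PLB	posterolateral branch
LM	left main coronary artery
pLAD	proximal left anterior descending artery
mLAD	mid left anterior descending artery
dLAD	distal left anterior descending artery
D1	first diagonal branch
D2	second diagonal branch
pCx	proximal left circumflex artery
dCx	distal left circumflex artery
OM1	first obtuse marginal branch
OM2	second obtuse marginal branch
RI	ramus intermedius
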