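label,Fd,Fp,Eh,delta_v,smarts,priority
COOH,530,420,10000,28.5,[CX3](=[OX1])[OX2H1],10
COO,390,490,7000,18.0,[CX3](=[OX1])[OX2H0],20
CO,290,770,2000,10.8,[CX3]=[OX1],30
CH3,420,0,0,33.5,[CX4H3],40
CH2,270,0,0,16.1,[CX4H2],41
CH,80,0,0,-1.0,[CX4H1],42
C,-70,0,0,-19.2,[CX4H0],43
CH2=,400,0,0,28.5,[CX3H2],50
CH=,200,0,0,13.5,"[CX3H1,cX3H1]",51
C=,70,0,0,-5.5,"[CX3H0,cX3H0]",52
OH,210,500,20000,10.0,[OX2H1],60
O,100,400,3000,3.8,"[OX2H0,oX2]",61
NH2,280,0,8400,19.2,[NX3H2],70
NH,160,210,3100,4.5,"[NX3H1,nX3H1]",71
N,20,800,5000,-9.0,"[NX3H0,nX3H0]",72
N=,20,800,5000,5.0,"[NX2,nX2]",73
S,440,0,0,12.0,"[SX2,sX2]",80
F,220,0,0,18.0,[F],90
Cl,450,550,400,24.0,[Cl],91
ring5plus,190,0,0,16.0,,100
ring34,190,0,0,18.0,,101
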