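name,role,delta_d,delta_p,delta_h,inorganic,molar_mass,printed_ra,printed_chi
Cefdinir,drug,17.29,8.2,11.2,False,395.41,,
PVP K30,polymer,18.5,8.0,12.0,False,,4.11,0.098
HPMC 606,polymer,17.4,10.2,10.9,False,,3.93,0.076
Eudragit L100,polymer,17.6,9.5,6.9,False,,5.32,0.135
SBA-15,mesoporous_carrier,15.2,3.0,8.0,True,,7.92,NA
L-arginine,coformer,16.8,14.2,17.5,False,174.20,4.77,0.260
L-phenylalanine,coformer,18.3,8.4,11.2,False,165.19,3.25,0.297
L-tryptophan,coformer,17.9,10.5,12.4,False,204.23,2.94,0.321
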