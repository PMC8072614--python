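trait,sigma_g,sigma_p,h2,r_gebv,direction,units
FY,30.67,70.13,0.29,0.80,1,kg
PY,21.33,55.45,0.22,0.79,1,kg
BCS,0.15,0.35,0.23,0.77,1,score
STAT,2.19,4.42,0.47,0.77,1,cm
AFS,10.91,56.08,0.04,0.69,-1,days
FSTC,7.45,44.68,0.03,0.74,-1,days
CK,0.03,0.21,0.02,0.61,-1,case
DA,0.03,0.15,0.04,0.59,-1,case
DMI,1.54,3.25,0.23,0.59,1,kg DM/day
RFI,0.89,2.50,0.13,0.40,-1,kg DM/day
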