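trait_a,trait_b,kind,value,se,provenance
DMI,FY,g,0.43,0.09,printed
DMI,PY,g,0.50,0.09,printed
DMI,BCS,g,0.14,0.14,printed
DMI,STAT,g,0.05,0.13,printed
DMI,AFS,g,-0.61,0.17,printed
DMI,FSTC,g,-0.13,0.23,printed
DMI,CK,g,-0.07,0.21,printed
DMI,DA,g,-0.13,0.16,printed
DMI,FY,p,0.29,0.02,printed
DMI,PY,p,0.29,0.02,printed
DMI,BCS,p,0.01,0.02,printed
DMI,STAT,p,0.25,0.04,printed
DMI,AFS,p,-0.05,0.04,printed
DMI,FSTC,p,0.04,0.04,printed
DMI,CK,p,0.23,0.14,printed
DMI,DA,p,0.15,0.17,printed
RFI,FY,g,-0.07,0.14,printed
RFI,PY,g,0.08,0.14,printed
RFI,BCS,g,0.35,0.17,printed
RFI,STAT,g,-0.16,0.15,printed
RFI,AFS,g,-0.41,0.24,printed
RFI,FSTC,g,-0.04,0.29,printed
RFI,CK,g,-0.09,0.26,printed
RFI,DA,g,-0.19,0.21,printed
RFI,FY,p,0.03,0.03,printed
RFI,PY,p,0.03,0.02,printed
RFI,BCS,p,0.03,0.02,printed
RFI,STAT,p,0.08,0.04,printed
RFI,AFS,p,-0.05,0.04,printed
RFI,FSTC,p,0.05,0.04,printed
RFI,CK,p,-0.32,0.16,printed
RFI,DA,p,-0.31,0.21,printed
DMI,RFI,g,0.68,0.07,printed
DMI,RFI,p,0.82,0.02,printed
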