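scenario,FY,PY,BCS,STAT,AFS,FSTC,CK,DA,DMI,RFI,total_cad
BASE,0.53,0.44,-0.09,0.00,-0.11,0.18,-0.16,0.05,0.26,0.04,206.44
BASE_SD,0.53,0.44,-0.08,0.00,-0.10,0.18,-0.16,0.06,0.21,0.02,204.45
DMI_C,0.46,0.33,-0.20,0.00,0.09,0.25,-0.13,0.13,0.00,-0.15,161.11
DMI_P,0.53,0.43,-0.05,0.00,-0.11,0.17,-0.18,0.05,0.27,0.06,167.16
DMI_N,0.54,0.42,-0.11,0.00,-0.04,0.21,-0.18,0.08,0.19,-0.02,174.05
DMI_C_SD,0.44,0.28,0.05,0.00,0.02,0.11,-0.29,0.04,0.00,-0.09,167.12
DMI_P_SD,0.51,0.44,-0.08,0.00,-0.14,0.18,-0.13,0.05,0.25,0.06,167.05
DMI_N_SD,0.53,0.41,-0.11,0.00,-0.05,0.19,-0.18,0.07,0.13,-0.03,183.04
RFI_C,0.53,0.41,-0.05,0.01,-0.07,0.17,-0.21,0.06,0.22,0.00,196.57
RFI_P,0.54,0.44,-0.16,0.02,-0.07,0.20,-0.13,0.08,0.21,-0.02,211.58
RFI_N,0.51,0.43,-0.02,0.00,-0.14,0.16,-0.18,0.03,0.30,0.10,194.81
RFI_C_SD,0.51,0.41,0.00,0.00,-0.10,0.15,-0.21,0.04,0.18,0.00,200.15
RFI_P_SD,0.53,0.44,-0.15,0.00,-0.08,0.19,-0.13,0.07,0.17,-0.02,211.19
RFI_N_SD,0.52,0.43,-0.05,0.01,-0.12,0.19,-0.17,0.05,0.23,0.06,196.89
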