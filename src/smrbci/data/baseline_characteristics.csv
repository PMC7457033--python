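patient_id,group,sex,age,tsi_months,baseline_fma
OME1,BCI,M,31,5,36
OME2,BCI,M,40,4,30
OME3,BCI,M,42,1,50
OME4,BCI,M,47,1,37
OME5,BCI,M,36,3,28
OME6,BCI,M,30,5,25
OME7,BCI,M,65,3,13
CG1,control,F,72,1,19
CG2,control,M,37,4,28
CG3,control,F,43,3,29
CG4,control,M,64,4.5,26
CG5,control,M,47,2,28
CG6,control,M,64,6,42
CG7,control,M,42,4,54
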