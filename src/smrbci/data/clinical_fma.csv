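patient_id,group,pre,post
OME1,BCI,36,45
OME2,BCI,30,32
OME3,BCI,50,65
OME4,BCI,37,60
OME5,BCI,28,34
OME6,BCI,25,28
OME7,BCI,13,14
CG1,control,19,34
CG2,control,28,31
CG3,control,29,36
CG4,control,26,28
CG5,control,28,30
CG6,control,42,42
CG7,control,54,58
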