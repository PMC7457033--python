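patient_id,timepoint,hemisphere,value
OME1,T1,ipsilesional,0.103
OME1,T1,contralesional,0.018
OME1,T12,ipsilesional,-0.554
OME1,T12,contralesional,-0.505
OME2,T1,ipsilesional,0.055
OME2,T1,contralesional,-0.007
OME2,T12,ipsilesional,-0.126
OME2,T12,contralesional,-0.111
OME3,T1,ipsilesional,-0.008
OME3,T1,contralesional,-0.059
OME3,T12,ipsilesional,-0.242
OME3,T12,contralesional,-0.120
OME4,T1,ipsilesional,-0.392
OME4,T1,contralesional,-0.314
OME4,T12,ipsilesional,-0.607
OME4,T12,contralesional,-0.587
OME5,T1,ipsilesional,-0.092
OME5,T1,contralesional,0.024
OME5,T12,ipsilesional,-0.155
OME5,T12,contralesional,-0.106
OME6,T1,ipsilesional,-0.182
OME6,T1,contralesional,-0.176
OME6,T12,ipsilesional,-0.245
OME6,T12,contralesional,-0.416
OME7,T1,ipsilesional,-0.002
OME7,T1,contralesional,-0.040
OME7,T12,ipsilesional,-0.110
OME7,T12,contralesional,-0.034
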