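model,family,de_sheet_vacuum,de_bind_vacuum,bsse,de_sheet_water,de_bind_water
6A12,(110)+(220),0.879,-4.681,1.228,0.454,-2.904
6A12,(010)+(020),2.435,-2.979,0.881,1.321,-2.010
6B12,(110)+(220),2.872,-3.480,0.838,1.622,-1.902
6B12,(010)+(020),3.161,-2.850,0.698,1.845,-1.653
6O12,(110)+(220),0.000,-5.624,1.401,0.000,-3.372
6O12,(010)+(020),1.477,-4.023,1.142,0.400,-3.138
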