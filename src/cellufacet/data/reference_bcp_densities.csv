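model,hb_type,f_max,oo_distance,dha_angle,rho,e_hb
6A6,O2H..O2,0.925,2.748,162.870,0.035,-7.036
6A6,O6H..O2,0.950,2.743,160.517,0.026,-4.969
6A6,O6H..O6,0.923,2.767,162.871,0.036,-7.218
6A6,O2H..O6,0.913,2.757,161.001,0.043,-8.901
6A6,O3H..O5,0.938,2.738,160.252,0.025,-4.907
6A6,O3H..O4,0.663,2.771,160.359,0.035,-7.161
6A12,O2H..O2,0.930,2.747,162.849,0.038,-7.732
6A12,O6H..O2,0.956,2.749,161.395,0.033,-6.607
6A12,O6H..O6,0.924,2.765,163.360,0.037,-7.517
6A12,O2H..O6,0.891,2.754,159.548,0.023,-4.291
6A12,O3H..O5,0.942,2.728,159.264,0.025,-4.725
6A12,O6H..O3,0.671,2.767,162.158,0.038,-7.760
6A19,O2H..O2,0.960,2.762,164.572,0.039,-8.025
6A19,O6H..O2,0.976,2.736,161.872,0.018,-3.306
6A19,O6H..O6,0.923,2.761,162.411,0.038,-7.769
6A19,O2H..O6,0.984,2.722,163.884,0.040,-8.064
6A19,O3H..O5,0.974,2.707,160.031,0.024,-4.554
6A19,O6H..O3,0.634,2.804,159.806,0.039,-8.034
10A12,O2H..O2,0.926,2.752,162.679,0.031,-6.131
10A12,O6H..O2,0.962,2.746,161.647,0.037,-7.452
10A12,O6H..O6,0.924,2.767,163.299,0.034,-6.918
10A12,O2H..O6,0.914,2.752,160.441,0.040,-8.223
10A12,O3H..O5,0.948,2.731,159.488,0.027,-5.237
6B12,O2H..O2,0.914,2.748,162.806,0.030,-6.029
6B12,O6H..O2,0.921,2.750,160.769,0.023,-4.414
6B12,O2H..O6,0.926,2.752,161.920,0.033,-6.646
6B12,O3H..O5,0.930,2.732,159.522,0.042,-8.586
6O12,O6H..O2,0.844,2.756,161.307,0.035,-7.126
6O12,O3H..O6,0.712,2.788,159.231,0.037,-7.412
6O12,O2H..O6,0.764,2.786,158.271,0.020,-3.703
6O12,O3H..O5,0.958,2.732,161.898,0.020,-3.751
6O12,O6H..O3,0.872,2.747,161.186,0.026,-5.107
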