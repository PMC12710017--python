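wavelength_nm,refractive_index,k_cab,k_cxc,k_cbrown,k_cw,k_cm
400,1.45,8.83826e-05,0.0135335,0.02,1.66479e-15,5
410,1.45,0.000218749,0.0249352,0.02,2.53283e-14,5
420,1.45,0.000508607,0.0411112,0.02,3.44824e-13,5
430,1.45,0.0011109,0.0606531,0.02,4.20082e-12,5
440,1.45,0.00227942,0.0800737,0.02,4.57947e-11,5
450,1.45,0.00439369,0.0945959,0.02,4.46726e-10,5
460,1.45,0.00795595,0.1,0.02,3.89954e-09,5
470,1.45,0.0135335,0.0945959,0.02,3.046e-08,5
480,1.45,0.0216265,0.0800737,0.02,2.12907e-07,5
490,1.45,0.0324652,0.0606531,0.02,1.33167e-06,5
500,1.45,0.0457833,0.0411112,0.02,7.45331e-06,5
510,1.45,0.0606531,0.0249352,0.02,3.73289e-05,5
520,1.45,0.075484,0.0135335,0.02,0.000167297,5
530,1.45,0.0882497,0.00657285,0.02,0.000670925,5
540,1.45,0.0969233,0.00285655,0.02,0.00240772,5
550,1.45,0.1,0.0011109,0.02,0.00773184,5
560,1.45,0.0969233,0.000386592,0.02,0.022218,5
570,1.45,0.0882497,0.000120386,0.02,0.057131,5
580,1.45,0.075484,3.35463e-05,0.02,0.131457,5
590,1.45,0.0606531,8.36483e-06,0.02,0.270671,5
600,1.45,0.0457833,1.86645e-06,0.02,0.498704,5
610,1.45,0.0324652,3.72665e-07,0.02,0.822225,5
620,1.45,0.0216265,6.65836e-08,0.02,1.21306,5
630,1.45,0.0135335,1.06454e-08,0.02,1.60147,5
640,1.45,0.00795595,1.523e-09,0.02,1.89192,5
650,1.45,0.00439369,1.94977e-10,0.02,2,5
660,1.45,0.00227942,2.23363e-11,0.02,1.89192,5
670,1.45,0.0011109,2.28973e-12,0.02,1.60147,5
680,1.45,0.000508607,2.10041e-13,0.02,1.21306,5
690,1.45,0.000218749,1.72412e-14,0.02,0.822225,5
700,1.45,8.83826e-05,1.26642e-15,0.02,0.498704,5
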