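algorithm_id,tp,tn,fn,fp,sens,sens_lo,sens_hi,spec,spec_lo,spec_hi,ppv,ppv_lo,ppv_hi,npv,npv_lo,npv_hi,kappa,youden
1,21857,809174,16077,7518,57.6,57.1,58.1,99.1,99.1,99.1,74.4,73.9,74.9,98.1,98.0,98.1,0.64,0.57
2,15123,811960,22811,4732,39.9,39.4,40.4,99.4,99.4,99.4,76.2,75.6,76.8,97.3,97.2,97.3,0.51,0.39
3,18275,810683,19659,6009,48.2,47.7,48.7,99.3,99.2,99.3,75.3,74.7,75.8,97.6,97.6,97.7,0.57,0.47
4,11805,813103,26129,3589,31.1,30.7,31.6,99.6,99.5,99.6,76.7,76.0,77.4,96.9,96.8,96.9,0.43,0.31
5,24960,808123,12974,8569,65.8,65.3,66.3,99.0,98.9,99.0,74.4,74.0,74.9,98.4,98.4,98.4,0.69,0.65
6,14949,811989,22985,4703,39.4,38.9,39.9,99.4,99.4,99.4,76.1,75.5,76.7,97.2,97.2,97.3,0.50,0.39
7,24991,807959,12943,8733,65.9,65.4,66.4,98.9,98.9,99.0,74.1,73.6,74.6,98.4,98.4,98.5,0.68,0.65
8,13083,812797,24851,3895,34.5,34.0,35.0,99.5,99.5,99.5,77.1,76.4,77.7,97.0,97.0,97.1,0.46,0.34
9,20230,809885,17704,6807,53.3,52.8,53.8,99.2,99.1,99.2,74.8,74.3,75.3,97.9,97.8,97.9,0.61,0.52
10,10157,813629,27777,3063,26.8,26.3,27.2,99.6,99.6,99.6,76.8,76.1,77.5,96.7,96.7,96.7,0.38,0.26
11,25361,807660,12573,9032,66.9,66.4,67.3,98.9,98.9,98.9,73.7,73.3,74.2,98.5,98.4,98.5,0.69,0.66
12,20950,809610,16984,7082,55.2,54.7,55.7,99.1,99.1,99.2,74.7,74.2,75.2,97.9,97.9,98.0,0.62,0.54
13,11680,813147,26254,3545,30.8,30.3,31.3,99.6,99.6,99.6,76.7,76.0,77.4,96.9,96.8,96.9,0.42,0.30
14,24226,808497,13708,8195,63.9,63.4,64.3,99.0,99.0,99.0,74.7,74.3,75.2,98.3,98.3,98.4,0.68,0.63
15,14819,812028,23115,4664,39.1,38.6,39.6,99.4,99.4,99.4,76.1,75.5,76.7,97.2,97.2,97.3,0.50,0.38
16,24259,808335,13675,8357,64.0,63.5,64.4,99.0,99.0,99.0,74.4,73.9,74.9,98.3,98.3,98.4,0.67,0.63
17,10052,813659,27882,3033,26.5,26.1,26.9,99.6,99.6,99.6,76.8,76.1,77.5,96.7,96.6,96.7,0.38,0.26
18,24662,808019,13272,8673,65.0,64.5,65.5,98.9,98.9,99.0,74.0,73.5,74.5,98.4,98.4,98.4,0.68,0.64
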