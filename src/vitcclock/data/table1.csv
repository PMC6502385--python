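condition_id,series,vitc_dilution_ml,lugol_ml,c0,m0,repeat,t_obs
a1,a,120,5,0.001632,0.0068718,1,48.12
a1,a,120,5,0.001632,0.0068718,2,43.56
a2,a,90,5,0.002175,0.0068718,1,68.72
a2,a,90,5,0.002175,0.0068718,2,74.32
a3,a,60,5,0.003263,0.0068718,1,116.86
a3,a,60,5,0.003263,0.0068718,2,122.34
a4,a,45,5,0.004351,0.0068718,1,153.03
a4,a,45,5,0.004351,0.0068718,2,168.08
a5,a,30,5,0.006526,0.0068718,1,243.67
a5,a,30,5,0.006526,0.0068718,2,210.94
b1,b,60,2.5,0.003320,0.0034962,1,426.97
b1,b,60,2.5,0.003320,0.0034962,2,495.78
b2,b,60,3.75,0.003292,0.0051987,1,285.42
b2,b,60,3.75,0.003292,0.0051987,2,246.28
b3,b,60,5,0.003263,0.0068718,1,116.86
b3,b,60,5,0.003263,0.0068718,2,122.34
b4,b,60,7.5,0.003208,0.0101330,1,55.71
b4,b,60,7.5,0.003208,0.0101330,2,43.71
b5,b,60,10,0.003154,0.0132855,1,19.51
b5,b,60,10,0.003154,0.0132855,2,22.64
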