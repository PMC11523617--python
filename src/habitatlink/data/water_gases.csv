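sample_id,garden_id,status,gas_o2_pct,gas_n2_pct,ch4_ppmv,co2_ppmv,n2o_ppmv,toc_mg_l
ALST_NC,ALST,NC,2.11,5.02,18.74,2373.8,3.67,4.37
ARK_NC,ARK,NC,2.08,4.65,0.17,770.9,0.14,1
AVIA_NC,AVIA,NC,2.16,5.12,0.25,2071.3,2.74,7.9
BIG_NC,BIG,NC,2.12,5.02,0.18,2065.25,0.5,5.77
BIL_NC,BIL,NC,1.83,4.29,198.23,4200.24,0.73,11.61
BONN_NC,BONN,NC,1.87,4.42,0.04,5512.88,0.02,6.84
COR_NC,COR,NC,1.77,5.55,0.24,2674.62,1.49,24.92
DEC_NC,DEC,NC,2.12,4.97,0.12,11662.99,1.42,7.8
EDF_NC,EDF,NC,2.01,4.35,1.01,2098.92,1.02,6.56
ESP_NC,ESP,NC,6.45,21.22,0.37,365.14,0.49,3.18
FOR_NC,FOR,NC,2.07,5.22,0.14,1904.64,1.12,12.72
FRA_NC,FRA,NC,1.58,7.44,15.9,4674.8,0.37,39.45
GAR_NC,GAR,NC,2.85,6.43,0.22,1947.26,0.64,12.58
JUST_NC,JUST,NC,2.09,4.57,11.23,2212.85,4.79,9.09
MID_NC,MID,NC,1.6,4.01,0.18,12075.54,1.6,5.5
MOU_NC,MOU,NC,2.28,5.2,0.11,33.86,0.55,3.98
PER_NC,PER,NC,2.12,4.8,0.18,1978.87,0,22.82
QUA_NC,QUA,NC,1.97,4.65,0.17,417.37,0.28,14.52
REB_NC,REB,NC,2.19,4.61,0.23,1358.77,0.01,5.12
RECU_NC,RECU,NC,2.2,5.15,1.24,3593.56,0.24,28.09
SYT_NC,SYT,NC,0.69,4.67,69.23,12225.67,2.76,16.5
TAS_NC,TAS,NC,1.95,5.56,0.36,2383.38,1.51,20.04
VOIL_NC,VOIL,NC,2.11,5.08,1.52,3248.9,0.05,17.2
ALST_C,ALST,C,3.67,10.83,0.46,8966.9,1.67,7.65
ARK_C,ARK,C,0.31,5.22,9.04,28552.01,2.22,66
AVIA_C,AVIA,C,2.15,4.7,0.04,2038.17,0.2,3.2
BIG_C,BIG,C,3,6.58,0.24,1192.21,0.22,2.51
BIL_C,BIL,C,1.97,4.7,40.54,4233.84,0.54,6.33
BONN_C,BONN,C,2.35,5.33,0.06,1735.24,0.13,31.65
COR_C,COR,C,2.1,4.41,0.01,1809.48,0.05,32.97
DEC_C,DEC,C,2.04,5.07,0.95,2967.18,0.02,3.05
EDF_C,EDF,C,1.96,4.1,0.24,4611.83,0.05,3.77
ESP_C,ESP,C,2.42,5.23,0.06,789.28,0.51,5.2
FOR_C,FOR,C,2.2,4.93,0.23,1577.37,0.26,4.25
FRA_C,FRA,C,1.91,5.08,0.14,1516.77,0.02,35.76
GAR_C,GAR,C,1.78,4.51,0.25,6583.94,0.82,29.63
JUST_C,JUST,C,1.91,4.68,0.12,3391.08,0.59,17.4
MID_C,MID,C,2.46,5.55,0.24,1694.02,0.74,3
MOU_C,MOU,C,2.24,4.96,0.02,4190.09,0.06,7.84
PER_C,PER,C,2.34,5.71,1.48,4109.99,0.7,22.06
QUA_C,QUA,C,2.12,4.76,0.3,2264.26,0.48,11.97
REB_C,REB,C,2.11,4.37,0.04,731.88,0.01,2.14
RECU_C,RECU,C,2.07,4.88,0.5,3726.21,0.48,21.39
SYT_C,SYT,C,2.11,4.81,0.18,977.73,3.01,15.12
TAS_C,TAS,C,1.95,4.4,0.21,2757.52,0.77,24.15
VOIL_C,VOIL,C,1.91,4.66,0.5,1270.64,0.01,14.1
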