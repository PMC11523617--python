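sample_id,garden_id,status,f_mg_l,cl_mg_l,no2_mg_l,br_mg_l,no3_mg_l,po4_mg_l,so4_mg_l,na_mg_l,nh4_mg_l,k_mg_l,mg_mg_l,ca_mg_l
ALST_NC,ALST,NC,0.01,0.32,0.02,0.03,0.13,0,1.28,0.85,0.57,0.61,0.24,4.87
ARK_NC,ARK,NC,0.03,0.22,0,2.6,0.01,0.07,0.46,1.2,0.02,0.58,0.15,2.92
AVIA_NC,AVIA,NC,0.03,1.58,0.04,0.36,0.66,0.81,3.82,1.78,0.47,3.41,0.92,11.85
BIG_NC,BIG,NC,0.02,0.54,0.02,0.04,0.22,0.13,0.92,1.56,0.81,0.77,0.26,3.83
BIL_NC,BIL,NC,0.07,8.56,0.07,0.04,0.54,0.51,17.19,6.76,0,4.87,4.97,44.9
BONN_NC,BONN,NC,0.04,0.38,0.01,0.01,0.02,0,0.88,0.8,0.03,0.39,0.24,5.29
COR_NC,COR,NC,0.11,31.27,0.05,0.1,2.24,0.36,33.15,20.66,0.41,5.52,6.3,62.76
DEC_NC,DEC,NC,0.04,25.65,0.02,0.02,10.33,0,18.31,15.21,0.02,3,6.21,65.03
EDF_NC,EDF,NC,0.02,0.28,0.01,0.13,0.21,0.07,0.58,0.41,0.29,0.55,0.22,4.38
ESP_NC,ESP,NC,0.02,0.18,0.03,0.01,0.13,0,0.43,0.53,0.02,0.12,0.4,9.57
FOR_NC,FOR,NC,0.02,0.82,0.02,0.1,0.48,0.63,1.32,1.75,0.09,1.49,0.38,4.55
FRA_NC,FRA,NC,0.24,42.46,0,1.86,0.02,0.64,22.82,26.91,0.4,14.85,8.46,38.82
GAR_NC,GAR,NC,0.03,0.73,0.03,0.03,1.83,1.61,2.38,1.26,0.24,6.1,1.16,10.42
JUST_NC,JUST,NC,0.09,1.23,0.05,0.4,0.79,0.3,2.82,1.55,0.93,4.38,0.62,16.65
MID_NC,MID,NC,0.05,20.3,0.08,0,6.52,0.09,26.5,13.62,0.16,5.72,11.55,71.5
MOU_NC,MOU,NC,0.01,0.22,0.01,0.04,0.03,0,0.76,0.31,0,0.27,0.12,5.61
PER_NC,PER,NC,0.04,2.04,0.05,0,0.56,0.52,2.9,1.37,0.03,3.01,0.68,18.66
QUA_NC,QUA,NC,0.18,12.09,0.03,0,0.02,0.06,33.61,8.72,0,2.93,6.59,24.46
REB_NC,REB,NC,0.07,4.21,0.05,0.01,2.78,0.52,11.18,3.28,0.02,1.94,2.08,25.12
RECU_NC,RECU,NC,0.11,11.41,0.07,0,0.1,0,16.36,9.72,0.15,2.08,7.41,38.73
SYT_NC,SYT,NC,0.1,7.33,0.02,0.01,0.02,0,8.83,5.54,1.7,4.13,4.26,29.31
TAS_NC,TAS,NC,0.06,3.15,0.08,0.21,0.33,0,9.36,3.43,0.43,1.02,2.13,23.81
VOIL_NC,VOIL,NC,0.07,11.08,0.05,0,0.45,0.87,30.65,7.8,0.04,6.04,5.06,48.95
ALST_C,ALST,C,0.08,17.52,0.01,1.35,4.12,0,34.32,13.2,0.05,3.4,7.81,64.8
ARK_C,ARK,C,0.16,16.48,0.03,0,0.05,0.93,3.26,6.19,3.09,125.24,11.18,39.99
AVIA_C,AVIA,C,0.02,0.34,0.01,0.09,0.69,0.15,1.48,1,0.26,0.58,0.23,2.99
BIG_C,BIG,C,0.02,0.48,0.01,0.02,0.57,0.15,0.87,1.44,0,0.46,0.18,3.33
BIL_C,BIL,C,0.03,0.53,0.02,0.02,0.31,0.06,1.21,0.99,0.84,0.7,0.23,3.86
BONN_C,BONN,C,0.02,1.17,0.03,0.01,0.82,0.55,2.49,0.77,0.02,2.66,0.91,9.95
COR_C,COR,C,0.06,33.53,0.07,0,3.16,0,34.2,19.89,0,2.47,5.99,45.37
DEC_C,DEC,C,0.02,0.62,0.02,0.01,0.48,0.1,0.98,1.82,0.09,0.46,0.16,4.44
EDF_C,EDF,C,0.04,18.65,0.02,0,6,0.01,27.6,13.24,0,2.4,10.28,45.43
ESP_C,ESP,C,0.02,4.16,0.02,0.04,2.04,0.19,4.61,1.96,0,1.01,0.73,14.45
FOR_C,FOR,C,0.01,0.23,0.01,0,0.4,0.09,0.79,0.86,0,0.19,0.12,2.46
FRA_C,FRA,C,0.11,3.32,0.07,0.01,0.08,0.24,3.94,1.01,0.39,21.46,3.97,26.81
GAR_C,GAR,C,0.05,29.23,0.05,0.04,3.6,0.79,28.99,5.51,0.12,8.26,4.33,72.61
JUST_C,JUST,C,0.05,4.21,0.06,0.02,12.04,3.41,12.95,6.86,0,16.66,2.37,32.71
MID_C,MID,C,0.02,0.25,0.01,0.05,0.64,0.06,1.24,0.74,0.08,0.32,0.2,5.63
MOU_C,MOU,C,0.07,62.57,0,0,3.32,0.07,65.65,29.4,0,1.82,8.23,75.23
PER_C,PER,C,0.07,0.59,0.07,0.02,0.12,0.45,0.92,1.08,0.09,2.49,0.83,19.95
QUA_C,QUA,C,0.02,0.37,0.02,0.01,0.82,1.15,0.98,0.42,0.18,5.14,0.35,2.65
REB_C,REB,C,0.02,0.41,0.01,0.01,0.7,0.24,0.63,0.68,0,0.24,0.11,1.89
RECU_C,RECU,C,0.06,13.21,0.07,0,0.45,0.13,9.26,9.8,0,3.01,8.44,34.69
SYT_C,SYT,C,0.07,19.25,0.03,0.02,1.73,0,29.7,13.3,0,6.2,4.03,37.31
TAS_C,TAS,C,0.06,10.81,0.04,0.52,0.5,0,30.44,8.8,0.91,3.31,6.36,34.97
VOIL_C,VOIL,C,0.04,1.42,0.02,0.01,0.07,0.33,1.16,2.29,0.11,0.86,0.34,5.27
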