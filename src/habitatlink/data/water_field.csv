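sample_id,garden_id,status,container_type,material,temperature_c,salinity_ppt,ph,dissolved_o2_mg_l,redox_mv
ALST_NC,ALST,NC,rainwater collector,plastic,25.17,0,8.49,3.48,49
ARK_NC,ARK,NC,rainwater collector,plastic,19.09,0,7.93,8.6,190
AVIA_NC,AVIA,NC,bucket,plastic,20.42,0,6.95,7.1,305
BIG_NC,BIG,NC,rainwater collector,plastic,20.8,0,7.28,5.45,300
BIL_NC,BIL,NC,rainwater collector,plastic,25.64,0.2,7.45,4.78,18
BONN_NC,BONN,NC,rainwater collector,plastic,22.18,0,7.27,7.46,283
COR_NC,COR,NC,rainwater collector,plastic,14.95,0.3,7.35,8.51,250
DEC_NC,DEC,NC,rainwater collector,plastic,28.09,0.3,7.29,6.74,265
EDF_NC,EDF,NC,rainwater collector,plastic,26.38,0,7.99,2.64,105
ESP_NC,ESP,NC,rainwater collector,plastic,20.13,0,8.28,6.91,188
FOR_NC,FOR,NC,watering can,plastic,21.3,0,6.15,6.6,285
FRA_NC,FRA,NC,rainwater collector,plastic,17.7,0,6.98,7.86,245
GAR_NC,GAR,NC,rainwater collector,plastic,17.7,0,7.98,9,206
JUST_NC,JUST,NC,rainwater collector,plastic,20.23,0.1,7.59,3.28,70
MID_NC,MID,NC,rainwater collector,plastic,19.2,0.4,7.04,12.25,271
MOU_NC,MOU,NC,rainwater collector,plastic,23.02,0,6.41,7.94,214
PER_NC,PER,NC,rainwater collector,plastic,21.8,0.1,7.64,3,257
QUA_NC,QUA,NC,rainwater collector,plastic,24.93,0.1,7.44,6.56,192
REB_NC,REB,NC,rainwater collector,plastic,20.72,0.1,6.38,6.14,288
RECU_NC,RECU,NC,bucket,plastic,17.01,0.2,6.58,6.42,254
SYT_NC,SYT,NC,rainwater collector,metal,24.94,0.1,7.46,3.91,-158
TAS_NC,TAS,NC,bucket,plastic,14.82,0.1,8.17,5.96,228
VOIL_NC,VOIL,NC,rainwater collector,plastic,29.12,0.2,8.05,5.83,245
ALST_C,ALST,C,rainwater collector,plastic,25.51,0.3,8.19,5.04,230
ARK_C,ARK,C,rainwater collector,plastic,22.25,0.4,6.72,3.12,-64
AVIA_C,AVIA,C,rainwater collector,plastic,20.92,0,7.95,7.17,252
BIG_C,BIG,C,rainwater collector,plastic,21.98,0,8.02,8.85,317
BIL_C,BIL,C,rainwater collector,plastic,23.4,0,8.05,3.21,86
BONN_C,BONN,C,rainwater collector,plastic,21.22,0,7.3,6.79,199
COR_C,COR,C,rainwater collector,plastic,15.97,0.3,6.7,8.64,231
DEC_C,DEC,C,rainwater collector,plastic,26.29,0.012,7.63,10.12,194
EDF_C,EDF,C,rainwater collector,plastic,23.81,0,7.8,5.02,248
ESP_C,ESP,C,rainwater collector,plastic,20.29,0,7.99,7.39,165
FOR_C,FOR,C,rainwater collector,plastic,23.71,0,7.85,5.75,296
FRA_C,FRA,C,watering can,plastic,18.13,0.1,5.7,10.07,264
GAR_C,GAR,C,rainwater collector,plastic,18.45,0.3,7.97,6.82,160
JUST_C,JUST,C,rainwater collector,plastic,20.83,0.1,7.67,6.91,260
MID_C,MID,C,rainwater collector,plastic,20.43,0,7.28,4.56,284
MOU_C,MOU,C,rainwater collector,plastic,23.68,0.3,7.79,7.02,237
PER_C,PER,C,rainwater collector,plastic,21.5,0.1,7.26,1.95,71
QUA_C,QUA,C,rainwater collector,plastic,21.86,0,7.17,5.09,254
REB_C,REB,C,rainwater collector,plastic,21.21,0,5.72,8.32,328
RECU_C,RECU,C,rainwater collector,plastic,19.91,0.2,6.12,5.03,277
SYT_C,SYT,C,rainwater collector,metal,23.24,0.2,7.63,4.11,207
TAS_C,TAS,C,bucket,plastic,16.21,0.2,7.78,7.55,256
VOIL_C,VOIL,C,rainwater collector,plastic,25.97,0,8.76,9.23,199
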