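garden_id,pollution_group,score_atmo,d_agri,d_indus,d_highway,var_indus_printed,var_agri_printed,var_atmo_printed
MID,AGRI,8,2624,1167,183,0.0009,4993,0.0437
MOU,INDUS,6,1311,1829,544,0.0005,386,0.011
PER,AGRI,5,158,3442,121,0.0003,228,0.0209
RECU,ATMO,12,1228,4598,4,0.0002,1365,0.1958
REB,ATMO,12,2624,1986,56,0.0005,191,0.2159
BIL,ATMO,12,4066,1818,26,0.0004,92,0.1534
GAR,AGRI,6,327,2209,476,0.0005,1144,0.011
ARK,INDUS,8,2640,528,500,0.0019,192,0.0152
ALST,ATMO,8,1549,3967,464,0.0003,80,0.0172
FRA,INDUS,3,1584,787,3068,0.0013,48,0.0009
TAS,INDUS,6,2044,802,1587,0.0012,923,0.0038
JUST,ATMO,12,3541,2999,24,0.0003,5,0.0587
DEC,AGRI,4,200,3422,59,0.0003,246,0.0382
FOR,ATMO,12,2759,2022,23,0.0005,182,0.2352
SYT,INDUS,11,3317,1974,204,0.0005,113,0.0538
QUA,INDUS,3,1545,590,2495,0.0017,585,0.0012
COR,AGRI,5,164,8643,1430,0.0001,193,0.0034
ESP,AGRI,9,669,1963,814,0.0005,559,0.0111
EDF,INDUS,12,7059,631,14,0.0016,2508,0.0147
BIG,AGRI,3,465,1457,620,0.0007,1099,0.0044
AVIA,AGRI,6,319,1491,298,0.0007,1659,0.0148
BONN,AGRI,6,682,1373,220,0.0007,771,0.0209
VOIL,ATMO,12,3371,2288,16,0.0004,560,0.3004
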