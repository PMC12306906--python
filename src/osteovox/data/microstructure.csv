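micro_site,micro_group,age,bvtv_mean,bvtv_sd,tbth_mean,tbth_sd,tbsp_mean,tbsp_sd
clavicle,body,0-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,body,1-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,body,5-Y,0.15,0.03,0.19,0.06,1.1,0.14
clavicle,body,10-Y,0.15,0.03,0.19,0.06,1.1,0.14
clavicle,body,15-Y,0.15,0.03,0.19,0.06,1.1,0.14
clavicle,body,adult,0.15,0.03,0.19,0.06,1.1,0.14
clavicle,ends,0-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,ends,1-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,ends,5-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,ends,10-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,ends,15-Y,0.29,0.09,0.15,0.02,1.1,0.14
clavicle,ends,adult,0.29,0.09,0.14,0.02,1.1,0.14
femur,diaphysis,0-Y,0.37,0.11,0.11,0.017,0.388,0.103
femur,diaphysis,1-Y,0.22,0.07,0.16,0.06,0.538,0.11
femur,diaphysis,5-Y,0.26,0.06,0.24,0.053,0.538,0.077
femur,distal,0-Y,0.37,0.11,0.11,0.017,0.388,0.103
femur,distal,1-Y,0.22,0.07,0.16,0.06,0.538,0.11
femur,distal,5-Y,0.26,0.06,0.24,0.053,0.538,0.077
femur,distal,10-Y,0.26,0.06,0.24,0.053,0.538,0.077
femur,neck,adult,0.11,0.04,0.14,0.02,0.78,0.1
femur,proximal,0-Y,0.37,0.16,0.11,0.017,0.388,0.103
femur,proximal,1-Y,0.22,0.07,0.16,0.06,0.538,0.11
femur,proximal,5-Y,0.35,0.06,0.24,0.053,0.538,0.077
femur,proximal,10-Y,0.35,0.06,0.24,0.053,0.538,0.077
femur,proximal,15-Y,0.35,0.06,0.24,0.053,0.538,0.077
femur,trochanter,adult,0.17,0.06,0.19,0.03,0.99,0.2
humerus,diaphysis,0-Y,0.28,0.07,0.102,0.052,0.36,0.041
humerus,diaphysis,1-Y,0.22,0.07,0.174,0.033,0.58,0.27
humerus,diaphysis,5-Y,0.22,0.07,0.208,0.028,0.58,0.188
humerus,distal,0-Y,0.28,0.07,0.102,0.052,0.36,0.041
humerus,distal,1-Y,0.22,0.07,0.174,0.033,0.58,0.27
humerus,distal,5-Y,0.22,0.07,0.208,0.028,0.58,0.188
humerus,distal,10-Y,0.22,0.07,0.208,0.028,0.58,0.188
humerus,proximal,0-Y,0.28,0.07,0.102,0.052,0.36,0.041
humerus,proximal,1-Y,0.22,0.07,0.174,0.033,0.58,0.27
humerus,proximal,5-Y,0.22,0.07,0.208,0.028,0.58,0.188
humerus,proximal,10-Y,0.22,0.07,0.208,0.028,0.58,0.188
humerus,proximal,15-Y,0.22,0.07,0.208,0.028,0.58,0.188
humerus,proximal,adult,0.06,0.02,0.1,0.018,2.37,0.6
pelvis,iliac,0-Y,0.32,0.07,0.166,0.024,0.32,0.1
pelvis,iliac,1-Y,0.23,0.03,0.123,0.024,0.481,0.112
pelvis,iliac,5-Y,0.25,0.02,0.153,0.016,0.481,0.112
pelvis,iliac,10-Y,0.25,0.02,0.155,0.016,0.459,0.07
pelvis,iliac,15-Y,0.25,0.02,0.155,0.016,0.459,0.07
pelvis,iliac,adult,0.19,0.05,0.13,0.02,0.6,0.12
pelvis,ischiopubic,0-Y,0.32,0.07,0.166,0.024,0.32,0.1
pelvis,ischiopubic,1-Y,0.23,0.03,0.123,0.024,0.481,0.112
pelvis,ischiopubic,5-Y,0.25,0.02,0.153,0.016,0.481,0.112
pelvis,ischiopubic,10-Y,0.25,0.02,0.155,0.016,0.6,0.07
pelvis,ischiopubic,15-Y,0.25,0.02,0.155,0.016,0.75,0.07
pelvis,ischiopubic_hi,adult,0.25,0.03,0.3,0.02,1.0,0.4
pelvis,ischiopubic_lo,adult,0.17,0.01,0.17,0.03,0.75,0.15
pelvis,ischiopubic_mid,adult,0.21,0.02,0.235,0.025,0.875,0.275
radius_ulna,all,0-Y,0.21,0.05,0.08,0.02,0.51,0.121
radius_ulna,all,1-Y,0.16,0.05,0.134,0.02,0.765,0.121
radius_ulna,all,5-Y,0.16,0.05,0.16,0.02,0.765,0.11
ribs,all,0-Y,0.19,0.05,0.136,0.048,0.52,0.051
ribs,all,1-Y,0.29,0.1,0.231,0.078,0.51,0.071
ribs,all,5-Y,0.2,0.06,0.231,0.078,0.51,0.071
ribs,all,10-Y,0.2,0.06,0.231,0.078,0.51,0.071
ribs,all,15-Y,0.12,0.04,0.147,0.018,0.82,0.1
ribs,all,adult,0.12,0.04,0.147,0.018,0.82,0.1
sacrum,adult,adult,0.16,0.05,0.15,0.03,0.6,0.09
scapula,all,0-Y,0.28,0.08,0.12,0.1,0.482,0.243
scapula,all,1-Y,0.22,0.08,0.192,0.1,0.964,0.221
scapula,all,5-Y,0.22,0.08,0.24,0.1,0.964,0.221
scapula,all,10-Y,0.22,0.08,0.24,0.1,0.964,0.221
scapula,all,15-Y,0.22,0.08,0.24,0.1,0.964,0.221
scapula,all,adult,0.22,0.08,0.24,0.1,0.96,0.221
skull,vault,0-Y,0.52,0.12,0.29,0.09,0.57,0.2
skull,vault,1-Y,0.52,0.12,0.29,0.09,0.57,0.2
skull,vault,5-Y,0.52,0.12,0.29,0.09,0.57,0.2
skull,vault,10-Y,0.52,0.12,0.29,0.09,0.57,0.2
skull,vault,15-Y,0.52,0.12,0.29,0.09,0.57,0.2
skull,vault,adult,0.52,0.12,0.29,0.09,0.57,0.2
sternum,all,5-Y,0.15,0.04,0.135,0.04,1.0,0.06
sternum,all,10-Y,0.15,0.04,0.15,0.05,1.0,0.06
sternum,all,15-Y,0.15,0.04,0.15,0.05,1.0,0.06
sternum,all,adult,0.15,0.04,0.15,0.05,1.0,0.06
tibfib,diaphysis,0-Y,0.35,0.07,0.075,0.007,0.49,0.11
tibfib,diaphysis,1-Y,0.2,0.04,0.089,0.008,0.735,0.084
tibfib,diaphysis,5-Y,0.25,0.04,0.126,0.017,0.735,0.084
tibfib,metaphysis,0-Y,0.35,0.07,0.075,0.007,0.49,0.11
tibfib,metaphysis,1-Y,0.2,0.04,0.089,0.008,0.735,0.084
tibfib,metaphysis,5-Y,0.25,0.04,0.126,0.017,0.735,0.084
tibfib,metaphysis,10-Y,0.25,0.04,0.212,0.028,0.735,0.084
vertebrae_c,all,0-Y,0.6,0.07,0.25,0.014,0.6,0.12
vertebrae_c,all,1-Y,0.2,0.04,0.18,0.024,0.6,0.12
vertebrae_c,all,5-Y,0.21,0.05,0.14,0.02,0.6,0.12
vertebrae_c,all,10-Y,0.21,0.05,0.14,0.02,0.65,0.154
vertebrae_c,all,15-Y,0.21,0.05,0.14,0.02,0.65,0.154
vertebrae_c,all,adult,0.21,0.05,0.14,0.02,0.6,0.09
vertebrae_l,adult,adult,0.15,0.03,0.1,0.013,0.6,0.09
vertebrae_t,adult,adult,0.155,0.04,0.125,0.02,0.6,0.09
vertebrae_tl,all,0-Y,0.45,0.15,0.096,0.04,0.6,0.12
vertebrae_tl,all,1-Y,0.14,0.04,0.096,0.04,0.6,0.12
vertebrae_tl,all,5-Y,0.14,0.04,0.096,0.04,0.6,0.12
vertebrae_tl,all,10-Y,0.14,0.04,0.118,0.02,0.65,0.154
vertebrae_tl,all,15-Y,0.14,0.04,0.118,0.02,0.65,0.154
wrist,all,0-Y,0.22,0.14,0.12,0.032,0.25,0.13
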