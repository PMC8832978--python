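{
 "name": "physchem_distance_synthetic",
 "version": "1.0",
 "alphabet": "ACDEFGHIKLMNPQRSTVWY",
 "matrix": [
  [
   0.0,
   0.661909,
   1.637669,
   1.744955,
   1.617057,
   0.320248,
   1.419341,
   1.005412,
   1.993311,
   0.935978,
   1.176183,
   1.189016,
   0.615847,
   1.413739,
   2.71296,
   0.615877,
   0.699426,
   0.676012,
   2.380715,
   1.860638
  ],
  [
   0.661909,
   0.0,
   1.436876,
   1.461296,
   1.099381,
   0.940626,
   0.800546,
   0.717211,
   1.699332,
   0.552679,
   0.582728,
   0.76333,
   0.337628,
   0.906727,
   2.318956,
   0.575831,
   0.275913,
   0.498624,
   1.780808,
   1.217776
  ],
  [
   1.637669,
   1.436876,
   0.0,
   0.284604,
   2.184751,
   1.660256,
   1.200724,
   2.00183,
   0.445405,
   1.879106,
   1.63612,
   0.864626,
   1.150376,
   0.897288,
   1.257292,
   1.077088,
   1.191611,
   1.840429,
   2.599225,
   1.994479
  ],
  [
   1.744955,
   1.461296,
   0.284604,
   0.0,
   2.071271,
   1.810831,
   1.109035,
   1.962851,
   0.450287,
   1.84728,
   1.55573,
   0.908507,
   1.210237,
   0.864159,
   1.188615,
   1.203449,
   1.244781,
   1.846716,
   2.431968,
   1.853332
  ],
  [
   1.617057,
   1.099381,
   2.184751,
   2.071271,
   0.0,
   1.935106,
   1.138361,
   0.695547,
   2.350047,
   0.690685,
   0.580138,
   1.566058,
   1.369561,
   1.511158,
   2.78533,
   1.650363,
   1.317064,
   0.972331,
   0.828372,
   0.633605
  ],
  [
   0.320248,
   0.940626,
   1.660256,
   1.810831,
   1.935106,
   0.0,
   1.645022,
   1.320322,
   2.032936,
   1.255786,
   1.476791,
   1.324693,
   0.814318,
   1.573803,
   2.776059,
   0.701499,
   0.908329,
   0.993719,
   2.691956,
   2.155457
  ],
  [
   1.419341,
   0.800546,
   1.200724,
   1.109035,
   1.138361,
   1.645022,
   0.0,
   1.225494,
   1.270485,
   1.066715,
   0.676955,
   0.555611,
   0.840503,
   0.392697,
   1.69849,
   1.01647,
   0.739551,
   1.192646,
   1.46853,
   0.830211
  ],
  [
   1.005412,
   0.717211,
   2.00183,
   1.962851,
   0.695547,
   1.320322,
   1.225494,
   0.0,
   2.277437,
   0.189595,
   0.578735,
   1.420145,
   0.972975,
   1.485593,
   2.87385,
   1.232929,
   0.977896,
   0.334852,
   1.521291,
   1.175812
  ],
  [
   1.993311,
   1.699332,
   0.445405,
   0.450287,
   2.350047,
   2.032936,
   1.270485,
   2.277437,
   0.0,
   2.139074,
   1.832863,
   1.003394,
   1.458186,
   0.943841,
   0.81269,
   1.39637,
   1.456161,
   2.141081,
   2.635198,
   2.042345
  ],
  [
   0.935978,
   0.552679,
   1.879106,
   1.84728,
   0.690685,
   1.255786,
   1.066715,
   0.189595,
   2.139074,
   0.0,
   0.45236,
   1.251993,
   0.836391,
   1.319823,
   2.72333,
   1.097992,
   0.81912,
   0.284029,
   1.490709,
   1.080212
  ],
  [
   1.176183,
   0.582728,
   1.63612,
   1.55573,
   0.580138,
   1.476791,
   0.676955,
   0.578735,
   1.832863,
   0.45236,
   0.0,
   1.013411,
   0.809328,
   0.997814,
   2.350789,
   1.090726,
   0.757942,
   0.669311,
   1.240576,
   0.722206
  ],
  [
   1.189016,
   0.76333,
   0.864626,
   0.908507,
   1.566058,
   1.324693,
   0.555611,
   1.420145,
   1.003394,
   1.251993,
   1.013411,
   0.0,
   0.61821,
   0.271538,
   1.580047,
   0.62862,
   0.532201,
   1.253271,
   2.004731,
   1.361425
  ],
  [
   0.615847,
   0.337628,
   1.150376,
   1.210237,
   1.369561,
   0.814318,
   0.840503,
   0.972975,
   1.458186,
   0.836391,
   0.809328,
   0.61821,
   0.0,
   0.81532,
   2.143846,
   0.290809,
   0.169108,
   0.732716,
   2.026491,
   1.435256
  ],
  [
   1.413739,
   0.906727,
   0.897288,
   0.864159,
   1.511158,
   1.573803,
   0.392697,
   1.485593,
   0.943841,
   1.319823,
   0.997814,
   0.271538,
   0.81532,
   0.0,
   1.428955,
   0.880991,
   0.725662,
   1.374825,
   1.852057,
   1.21418
  ],
  [
   2.71296,
   2.318956,
   1.257292,
   1.188615,
   2.78533,
   2.776059,
   1.69849,
   2.87385,
   0.81269,
   2.72333,
   2.350789,
   1.580047,
   2.143846,
   1.428955,
   0.0,
   2.10452,
   2.098932,
   2.779861,
   2.846471,
   2.324823
  ],
  [
   0.615877,
   0.575831,
   1.077088,
   1.203449,
   1.650363,
   0.701499,
   1.01647,
   1.232929,
   1.39637,
   1.097992,
   1.090726,
   0.62862,
   0.290809,
   0.880991,
   2.10452,
   0.0,
   0.352604,
   0.957559,
   2.28932,
   1.682275
  ],
  [
   0.699426,
   0.275913,
   1.191611,
   1.244781,
   1.317064,
   0.908329,
   0.739551,
   0.977896,
   1.456161,
   0.81912,
   0.757942,
   0.532201,
   0.169108,
   0.725662,
   2.098932,
   0.352604,
   0.0,
   0.751165,
   1.940654,
   1.337085
  ],
  [
   0.676012,
   0.498624,
   1.840429,
   1.846716,
   0.972331,
   0.993719,
   1.192646,
   0.334852,
   2.141081,
   0.284029,
   0.669311,
   1.253271,
   0.732716,
   1.374825,
   2.779861,
   0.957559,
   0.751165,
   0.0,
   1.774334,
   1.342214
  ],
  [
   2.380715,
   1.780808,
   2.599225,
   2.431968,
   0.828372,
   2.691956,
   1.46853,
   1.521291,
   2.635198,
   1.490709,
   1.240576,
   2.004731,
   2.026491,
   1.852057,
   2.846471,
   2.28932,
   1.940654,
   1.774334,
   0.0,
   0.644276
  ],
  [
   1.860638,
   1.217776,
   1.994479,
   1.853332,
   0.633605,
   2.155457,
   0.830211,
   1.175812,
   2.042345,
   1.080212,
   0.722206,
   1.361425,
   1.435256,
   1.21418,
   2.324823,
   1.682275,
   1.337085,
   1.342214,
   0.644276,
   0.0
  ]
 ]
}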