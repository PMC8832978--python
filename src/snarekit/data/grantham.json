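{
 "name": "grantham",
 "version": "1.0",
 "alphabet": "ACDEFGHIKLMNPQRSTVWY",
 "matrix": [
  [
   0.0,
   195.260881,
   125.914406,
   106.853266,
   112.729943,
   60.074468,
   85.606471,
   93.785939,
   105.71011,
   96.313907,
   84.550927,
   110.563626,
   26.909776,
   90.88085,
   111.411308,
   99.263216,
   58.099839,
   64.51521,
   147.921376,
   111.735357
  ],
  [
   195.260881,
   0.0,
   153.776865,
   169.660884,
   204.658,
   158.440422,
   174.071916,
   197.509895,
   201.845144,
   197.689307,
   195.812195,
   138.94945,
   168.812929,
   154.434216,
   179.771577,
   111.81975,
   149.125838,
   191.484666,
   214.645037,
   193.980151
  ],
  [
   125.914406,
   153.776865,
   0.0,
   44.663453,
   176.758966,
   93.891195,
   81.345102,
   168.302598,
   101.590682,
   171.983686,
   160.23775,
   23.035691,
   108.051956,
   61.365286,
   95.93987,
   65.557147,
   85.188321,
   152.213846,
   190.803574,
   160.148305
  ],
  [
   106.853266,
   169.660884,
   44.663453,
   0.0,
   140.396951,
   97.980931,
   40.847946,
   134.339055,
   56.942943,
   138.52549,
   126.251182,
   40.91283,
   93.85445,
   29.312307,
   54.090076,
   79.892779,
   65.587684,
   121.488494,
   152.460239,
   122.938762
  ],
  [
   112.729943,
   204.658,
   176.758966,
   140.396951,
   0.0,
   153.327435,
   100.126911,
   21.30507,
   102.276033,
   21.852698,
   28.565461,
   158.32068,
   113.877118,
   115.739353,
   97.160671,
   155.012036,
   102.994352,
   50.001036,
   39.707352,
   21.63816
  ],
  [
   60.074468,
   158.440422,
   93.891195,
   97.980931,
   153.327435,
   0.0,
   97.662012,
   135.597377,
   126.624727,
   137.873208,
   127.112266,
   79.450484,
   41.683994,
   87.281327,
   125.294192,
   55.34024,
   59.234457,
   108.930839,
   184.032564,
   147.120034
  ],
  [
   85.606471,
   174.071916,
   81.345102,
   40.847946,
   100.126911,
   97.662012,
   0.0,
   94.461925,
   32.445614,
   98.823154,
   86.457785,
   68.44499,
   76.377704,
   24.115747,
   28.857224,
   89.0528,
   46.814519,
   84.003571,
   114.712151,
   83.438324
  ],
  [
   93.785939,
   197.509895,
   168.302598,
   134.339055,
   21.30507,
   135.597377,
   94.461925,
   0.0,
   101.746322,
   4.861523,
   10.134332,
   149.110458,
   95.501854,
   108.709402,
   97.715244,
   141.984939,
   89.400633,
   29.648114,
   60.607651,
   33.091276
  ],
  [
   105.71011,
   201.845144,
   101.590682,
   56.942943,
   102.276033,
   126.624727,
   32.445614,
   101.746322,
   0.0,
   106.47573,
   94.614695,
   94.006479,
   102.849436,
   53.298529,
   26.038236,
   120.691518,
   77.843567,
   97.125303,
   109.578832,
   84.898247
  ],
  [
   96.313907,
   197.689307,
   171.983686,
   138.52549,
   21.852698,
   137.873208,
   98.823154,
   4.861523,
   106.47573,
   0.0,
   14.322027,
   152.531848,
   97.905128,
   112.589746,
   102.014635,
   144.269222,
   92.476056,
   31.826702,
   61.060906,
   35.724357
  ],
  [
   84.550927,
   195.812195,
   160.23775,
   126.251182,
   28.565461,
   127.112266,
   86.457785,
   10.134332,
   94.614695,
   14.322027,
   0.0,
   141.338775,
   86.708985,
   101.032192,
   91.759114,
   135.041719,
   81.146554,
   21.550179,
   66.72474,
   35.269141
  ],
  [
   110.563626,
   138.94945,
   23.035691,
   40.91283,
   158.32068,
   79.450484,
   68.44499,
   149.110458,
   94.006479,
   152.531848,
   141.338775,
   0.0,
   90.276281,
   45.812527,
   85.226171,
   46.300748,
   64.859701,
   133.052939,
   174.010889,
   142.416917
  ],
  [
   26.909776,
   168.812929,
   108.051956,
   93.85445,
   113.877118,
   41.683994,
   76.377704,
   95.501854,
   102.849436,
   97.905128,
   86.708985,
   90.276281,
   0.0,
   75.234955,
   102.850314,
   73.449294,
   37.613157,
   67.875984,
   146.814156,
   109.760114
  ],
  [
   90.88085,
   154.434216,
   61.365286,
   29.312307,
   115.739353,
   87.281327,
   24.115747,
   108.709402,
   53.298529,
   112.589746,
   101.032192,
   45.812527,
   75.234955,
   0.0,
   42.870388,
   68.287802,
   41.158964,
   96.452737,
   130.376099,
   98.91351
  ],
  [
   111.411308,
   179.771577,
   95.93987,
   54.090076,
   97.160671,
   125.294192,
   28.857224,
   97.715244,
   26.038236,
   102.014635,
   91.759114,
   85.226171,
   102.850314,
   42.870388,
   0.0,
   109.357165,
   71.064611,
   95.923397,
   101.424045,
   77.20932
  ],
  [
   99.263216,
   111.81975,
   65.557147,
   79.892779,
   155.012036,
   55.34024,
   89.0528,
   141.984939,
   120.691518,
   144.269222,
   135.041719,
   46.300748,
   73.449294,
   68.287802,
   109.357165,
   0.0,
   57.825177,
   123.196194,
   176.810402,
   143.29609
  ],
  [
   58.099839,
   149.125838,
   85.188321,
   65.587684,
   102.994352,
   59.234457,
   46.814519,
   89.400633,
   77.843567,
   92.476056,
   81.146554,
   64.859701,
   37.613157,
   41.158964,
   71.064611,
   57.825177,
   0.0,
   69.587857,
   128.48508,
   92.369282
  ],
  [
   64.51521,
   191.484666,
   152.213846,
   121.488494,
   50.001036,
   108.930839,
   84.003571,
   29.648114,
   97.125303,
   31.826702,
   21.550179,
   133.052939,
   67.875984,
   96.452737,
   95.923397,
   123.196194,
   69.587857,
   0.0,
   88.079556,
   54.734862
  ],
  [
   147.921376,
   214.645037,
   190.803574,
   152.460239,
   39.707352,
   184.032564,
   114.712151,
   60.607651,
   109.578832,
   61.060906,
   66.72474,
   174.010889,
   146.814156,
   130.376099,
   101.424045,
   176.810402,
   128.48508,
   88.079556,
   0.0,
   37.162709
  ],
  [
   111.735357,
   193.980151,
   160.148305,
   122.938762,
   21.63816,
   147.120034,
   83.438324,
   33.091276,
   84.898247,
   35.724357,
   35.269141,
   142.416917,
   109.760114,
   98.91351,
   77.20932,
   143.29609,
   92.369282,
   54.734862,
   37.162709,
   0.0
  ]
 ]
}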