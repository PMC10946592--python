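{
 "schema_version": 1,
 "templates": {
  "L": {
   "name": "L",
   "order": 8,
   "a0": -42.926358,
   "a": [
    -2.03968,
    57.330821,
    8.111103,
    -21.448345,
    -3.38962,
    3.250756,
    0.3966,
    -0.079354
   ],
   "b": [
    75.971783,
    6.573391,
    -38.765649,
    -5.939747,
    9.5883,
    1.441277,
    -0.711392,
    -0.07298
   ],
   "post_scale_kind": "additive_s",
   "post_scale": -0.001655,
   "domain_axis": "log10_nm",
   "lambda_lo": 360,
   "lambda_hi": 850,
   "out_of_range": "error",
   "output_units": "log_absorbance"
  },
  "M": {
   "name": "M",
   "order": 8,
   "a0": -210.656885,
   "a": [
    -0.145807,
    305.471058,
    6.838622,
    -118.48902,
    -3.797355,
    19.972851,
    0.691341,
    -0.707069
   ],
   "b": [
    386.731976,
    5.021838,
    -208.206234,
    -5.762587,
    55.180346,
    1.899046,
    -5.089181,
    -0.141993
   ],
   "post_scale_kind": "additive_s",
   "post_scale": 0.000589,
   "domain_axis": "log10_nm",
   "lambda_lo": 360,
   "lambda_hi": 850,
   "out_of_range": "error",
   "output_units": "log_absorbance"
  },
  "S": {
   "name": "S",
   "order": 8,
   "a0": 207.388095,
   "a": [
    -6.306562,
    -315.66506,
    19.641474,
    121.858468,
    -8.677406,
    -20.631872,
    1.048302,
    0.789878
   ],
   "b": [
    -393.710048,
    19.291754,
    214.221157,
    -15.182074,
    -56.759638,
    3.693488,
    5.365662,
    -0.148036
   ],
   "post_scale_kind": "additive_s",
   "post_scale": 0.000236,
   "domain_axis": "log10_nm",
   "lambda_lo": 360,
   "lambda_hi": 850,
   "out_of_range": "error",
   "output_units": "log_absorbance"
  },
  "L_ser180_poly": {
   "name": "L_ser180_poly",
   "order": 8,
   "a0": -42.417609,
   "a": [
    -2.656792,
    56.477063,
    9.061442,
    -20.97461,
    -3.785039,
    3.134495,
    0.439302,
    -0.072988
   ],
   "b": [
    75.011094,
    7.509398,
    -38.068488,
    -6.642746,
    9.322071,
    1.603799,
    -0.676959,
    -0.078858
   ],
   "post_scale_kind": "additive_s",
   "post_scale": -0.004264,
   "domain_axis": "log10_nm",
   "lambda_lo": 360,
   "lambda_hi": 850,
   "out_of_range": "error",
   "output_units": "log_absorbance"
  },
  "L_common": {
   "name": "L_common",
   "order": 8,
   "a0": -2.125656,
   "a": [
    5.467793,
    -0.953011,
    -3.003999,
    -1.367085,
    0.516505,
    0.610042,
    0.100928,
    -0.02788
   ],
   "b": [
    0.896066,
    -5.03771,
    -0.950862,
    1.770211,
    1.15055,
    0.051821,
    -0.177357,
    -0.042774
   ],
   "post_scale_kind": "additive_s",
   "post_scale": 0.000705,
   "domain_axis": "log10_nm",
   "lambda_lo": 360,
   "lambda_hi": 850,
   "out_of_range": "error",
   "output_units": "log_absorbance"
  },
  "macular": {
   "name": "macular",
   "order": 11,
   "a0": 3712.203779,
   "a": [
    374.181158,
    -5887.285752,
    -716.042904,
    2882.109266,
    468.49807,
    -817.12409,
    -144.799646,
    115.56528,
    18.66782,
    -5.468375,
    -0.504396
   ],
   "b": [
    -7007.698964,
    -633.047523,
    4386.881125,
    638.134755,
    -1653.756739,
    -286.403898,
    340.336483,
    59.165083,
    -30.234454,
    -4.133506,
    0.509417
   ],
   "post_scale_kind": "multiplicative_d",
   "post_scale": 1.005005,
   "domain_axis": "linear_nm",
   "lambda_lo": 375,
   "lambda_hi": 550,
   "out_of_range": "zero",
   "output_units": "density"
  },
  "lens": {
   "name": "lens",
   "order": 9,
   "a0": -313.950863,
   "a": [
    -70.321682,
    471.539586,
    127.016822,
    -188.163808,
    -68.307849,
    33.449826,
    13.652409,
    -1.282577,
    -0.447784
   ],
   "b": [
    585.471973,
    117.35391,
    -324.470054,
    -104.551249,
    89.781537,
    35.272364,
    -8.756817,
    -3.512653,
    0.042829
   ],
   "post_scale_kind": "multiplicative_d",
   "post_scale": 1.009187,
   "domain_axis": "linear_nm",
   "lambda_lo": 360,
   "lambda_hi": 660,
   "out_of_range": "zero",
   "output_units": "density"
  }
 },
 "matrices": {
  "rgb10_to_lms10": {
   "from_space": "RGB10",
   "to_space": "LMS10",
   "m": [
    [
     2.846201,
     11.092401,
     1.0
    ],
    [
     0.168926,
     8.265895,
     1.0
    ],
    [
     0.0,
     0.0106,
     1.0
    ]
   ]
  },
  "lms2_to_xyz": {
   "from_space": "LMS2",
   "to_space": "XYZ2",
   "m": [
    [
     1.94735469,
     -1.41445123,
     0.36476327
    ],
    [
     0.68990272,
     0.34832189,
     0.0
    ],
    [
     0.0,
     0.0,
     1.93485343
    ]
   ]
  },
  "lms10_to_xyz": {
   "from_space": "LMS10",
   "to_space": "XYZ10",
   "m": [
    [
     1.93986443,
     -1.34664359,
     0.43044935
    ],
    [
     0.69283932,
     0.34967567,
     0.0
    ],
    [
     0.0,
     0.0,
     2.14687945
    ]
   ]
  }
 }
}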