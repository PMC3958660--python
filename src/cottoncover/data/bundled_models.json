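{
 "description": "Exponential canopy-cover calibration parameters y = k*exp(b*CC) for cotton, pooled and grouped by cultivar and N fertilizer rate.",
 "applicability": "emergence to full bloom; canopy cover in [0, 1]",
 "units": {
  "total_N": "g m-2",
  "LAI": "m2 m-2",
  "biomass": "g m-2"
 },
 "sha256": "254ac31ac212d4c584836dc55c02f3a25b8bd01a573d336b7874b855f9d496f0",
 "entries": [
  {
   "property": "total_N",
   "grouping": "pooled",
   "k": 0.619,
   "b": 4.262,
   "calibration_rmse": 1.479,
   "calibration_r_squared": 0.978
  },
  {
   "property": "LAI",
   "grouping": "pooled",
   "k": 0.448,
   "b": 2.631,
   "calibration_rmse": 0.287,
   "calibration_r_squared": 0.935
  },
  {
   "property": "biomass",
   "grouping": "pooled",
   "k": 36.297,
   "b": 4.172,
   "calibration_rmse": 134.412,
   "calibration_r_squared": 0.901
  },
  {
   "property": "total_N",
   "grouping": "cultivar:XLZ43",
   "k": 0.712,
   "b": 4.285,
   "calibration_rmse": 1.483,
   "calibration_r_squared": 0.966
  },
  {
   "property": "LAI",
   "grouping": "cultivar:XLZ43",
   "k": 0.452,
   "b": 2.622,
   "calibration_rmse": 0.483,
   "calibration_r_squared": 0.946
  },
  {
   "property": "biomass",
   "grouping": "cultivar:XLZ43",
   "k": 37.175,
   "b": 4.206,
   "calibration_rmse": 110.714,
   "calibration_r_squared": 0.892
  },
  {
   "property": "total_N",
   "grouping": "cultivar:XLZ48",
   "k": 0.769,
   "b": 4.251,
   "calibration_rmse": 1.437,
   "calibration_r_squared": 0.969
  },
  {
   "property": "LAI",
   "grouping": "cultivar:XLZ48",
   "k": 0.438,
   "b": 2.65,
   "calibration_rmse": 0.496,
   "calibration_r_squared": 0.924
  },
  {
   "property": "biomass",
   "grouping": "cultivar:XLZ48",
   "k": 33.731,
   "b": 4.208,
   "calibration_rmse": 146.344,
   "calibration_r_squared": 0.879
  },
  {
   "property": "total_N",
   "grouping": "nrate:N0",
   "k": 0.497,
   "b": 4.238,
   "calibration_rmse": 1.793,
   "calibration_r_squared": 0.949
  },
  {
   "property": "total_N",
   "grouping": "nrate:N1",
   "k": 0.549,
   "b": 4.241,
   "calibration_rmse": 1.459,
   "calibration_r_squared": 0.965
  },
  {
   "property": "total_N",
   "grouping": "nrate:N2",
   "k": 0.632,
   "b": 4.248,
   "calibration_rmse": 1.328,
   "calibration_r_squared": 0.975
  },
  {
   "property": "total_N",
   "grouping": "nrate:N3",
   "k": 0.752,
   "b": 4.256,
   "calibration_rmse": 1.287,
   "calibration_r_squared": 0.978
  },
  {
   "property": "total_N",
   "grouping": "nrate:N4",
   "k": 0.801,
   "b": 4.265,
   "calibration_rmse": 1.384,
   "calibration_r_squared": 0.957
  },
  {
   "property": "LAI",
   "grouping": "nrate:N0",
   "k": 0.368,
   "b": 2.596,
   "calibration_rmse": 0.565,
   "calibration_r_squared": 0.864
  },
  {
   "property": "LAI",
   "grouping": "nrate:N1",
   "k": 0.384,
   "b": 2.896,
   "calibration_rmse": 0.508,
   "calibration_r_squared": 0.91
  },
  {
   "property": "LAI",
   "grouping": "nrate:N2",
   "k": 0.46,
   "b": 2.907,
   "calibration_rmse": 0.194,
   "calibration_r_squared": 0.9618
  },
  {
   "property": "LAI",
   "grouping": "nrate:N3",
   "k": 0.465,
   "b": 2.959,
   "calibration_rmse": 0.265,
   "calibration_r_squared": 0.966
  },
  {
   "property": "LAI",
   "grouping": "nrate:N4",
   "k": 0.481,
   "b": 2.988,
   "calibration_rmse": 0.496,
   "calibration_r_squared": 0.939
  },
  {
   "property": "biomass",
   "grouping": "nrate:N0",
   "k": 20.043,
   "b": 3.465,
   "calibration_rmse": 348.664,
   "calibration_r_squared": 0.758
  },
  {
   "property": "biomass",
   "grouping": "nrate:N1",
   "k": 23.769,
   "b": 4.378,
   "calibration_rmse": 225.427,
   "calibration_r_squared": 0.885
  },
  {
   "property": "biomass",
   "grouping": "nrate:N2",
   "k": 27.519,
   "b": 4.632,
   "calibration_rmse": 139.005,
   "calibration_r_squared": 0.864
  },
  {
   "property": "biomass",
   "grouping": "nrate:N3",
   "k": 28.283,
   "b": 4.674,
   "calibration_rmse": 124.954,
   "calibration_r_squared": 0.948
  },
  {
   "property": "biomass",
   "grouping": "nrate:N4",
   "k": 28.736,
   "b": 4.697,
   "calibration_rmse": 192.813,
   "calibration_r_squared": 0.938
  }
 ]
}
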