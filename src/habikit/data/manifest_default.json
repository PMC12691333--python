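{
 "name": "default",
 "version": 1,
 "total_per_region": 1218,
 "filters": [
  "original",
  "log.sigma.1.0.mm.3D",
  "log.sigma.2.0.mm.3D",
  "log.sigma.3.0.mm.3D",
  "log.sigma.4.0.mm.3D",
  "log.sigma.5.0.mm.3D",
  "wavelet.LLL",
  "wavelet.LLH",
  "wavelet.LHL",
  "wavelet.LHH",
  "wavelet.HLL",
  "wavelet.HLH",
  "wavelet.HHL",
  "wavelet.HHH"
 ],
 "families": {
  "firstorder": [
   "Energy",
   "TotalEnergy",
   "Entropy",
   "Minimum",
   "10Percentile",
   "90Percentile",
   "Maximum",
   "Mean",
   "Median",
   "InterquartileRange",
   "Range",
   "MeanAbsoluteDeviation",
   "RobustMeanAbsoluteDeviation",
   "RootMeanSquared",
   "Skewness",
   "Kurtosis",
   "Variance",
   "Uniformity"
  ],
  "glcm": [
   "Autocorrelation",
   "JointAverage",
   "ClusterProminence",
   "ClusterShade",
   "ClusterTendency",
   "Contrast",
   "Correlation",
   "DifferenceAverage",
   "DifferenceEntropy",
   "DifferenceVariance",
   "Id",
   "Idm",
   "Idmn",
   "Idn",
   "InverseVariance",
   "JointEnergy",
   "JointEntropy",
   "MaximumProbability",
   "SumAverage",
   "SumEntropy",
   "SumSquares"
  ],
  "glrlm": [
   "ShortRunEmphasis",
   "LongRunEmphasis",
   "GrayLevelNonUniformity",
   "GrayLevelNonUniformityNormalized",
   "RunLengthNonUniformity",
   "RunLengthNonUniformityNormalized",
   "RunPercentage",
   "GrayLevelVariance",
   "RunVariance",
   "RunEntropy",
   "LowGrayLevelRunEmphasis",
   "HighGrayLevelRunEmphasis",
   "ShortRunLowGrayLevelEmphasis",
   "ShortRunHighGrayLevelEmphasis",
   "LongRunLowGrayLevelEmphasis",
   "LongRunHighGrayLevelEmphasis"
  ],
  "glszm": [
   "SmallAreaEmphasis",
   "LargeAreaEmphasis",
   "GrayLevelNonUniformity",
   "GrayLevelNonUniformityNormalized",
   "SizeZoneNonUniformity",
   "SizeZoneNonUniformityNormalized",
   "ZonePercentage",
   "GrayLevelVariance",
   "ZoneVariance",
   "ZoneEntropy",
   "LowGrayLevelZoneEmphasis",
   "HighGrayLevelZoneEmphasis",
   "SmallAreaLowGrayLevelEmphasis",
   "SmallAreaHighGrayLevelEmphasis",
   "LargeAreaLowGrayLevelEmphasis",
   "LargeAreaHighGrayLevelEmphasis"
  ],
  "gldm": [
   "SmallDependenceEmphasis",
   "LargeDependenceEmphasis",
   "GrayLevelNonUniformity",
   "DependenceNonUniformity",
   "GrayLevelVariance",
   "DependenceEntropy",
   "SmallDependenceLowGrayLevelEmphasis",
   "SmallDependenceHighGrayLevelEmphasis",
   "LargeDependenceLowGrayLevelEmphasis",
   "LargeDependenceHighGrayLevelEmphasis"
  ],
  "ngtdm": [
   "Coarseness",
   "Contrast",
   "Busyness",
   "Complexity",
   "Strength"
  ]
 },
 "shape": [
  "VoxelVolume",
  "MeshVolume",
  "SurfaceArea",
  "SurfaceVolumeRatio",
  "Sphericity",
  "Maximum3DDiameter",
  "Maximum2DDiameterSlice",
  "Maximum2DDiameterColumn",
  "Maximum2DDiameterRow",
  "MajorAxisLength",
  "MinorAxisLength",
  "LeastAxisLength",
  "Elongation",
  "Flatness"
 ],
 "discretization": {
  "original": {
   "rule": "width",
   "bin_width": 25.0
  },
  "filtered": {
   "rule": "count",
   "n_bins": 32
  }
 },
 "wavelet": "coif1",
 "aggregation": "average_over_directions"
}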