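{
 "name": "small",
 "version": 1,
 "filters": [
  "original"
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
 "aggregation": "average_over_directions",
 "total_per_region": 69
}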