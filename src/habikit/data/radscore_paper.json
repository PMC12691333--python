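{
 "paper_voi": {
  "description": "Published whole-tumor (VOI) radiomics score: LASSO-logistic linear combination of six whole-tumor features.",
  "intercept": -1314.76350183194,
  "coefficients": {
   "original_firstorder_InterquartileRange": -0.049373886121726,
   "log.sigma.2.0.mm.3D_glrlm_ShortRunLowGrayLevelEmphasis": -3.3462260807435,
   "log.sigma.5.0.mm.3D_glszm_SizeZoneNonUniformityNormalized": -2.45489742195494,
   "log.sigma.4.0.mm.3D_glcm_Idn": 37.5565903019046,
   "wavelet.LHH_glrlm_GrayLevelVariance": 5112.07298466082,
   "wavelet.HLH_glszm_SmallAreaHighGrayLevelEmphasis": 0.415506640475669
  }
 },
 "paper_sub": {
  "description": "Published subregional (habitat) radiomics score: linear combination of seven Sub{j}-prefixed features (interpreted as additive terms).",
  "intercept": 49.263094558148,
  "coefficients": {
   "Sub1_wavelet.LLH_glszm_SmallAreaHighGrayLevelEmphasis": 0.49585946384375,
   "Sub1_log.sigma.5.0.mm.3D_glcm_Correlation": -3.11826715000125,
   "Sub3_log.sigma.1.0.mm.3D_firstorder_Kurtosis": 0.0477379368324887,
   "Sub2_wavelet.LHH_glrlm_GrayLevelNonUniformityNormalized": -99.5853551879633,
   "Sub3_wavelet.LLL_gldm_LargeDependenceLowGrayLevelEmphasis": 0.00297377200986883,
   "Sub3_wavelet.LHH_glszm_LargeAreaLowGrayLevelEmphasis": 1.21232489590441e-08,
   "Sub3_log.sigma.5.0.mm.3D_glcm_ClusterProminence": -1.23756693776612
  }
 }
}
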