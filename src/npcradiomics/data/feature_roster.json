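[
 "HIST.mean",
 "HIST.median",
 "HIST.min",
 "HIST.max",
 "HIST.range",
 "HIST.variance",
 "HIST.skewness",
 "HIST.kurtosis",
 "HIST.energy",
 "HIST.entropy",
 "GLCM.angular_second_moment",
 "GLCM.contrast",
 "GLCM.correlation",
 "GLCM.sum_of_squares_variance",
 "GLCM.inverse_difference_moment",
 "GLCM.sum_average",
 "GLCM.sum_variance",
 "GLCM.sum_entropy",
 "GLCM.entropy",
 "GLCM.difference_variance",
 "GLCM.difference_entropy",
 "GLCM.information_Measure_I",
 "GLCM.information_Measure_II",
 "GLCM.maximal_correlation_coefficient",
 "GLCM.autocorrelation",
 "GLCM.cluster_shade",
 "GLCM.cluster_prominence",
 "GLCM.dissimilarity",
 "GLCM.homogeneity2",
 "GLCM.maximum_probability",
 "GLCM.inverse_difference_normalized",
 "GLCM.inverse_difference_moment_normalized",
 "GLRLM.SRE",
 "GLRLM.LRE",
 "GLRLM.GLN",
 "GLRLM.RLN",
 "GLRLM.RP",
 "GLRLM.LGRE",
 "GLRLM.HGRE",
 "GLRLM.SRLGE",
 "GLRLM.SRHGE",
 "LL_HIST.mean",
 "LL_HIST.median",
 "LL_HIST.min",
 "LL_HIST.max",
 "LL_HIST.range",
 "LL_HIST.variance",
 "LL_HIST.skewness",
 "LL_HIST.kurtosis",
 "LL_HIST.energy",
 "LL_HIST.entropy",
 "LL_GLCM.angular_second_moment",
 "LL_GLCM.contrast",
 "LL_GLCM.correlation",
 "LL_GLCM.sum_of_squares_variance",
 "LL_GLCM.inverse_difference_moment",
 "LL_GLCM.sum_average",
 "LL_GLCM.sum_variance",
 "LL_GLCM.sum_entropy",
 "LL_GLCM.entropy",
 "LL_GLCM.difference_variance",
 "LL_GLCM.difference_entropy",
 "LL_GLCM.information_Measure_I",
 "LL_GLCM.information_Measure_II",
 "LL_GLCM.maximal_correlation_coefficient",
 "LL_GLCM.autocorrelation",
 "LL_GLCM.cluster_shade",
 "LL_GLCM.cluster_prominence",
 "LL_GLCM.dissimilarity",
 "LL_GLCM.homogeneity2",
 "LL_GLCM.maximum_probability",
 "LL_GLCM.inverse_difference_normalized",
 "LL_GLCM.inverse_difference_moment_normalized",
 "LL_GLRLM.SRE",
 "LL_GLRLM.LRE",
 "LL_GLRLM.GLN",
 "LL_GLRLM.RLN",
 "LL_GLRLM.RP",
 "LL_GLRLM.LGRE",
 "LL_GLRLM.HGRE",
 "LL_GLRLM.SRLGE",
 "LL_GLRLM.SRHGE",
 "LH_HIST.mean",
 "LH_HIST.median",
 "LH_HIST.min",
 "LH_HIST.max",
 "LH_HIST.range",
 "LH_HIST.variance",
 "LH_HIST.skewness",
 "LH_HIST.kurtosis",
 "LH_HIST.energy",
 "LH_HIST.entropy",
 "LH_GLCM.angular_second_moment",
 "LH_GLCM.contrast",
 "LH_GLCM.correlation",
 "LH_GLCM.sum_of_squares_variance",
 "LH_GLCM.inverse_difference_moment",
 "LH_GLCM.sum_average",
 "LH_GLCM.sum_variance",
 "LH_GLCM.sum_entropy",
 "LH_GLCM.entropy",
 "LH_GLCM.difference_variance",
 "LH_GLCM.difference_entropy",
 "LH_GLCM.information_Measure_I",
 "LH_GLCM.information_Measure_II",
 "LH_GLCM.maximal_correlation_coefficient",
 "LH_GLCM.autocorrelation",
 "LH_GLCM.cluster_shade",
 "LH_GLCM.cluster_prominence",
 "LH_GLCM.dissimilarity",
 "LH_GLCM.homogeneity2",
 "LH_GLCM.maximum_probability",
 "LH_GLCM.inverse_difference_normalized",
 "LH_GLCM.inverse_difference_moment_normalized",
 "LH_GLRLM.SRE",
 "LH_GLRLM.LRE",
 "LH_GLRLM.GLN",
 "LH_GLRLM.RLN",
 "LH_GLRLM.RP",
 "LH_GLRLM.LGRE",
 "LH_GLRLM.HGRE",
 "LH_GLRLM.SRLGE",
 "LH_GLRLM.SRHGE",
 "HL_HIST.mean",
 "HL_HIST.median",
 "HL_HIST.min",
 "HL_HIST.max",
 "HL_HIST.range",
 "HL_HIST.variance",
 "HL_HIST.skewness",
 "HL_HIST.kurtosis",
 "HL_HIST.energy",
 "HL_HIST.entropy",
 "HL_GLCM.angular_second_moment",
 "HL_GLCM.contrast",
 "HL_GLCM.correlation",
 "HL_GLCM.sum_of_squares_variance",
 "HL_GLCM.inverse_difference_moment",
 "HL_GLCM.sum_average",
 "HL_GLCM.sum_variance",
 "HL_GLCM.sum_entropy",
 "HL_GLCM.entropy",
 "HL_GLCM.difference_variance",
 "HL_GLCM.difference_entropy",
 "HL_GLCM.information_Measure_I",
 "HL_GLCM.information_Measure_II",
 "HL_GLCM.maximal_correlation_coefficient",
 "HL_GLCM.autocorrelation",
 "HL_GLCM.cluster_shade",
 "HL_GLCM.cluster_prominence",
 "HL_GLCM.dissimilarity",
 "HL_GLCM.homogeneity2",
 "HL_GLCM.maximum_probability",
 "HL_GLCM.inverse_difference_normalized",
 "HL_GLCM.inverse_difference_moment_normalized",
 "HL_GLRLM.SRE",
 "HL_GLRLM.LRE",
 "HL_GLRLM.GLN",
 "HL_GLRLM.RLN",
 "HL_GLRLM.RP",
 "HL_GLRLM.LGRE",
 "HL_GLRLM.HGRE",
 "HL_GLRLM.SRLGE",
 "HL_GLRLM.SRHGE",
 "HH_HIST.mean",
 "HH_HIST.median",
 "HH_HIST.min",
 "HH_HIST.max",
 "HH_HIST.range",
 "HH_HIST.variance",
 "HH_HIST.skewness",
 "HH_HIST.kurtosis",
 "HH_HIST.energy",
 "HH_HIST.entropy",
 "HH_GLCM.angular_second_moment",
 "HH_GLCM.contrast",
 "HH_GLCM.correlation",
 "HH_GLCM.sum_of_squares_variance",
 "HH_GLCM.inverse_difference_moment",
 "HH_GLCM.sum_average",
 "HH_GLCM.sum_variance",
 "HH_GLCM.sum_entropy",
 "HH_GLCM.entropy",
 "HH_GLCM.difference_variance",
 "HH_GLCM.difference_entropy",
 "HH_GLCM.information_Measure_I",
 "HH_GLCM.information_Measure_II",
 "HH_GLCM.maximal_correlation_coefficient",
 "HH_GLCM.autocorrelation",
 "HH_GLCM.cluster_shade",
 "HH_GLCM.cluster_prominence",
 "HH_GLCM.dissimilarity",
 "HH_GLCM.homogeneity2",
 "HH_GLCM.maximum_probability",
 "HH_GLCM.inverse_difference_normalized",
 "HH_GLCM.inverse_difference_moment_normalized",
 "HH_GLRLM.SRE",
 "HH_GLRLM.LRE",
 "HH_GLRLM.GLN",
 "HH_GLRLM.RLN",
 "HH_GLRLM.RP",
 "HH_GLRLM.LGRE",
 "HH_GLRLM.HGRE",
 "HH_GLRLM.SRLGE",
 "HH_GLRLM.SRHGE",
 "FRAC.box_counting_dimension",
 "FRAC.intensity_fractal_dimension",
 "FRAC.lacunarity"
]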