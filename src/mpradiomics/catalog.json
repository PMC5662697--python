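{
  "version": 1,
  "notes": {
    "firstorder": "Statistics of the raw (unquantized) intensity sample; entropy and uniformity use a 64-bin histogram; kurtosis is non-excess (normal -> 3).",
    "highorder": "Matrix-based texture statistics on region-quantized levels; matrices pooled over the 13 unique 3D direction offsets at distance 1 (GLCM, GLRLM); GLSZM zones are 26-connected; NGTDM uses the 26-neighbourhood mean."
  },
  "firstorder": [
    "mean", "median", "minimum", "maximum", "range", "std", "variance",
    "skewness", "kurtosis", "energy", "entropy", "uniformity"
  ],
  "GLCM": [
    "autocorrelation", "cluster_prominence", "cluster_shade", "cluster_tendency",
    "contrast", "correlation", "difference_entropy", "dissimilarity",
    "energy", "entropy", "homogeneity1", "homogeneity2",
    "IMC1", "IMC2", "IDMN", "IDN", "inverse_variance", "max_probability",
    "sum_average", "sum_entropy", "sum_variance", "variance"
  ],
  "GLRLM": [
    "SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
    "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLV", "RLV"
  ],
  "GLSZM": [
    "SAE", "LAE", "GLN", "SZN", "ZP", "LGZE", "HGZE",
    "SALGE", "SAHGE", "LALGE", "LAHGE", "GLV"
  ],
  "NGTDM": ["coarseness", "contrast", "busyness", "complexity", "strength"]
}
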