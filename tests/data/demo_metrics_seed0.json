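{
 "validated_peaks": {
  "D0": {
   "n_called": 60,
   "n_truth": 60,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  },
  "D3": {
   "n_called": 60,
   "n_truth": 60,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  },
  "D6": {
   "n_called": 60,
   "n_truth": 60,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  }
 },
 "cis_class": {
  "promoter": {
   "n_called": 60,
   "n_truth": 60,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  },
  "enhancer": {
   "n_called": 120,
   "n_truth": 120,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  }
 },
 "super_enhancers": {
  "n_called": 31,
  "n_truth": 30,
  "precision": 0.967741935483871,
  "recall": 1.0,
  "jaccard": 0.967741935483871
 },
 "target_links": {
  "D0": {
   "n_called": 51,
   "n_truth": 53,
   "precision": 1.0,
   "recall": 0.9622641509433962,
   "jaccard": 0.9622641509433962
  },
  "D3": {
   "n_called": 50,
   "n_truth": 53,
   "precision": 1.0,
   "recall": 0.9433962264150944,
   "jaccard": 0.9433962264150944
  },
  "D6": {
   "n_called": 53,
   "n_truth": 53,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  }
 },
 "temporal_classes": {
  "D0": {
   "n_called": 39,
   "n_truth": 40,
   "precision": 1.0,
   "recall": 0.975,
   "jaccard": 0.975
  },
  "D3": {
   "n_called": 37,
   "n_truth": 40,
   "precision": 1.0,
   "recall": 0.925,
   "jaccard": 0.925
  },
  "D6": {
   "n_called": 40,
   "n_truth": 40,
   "precision": 1.0,
   "recall": 1.0,
   "jaccard": 1.0
  }
 },
 "fisher_cooccupancy": {
  "odds_ratio": 13.867647058823529,
  "pvalue": 5.025880743784999e-20
 },
 "runx2_loss": {
  "n_called": 82,
  "n_truth": 82,
  "precision": 0.9878048780487805,
  "recall": 0.9878048780487805,
  "jaccard": 0.9759036144578314
 },
 "motif_enrichment": {
  "fraction_bound": 0.5584415584415584,
  "fraction_background": 0.1111111111111111,
  "odds_ratio": 10.117647058823529,
  "pvalue": 1.8828741120609696e-13
 }
}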