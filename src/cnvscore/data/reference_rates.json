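{
  "comment": "Published tallies from a nine-laboratory CNV classification comparison; numerator/denominator pairs. Used as worked-example inputs for pooled-rate and chi-square reporting.",
  "distributed_panel": {
    "n": 234,
    "previous_method_complete": [41, 234],
    "metric_complete": [177, 234],
    "metric_subsets": {
      "recurrent_deletions": [43, 47],
      "nonrecurrent_duplications": [47, 63],
      "recurrent_duplications": [34, 47],
      "nonrecurrent_deletions": [53, 77]
    },
    "post_review_complete": [199, 234]
  },
  "submitted_panel": {
    "n": 72,
    "metric_complete": [47, 72],
    "post_review_complete": [61, 72]
  }
}
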