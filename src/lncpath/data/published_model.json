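{
 "terms": [
  ["AC020916.1", -0.442],
  ["AC079313.1", 0.933],
  ["AC245128.3", 0.333],
  ["AL135818.1", -0.861],
  ["LINC02818", 1.27],
  ["RASA2_IT1", 2.104]
 ],
 "training_median": 0.0
}
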