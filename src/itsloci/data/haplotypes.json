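{
  "alignment_length": 662,
  "regions": {"ITS1": [1, 300], "5.8S": [300, 440], "ITS2": [440, 663]},
  "columns": [39, 114, 122, 130, 145, 146, 200, 269, 334, 466, 475, 559, 649],
  "haplotypes": {
    "A": {"39": "T", "114": "A", "122": "A", "130": "A", "145": "G", "146": "A", "200": "T", "269": "G", "334": "A", "466": "A", "475": "T", "559": "G", "649": "T"},
    "B": {"39": "-", "114": "G", "122": "G", "130": "G", "145": "A", "146": "T", "200": "C", "269": "G", "334": "G", "466": "A", "475": "T", "559": "A", "649": "A"},
    "C": {"39": "-", "114": "A", "122": "G", "130": "G", "145": "A", "146": "T", "200": "C", "269": "A", "334": "A", "466": "C", "475": "-", "559": "G", "649": "T"}
  }
}
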