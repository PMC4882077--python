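{
  "PRS016": {
    "enzymes": ["SalI"],
    "primers": ["CCGTCAAGGTCCTCAGTGAT", "TTTAGTGCTCATGGCAGCAG"],
    "alleles": {
      "1": {"length": 700, "cuts": {"SalI": [481]}},
      "2": {"length": 700, "cuts": {"SalI": [271, 481]}}
    }
  },
  "PRS049": {
    "enzymes": ["KpnI"],
    "primers": ["CCGAACGGTTCCATGACTAT", "TGTGGTCTCGCTTCATCTTG"],
    "alleles": {
      "1": {"length": 479, "cuts": {"KpnI": []}},
      "2": {"length": 479, "cuts": {"KpnI": [292]}}
    }
  },
  "PRS088": {
    "enzymes": ["AvaII"],
    "primers": ["CTCGCAATTAGCTTCCAAGG", "CGGTTGTCCAAGATCAAGGT"],
    "alleles": {
      "1": {"length": 757, "cuts": {"AvaII": []}},
      "2": {"length": 757, "cuts": {"AvaII": [449]}}
    }
  },
  "ITS": {
    "enzymes": ["MboII", "FokI"],
    "primers": ["GGAAGTAAAAGTCGTAACAAGG", "TCCTCCGCTTATTGATATGC"],
    "gel": {"resolution_rel": 0.02, "min_visible_bp": 150, "flag_redundant_smallest": true},
    "alleles": {
      "A": {"length": 773, "cuts": {"MboII": [396], "FokI": []}},
      "B": {"length": 772, "cuts": {"MboII": [], "FokI": [563]}},
      "C": {"length": 771, "cuts": {"MboII": [395, 659], "FokI": [562]}}
    }
  }
}
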