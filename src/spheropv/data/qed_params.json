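{
  "comment": "Asymmetric double-sigmoid desirability parameters (a, b, c, d, e, f) and the function maximum dmax for the eight QED descriptors, as fitted in the original QED publication (Bickerton et al., Nature Chemistry 4:90-98, 2012).",
  "version": "qed-2012",
  "parameters": {
    "MW":     {"a": 2.817065973,  "b": 392.5754953, "c": 290.7489764,  "d": 2.419764353, "e": 49.22325677, "f": 65.37051707, "dmax": 104.9805561},
    "ALOGP":  {"a": 3.172690585,  "b": 137.8624751, "c": 2.534937431,  "d": 4.581497897, "e": 0.822739154, "f": 0.576295591, "dmax": 131.3186604},
    "HBA":    {"a": 2.948620388,  "b": 160.4605972, "c": 3.615294657,  "d": 4.435986202, "e": 0.290141953, "f": 1.300669958, "dmax": 148.7763046},
    "HBD":    {"a": 1.618662227,  "b": 1010.051101, "c": 0.985094388,  "d": 1e-09,       "e": 0.713820843, "f": 0.920922555, "dmax": 258.1632616},
    "PSA":    {"a": 1.876861559,  "b": 125.2232657, "c": 62.90773554,  "d": 87.83366614, "e": 12.01999824, "f": 28.51324732, "dmax": 104.5686167},
    "ROTB":   {"a": 0.01,         "b": 272.4121427, "c": 2.55837997,   "d": 1.565547684, "e": 1.271567166, "f": 2.758063707, "dmax": 105.4420403},
    "AROM":   {"a": 3.21778897,   "b": 957.7374108, "c": 2.274627939,  "d": 1e-09,       "e": 1.317690384, "f": 0.375760881, "dmax": 312.337261},
    "ALERTS": {"a": 0.01,         "b": 1199.094025, "c": -0.09002883,  "d": 1e-09,       "e": 0.185904477, "f": 0.875193782, "dmax": 417.725314}
  }
}
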