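{
  "trine_symmetric": {
    "file": "trine_symmetric.csv",
    "n": 7076,
    "model": "trine",
    "description": "Click counts from the symmetric trine experiment (phi0 = pi/6)."
  },
  "trine_asymmetric": {
    "file": "trine_asymmetric.csv",
    "n": 6756,
    "model": "trine",
    "description": "Click counts from the asymmetric trine experiment (phi0 = 2 pi/9)."
  },
  "ccr5": {
    "file": "ccr5.csv",
    "n": 212,
    "model": "hwe",
    "description": "CCR-5 genotype counts (A1A1, A1A2, A2A2) in a sample of 212 AIDS-free men."
  },
  "fly_diversity": {
    "file": "fly_diversity.csv",
    "n": 363,
    "model": "ordered",
    "description": "Fly species-abundance counts over 18 ranked species."
  }
}
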