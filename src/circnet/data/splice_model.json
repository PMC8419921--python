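{
 "donor": [
  {
   "A": 0.25,
   "C": 0.4,
   "G": 0.2,
   "T": 0.15
  },
  {
   "A": 0.55,
   "C": 0.15,
   "G": 0.2,
   "T": 0.1
  },
  {
   "A": 0.12,
   "C": 0.07,
   "G": 0.75,
   "T": 0.06
  },
  {
   "A": 0.005,
   "C": 0.005,
   "G": 0.985,
   "T": 0.005
  },
  {
   "A": 0.005,
   "C": 0.005,
   "G": 0.005,
   "T": 0.985
  },
  {
   "A": 0.85,
   "C": 0.04,
   "G": 0.07,
   "T": 0.04
  },
  {
   "A": 0.7,
   "C": 0.1,
   "G": 0.15,
   "T": 0.05
  },
  {
   "A": 0.1,
   "C": 0.06,
   "G": 0.8,
   "T": 0.04
  },
  {
   "A": 0.18,
   "C": 0.25,
   "G": 0.12,
   "T": 0.45
  }
 ],
 "acceptor": [
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.12,
   "C": 0.33,
   "G": 0.1,
   "T": 0.45
  },
  {
   "A": 0.08,
   "C": 0.6,
   "G": 0.07,
   "T": 0.25
  },
  {
   "A": 0.985,
   "C": 0.005,
   "G": 0.005,
   "T": 0.005
  },
  {
   "A": 0.005,
   "C": 0.005,
   "G": 0.985,
   "T": 0.005
  },
  {
   "A": 0.22,
   "C": 0.15,
   "G": 0.5,
   "T": 0.13
  },
  {
   "A": 0.2,
   "C": 0.4,
   "G": 0.15,
   "T": 0.25
  },
  {
   "A": 0.25,
   "C": 0.17,
   "G": 0.45,
   "T": 0.13
  }
 ],
 "background": {
  "A": 0.25,
  "C": 0.25,
  "G": 0.25,
  "T": 0.25
 },
 "scale": 0.56664606
}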