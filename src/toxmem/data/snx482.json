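{
 "name": "SNX-482",
 "uniprot_name": "omega-theraphotoxin-Hg1a",
 "description": "41-residue ICK gating-modifier toxin; formal charges at neutral pH (His neutral); residue masses are average masses of the peptide-bonded residue (free amino acid minus one water).",
 "hydrophobic_patch": [
  9,
  10,
  11,
  12,
  29,
  30,
  31,
  32,
  33,
  34,
  35
 ],
 "residues": [
  {
   "position": 1,
   "aa": "G",
   "charge": 0,
   "mass_da": 57.0513
  },
  {
   "position": 2,
   "aa": "V",
   "charge": 0,
   "mass_da": 99.131
  },
  {
   "position": 3,
   "aa": "D",
   "charge": -1,
   "mass_da": 115.0874
  },
  {
   "position": 4,
   "aa": "K",
   "charge": 1,
   "mass_da": 128.1723
  },
  {
   "position": 5,
   "aa": "A",
   "charge": 0,
   "mass_da": 71.0779
  },
  {
   "position": 6,
   "aa": "G",
   "charge": 0,
   "mass_da": 57.0513
  },
  {
   "position": 7,
   "aa": "C",
   "charge": 0,
   "mass_da": 103.1429
  },
  {
   "position": 8,
   "aa": "R",
   "charge": 1,
   "mass_da": 156.1857
  },
  {
   "position": 9,
   "aa": "Y",
   "charge": 0,
   "mass_da": 163.1732
  },
  {
   "position": 10,
   "aa": "M",
   "charge": 0,
   "mass_da": 131.196
  },
  {
   "position": 11,
   "aa": "F",
   "charge": 0,
   "mass_da": 147.1738
  },
  {
   "position": 12,
   "aa": "G",
   "charge": 0,
   "mass_da": 57.0513
  },
  {
   "position": 13,
   "aa": "G",
   "charge": 0,
   "mass_da": 57.0513
  },
  {
   "position": 14,
   "aa": "C",
   "charge": 0,
   "mass_da": 103.1429
  },
  {
   "position": 15,
   "aa": "S",
   "charge": 0,
   "mass_da": 87.0773
  },
  {
   "position": 16,
   "aa": "V",
   "charge": 0,
   "mass_da": 99.131
  },
  {
   "position": 17,
   "aa": "N",
   "charge": 0,
   "mass_da": 114.1026
  },
  {
   "position": 18,
   "aa": "D",
   "charge": -1,
   "mass_da": 115.0874
  },
  {
   "position": 19,
   "aa": "D",
   "charge": -1,
   "mass_da": 115.0874
  },
  {
   "position": 20,
   "aa": "C",
   "charge": 0,
   "mass_da": 103.1429
  },
  {
   "position": 21,
   "aa": "C",
   "charge": 0,
   "mass_da": 103.1429
  },
  {
   "position": 22,
   "aa": "P",
   "charge": 0,
   "mass_da": 97.1152
  },
  {
   "position": 23,
   "aa": "R",
   "charge": 1,
   "mass_da": 156.1857
  },
  {
   "position": 24,
   "aa": "L",
   "charge": 0,
   "mass_da": 113.1576
  },
  {
   "position": 25,
   "aa": "G",
   "charge": 0,
   "mass_da": 57.0513
  },
  {
   "position": 26,
   "aa": "C",
   "charge": 0,
   "mass_da": 103.1429
  },
  {
   "position": 27,
   "aa": "H",
   "charge": 0,
   "mass_da": 137.1393
  },
  {
   "position": 28,
   "aa": "S",
   "charge": 0,
   "mass_da": 87.0773
  },
  {
   "position": 29,
   "aa": "L",
   "charge": 0,
   "mass_da": 113.1576
  },
  {
   "position": 30,
   "aa": "F",
   "charge": 0,
   "mass_da": 147.1738
  },
  {
   "position": 31,
   "aa": "S",
   "charge": 0,
   "mass_da": 87.0773
  },
  {
   "position": 32,
   "aa": "Y",
   "charge": 0,
   "mass_da": 163.1732
  },
  {
   "position": 33,
   "aa": "C",
   "charge": 0,
   "mass_da": 103.1429
  },
  {
   "position": 34,
   "aa": "A",
   "charge": 0,
   "mass_da": 71.0779
  },
  {
   "position": 35,
   "aa": "W",
   "charge": 0,
   "mass_da": 186.2099
  },
  {
   "position": 36,
   "aa": "D",
   "charge": -1,
   "mass_da": 115.0874
  },
  {
   "position": 37,
   "aa": "L",
   "charge": 0,
   "mass_da": 113.1576
  },
  {
   "position": 38,
   "aa": "T",
   "charge": 0,
   "mass_da": 101.1039
  },
  {
   "position": 39,
   "aa": "F",
   "charge": 0,
   "mass_da": 147.1738
  },
  {
   "position": 40,
   "aa": "S",
   "charge": 0,
   "mass_da": 87.0773
  },
  {
   "position": 41,
   "aa": "D",
   "charge": -1,
   "mass_da": 115.0874
  }
 ]
}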