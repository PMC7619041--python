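{
 "primary": {
  "1": "CB",
  "2": "TH",
  "3": "MB",
  "4": "HB",
  "5": "Isocortex",
  "6": "HY",
  "7": "OLF",
  "8": "CTXsp",
  "9": "STR",
  "10": "PAL",
  "11": "HPF"
 },
 "map": {
  "1": 1,
  "2": 2,
  "3": 3,
  "4": 4,
  "5": 5,
  "6": 6,
  "7": 7,
  "8": 8,
  "9": 9,
  "10": 10,
  "11": 11
 }
}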