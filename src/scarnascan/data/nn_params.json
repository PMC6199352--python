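{
 "bulge_penalty": 3.0,
 "comment": "Nearest-neighbor RNA stack free energies (Turner-2004-style) and hairpin loop initiation penalties, kcal/mol at 37C. DNA letters, T read as U. Stack keys are 'XY/ZW' = 5'-XY-3' over 3'-ZW-5', X:Z and Y:W paired. Table is symmetric under reading the duplex from the other end. Terminal-pair penalties are not modelled.",
 "hairpin_loop": {
  "10": 6.5,
  "11": 6.6,
  "12": 6.7,
  "13": 6.8,
  "3": 5.4,
  "4": 5.6,
  "5": 5.7,
  "6": 5.4,
  "7": 6.0,
  "8": 5.5,
  "9": 6.4
 },
 "stack": {
  "AA/TT": -0.93,
  "AC/TG": -2.24,
  "AG/TC": -2.08,
  "AG/TT": -0.55,
  "AT/TA": -1.1,
  "AT/TG": -1.36,
  "CA/GT": -2.11,
  "CC/GG": -3.26,
  "CG/GC": -2.36,
  "CG/GT": -1.41,
  "CT/GA": -2.08,
  "CT/GG": -2.11,
  "GA/CT": -2.35,
  "GA/TT": -1.0,
  "GC/CG": -3.42,
  "GC/TG": -2.51,
  "GG/CC": -3.26,
  "GG/CT": -1.53,
  "GG/TC": -2.11,
  "GG/TT": -0.5,
  "GT/CA": -2.24,
  "GT/CG": -2.51,
  "GT/TA": -1.36,
  "GT/TG": 0.47,
  "TA/AT": -1.33,
  "TA/GT": -1.27,
  "TC/AG": -2.35,
  "TC/GG": -1.53,
  "TG/AC": -2.11,
  "TG/AT": -1.27,
  "TG/GC": -1.41,
  "TG/GT": 0.3,
  "TT/AA": -0.93,
  "TT/AG": -1.0,
  "TT/GA": -0.55,
  "TT/GG": -0.5
 },
 "units": "kcal/mol",
 "version": "scarnascan-nn-1.0"
}
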