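# Default 45-channel probe for the breathing / thermal-QST study design:
# 8 emitters x 28 detectors at 3 cm nominal separation, two wavelengths
# (690 / 830 nm).  The emitter-detector pairing below is a stand-in with the
# correct counts; published montages give only a schematic cap drawing, so
# the exact pairing is a configuration choice, not a reconstruction.
# Channels are numbered 1..45 in canonical (emitter, detector) sort order.
wavelengths_nm: [690.0, 830.0]
nominal_separation_mm: 30.0
pairs:  # [emitter, detector], canonical order
  - [1, 1]
  - [1, 2]
  - [1, 3]
  - [1, 4]
  - [1, 5]
  - [2, 4]
  - [2, 5]
  - [2, 6]
  - [2, 7]
  - [2, 8]
  - [2, 9]
  - [3, 7]
  - [3, 8]
  - [3, 9]
  - [3, 10]
  - [3, 11]
  - [3, 12]
  - [4, 10]
  - [4, 11]
  - [4, 12]
  - [4, 13]
  - [4, 14]
  - [4, 15]
  - [5, 13]
  - [5, 14]
  - [5, 15]
  - [5, 16]
  - [5, 17]
  - [5, 18]
  - [6, 16]
  - [6, 17]
  - [6, 18]
  - [6, 19]
  - [6, 20]
  - [6, 21]
  - [7, 19]
  - [7, 20]
  - [7, 21]
  - [7, 22]
  - [7, 23]
  - [8, 24]
  - [8, 25]
  - [8, 26]
  - [8, 27]
  - [8, 28]
# Anatomical label per channel (1-based channel index -> region).
# Bilateral anterior prefrontal (aPFC), dorsolateral prefrontal (DLPFC),
# premotor (PMC), supplementary motor (SMA), motor (M1), primary
# somatosensory (S1), visual (V1), superior temporal (STG),
# temporo-parietal junction (TPJ), inferior parietal lobule (IPL).
region_map:
  1: aPFC
  2: aPFC
  3: aPFC
  4: aPFC
  5: aPFC
  6: aPFC
  7: aPFC
  8: aPFC
  9: PMC
  10: PMC
  11: PMC
  12: PMC
  13: PMC
  14: PMC
  15: SMA
  16: SMA
  17: M1
  18: M1
  19: M1
  20: other
  21: other
  22: STG
  23: STG
  24: other
  25: other
  26: PMC
  27: M1
  28: M1
  29: S1
  30: S1
  31: DLPFC
  32: DLPFC
  33: PMC
  34: SMA
  35: S1
  36: S1
  37: other
  38: TPJ
  39: TPJ
  40: IPL
  41: IPL
  42: STG
  43: V1
  44: V1
  45: V1
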