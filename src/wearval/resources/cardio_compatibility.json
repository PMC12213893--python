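{
 "ecg": {
  "clean": [
   "nk_default",
   "langevin",
   "elgendi_ecg",
   "none"
  ],
  "peaks": [
   "brammer",
   "elgendi_dual_ma",
   "nabian_window",
   "gamboa"
  ],
  "pairs": [
   [
    "nk_default",
    "brammer"
   ],
   [
    "nk_default",
    "elgendi_dual_ma"
   ],
   [
    "nk_default",
    "nabian_window"
   ],
   [
    "nk_default",
    "gamboa"
   ],
   [
    "langevin",
    "brammer"
   ],
   [
    "langevin",
    "elgendi_dual_ma"
   ],
   [
    "langevin",
    "nabian_window"
   ],
   [
    "langevin",
    "gamboa"
   ],
   [
    "elgendi_ecg",
    "brammer"
   ],
   [
    "elgendi_ecg",
    "elgendi_dual_ma"
   ],
   [
    "elgendi_ecg",
    "nabian_window"
   ],
   [
    "elgendi_ecg",
    "gamboa"
   ],
   [
    "none",
    "brammer"
   ],
   [
    "none",
    "elgendi_dual_ma"
   ],
   [
    "none",
    "nabian_window"
   ],
   [
    "none",
    "gamboa"
   ]
  ]
 },
 "ppg": {
  "clean": [
   "langevin_ppg",
   "elgendi_ppg",
   "nabian_ppg",
   "none"
  ],
  "peaks": [
   "elgendi_dual_ma"
  ],
  "pairs": [
   [
    "langevin_ppg",
    "elgendi_dual_ma"
   ],
   [
    "elgendi_ppg",
    "elgendi_dual_ma"
   ],
   [
    "nabian_ppg",
    "elgendi_dual_ma"
   ],
   [
    "none",
    "elgendi_dual_ma"
   ]
  ]
 }
}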