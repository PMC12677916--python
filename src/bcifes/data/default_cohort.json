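{
 "_comment": [
  "Default synthetic cohort configuration.",
  "prescore: per-metric (mean, SD) at baseline G1.",
  "deltas[arm][metric][timepoint]: (mean, SD) of change from G1.",
  "BCI-FES G6 FMA effect is mean 4.5 with SD 3.75 so the paired",
  "standardized effect (Cohen's d) of the configured truth is 1.2.",
  "eeg_outcome_coupling: target Pearson r between Cz theta-power",
  "change and delta-FMA used by the coupling stage."
 ],
 "arms": [
  [
   "BCI-FES",
   12
  ],
  [
   "FES",
   12
  ],
  [
   "control",
   12
  ]
 ],
 "prescore": {
  "FMA": [
   19.2,
   10.1
  ],
  "MBI": [
   51.9,
   12.3
  ],
  "MoCA": [
   15.4,
   4.0
  ]
 },
 "deltas": {
  "BCI-FES": {
   "FMA": {
    "G2": [
     1.575,
     3.75
    ],
    "G3": [
     2.7,
     3.75
    ],
    "G4": [
     3.6,
     3.75
    ],
    "G5": [
     4.275,
     3.75
    ],
    "G6": [
     4.5,
     3.75
    ]
   },
   "MBI": {
    "G2": [
     1.89,
     4.909
    ],
    "G3": [
     3.24,
     4.909
    ],
    "G4": [
     4.32,
     4.909
    ],
    "G5": [
     5.13,
     4.909
    ],
    "G6": [
     5.4,
     4.909
    ]
   },
   "MoCA": {
    "G2": [
     0.8,
     2.0
    ],
    "G3": [
     1.3,
     2.0
    ],
    "G4": [
     1.6,
     2.0
    ],
    "G5": [
     0.6,
     2.0
    ],
    "G6": [
     -0.5,
     2.0
    ]
   }
  },
  "FES": {
   "FMA": {
    "G2": [
     0.595,
     4.25
    ],
    "G3": [
     1.02,
     4.25
    ],
    "G4": [
     1.36,
     4.25
    ],
    "G5": [
     1.615,
     4.25
    ],
    "G6": [
     1.7,
     4.25
    ]
   },
   "MBI": {
    "G2": [
     0.77,
     5.5
    ],
    "G3": [
     1.32,
     5.5
    ],
    "G4": [
     1.76,
     5.5
    ],
    "G5": [
     2.09,
     5.5
    ],
    "G6": [
     2.2,
     5.5
    ]
   },
   "MoCA": {
    "G2": [
     -0.1,
     2.0
    ],
    "G3": [
     -0.2,
     2.0
    ],
    "G4": [
     -0.2,
     2.0
    ],
    "G5": [
     -0.4,
     2.0
    ],
    "G6": [
     -0.8,
     2.0
    ]
   }
  },
  "control": {
   "FMA": {
    "G2": [
     0.315,
     4.5
    ],
    "G3": [
     0.54,
     4.5
    ],
    "G4": [
     0.72,
     4.5
    ],
    "G5": [
     0.855,
     4.5
    ],
    "G6": [
     0.9,
     4.5
    ]
   },
   "MBI": {
    "G2": [
     0.455,
     2.6
    ],
    "G3": [
     0.78,
     2.6
    ],
    "G4": [
     1.04,
     2.6
    ],
    "G5": [
     1.235,
     2.6
    ],
    "G6": [
     1.3,
     2.6
    ]
   },
   "MoCA": {
    "G2": [
     0.3,
     2.0
    ],
    "G3": [
     0.5,
     2.0
    ],
    "G4": [
     0.6,
     2.0
    ],
    "G5": [
     0.1,
     2.0
    ],
    "G6": [
     -0.4,
     2.0
    ]
   }
  }
 },
 "eeg_outcome_coupling": 0.68,
 "responder_profile": {
  "age_max": 70.0,
  "onset_max_months": 23.0,
  "mbi_min": 40.0,
  "delta_fma_min": 5.0
 },
 "profile_effect": 0.0,
 "seed": 0
}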