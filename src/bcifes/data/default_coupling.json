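{
 "_comment": [
  "Default EEG-outcome coupling configuration.",
  "rho: target Pearson correlation between the per-patient Cz",
  "theta-power change (post - pre, uV^2) and delta-FMA.",
  "Recordings are compact 60-s, 3-channel (C3/Cz/C4) segments: only",
  "Cz theta carries the outcome signal, so full-pipeline recovery",
  "runs stay cheap while retaining three 20-s Welch windows."
 ],
 "rho": 0.68,
 "channel": "Cz",
 "theta_center": 6.0,
 "theta_bandwidth": 3.0,
 "pre_theta_power": 18.0,
 "delta_power_mean": 8.0,
 "delta_power_sd": 6.0,
 "metric": "FMA",
 "timepoint": "G6",
 "eeg": {
  "channels": [
   "C3",
   "Cz",
   "C4"
  ],
  "duration": 60.0,
  "sampling_rate": 250.0,
  "background_rms": 2.0
 }
}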