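{
  "comment": "Per-class Chay-model regimes used by the mechanistic dataset generator. PD: tonic spiking limit cycle. RD: improved model (w_K > 1) producing irregular alternation of burst clusters without noise. CD: chaotic bursting of the original deterministic model. IMD: weak K-channel noise just past the firing boundary, producing spike skipping at near-integer multiples of the slow-wave period.",
  "dt": 0.001,
  "classes": {
    "PD": {
      "label": 0,
      "model": "deterministic",
      "params": {"g_KC": 10.0},
      "dt": 0.001,
      "threshold": -30.0,
      "refractory": 0.05,
      "chunk_T": 500.0,
      "transient_isis": 10
    },
    "RD": {
      "label": 1,
      "model": "improved",
      "params": {"g_KC": 11.5, "w_K": 1.1},
      "dt": 0.001,
      "threshold": -30.0,
      "refractory": 0.05,
      "chunk_T": 800.0,
      "transient_isis": 10
    },
    "CD": {
      "label": 2,
      "model": "deterministic",
      "params": {"g_KC": 11.12},
      "dt": 0.001,
      "threshold": -30.0,
      "refractory": 0.05,
      "chunk_T": 600.0,
      "transient_isis": 10
    },
    "IMD": {
      "label": 3,
      "model": "stochastic",
      "params": {"g_KC": 27.6},
      "noise": {"kind": "k_white", "D": 1.0, "N_K": 3000},
      "dt": 0.001,
      "threshold": -30.0,
      "refractory": 0.3,
      "chunk_T": 3000.0,
      "transient_isis": 2
    }
  }
}
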