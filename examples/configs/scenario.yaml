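# Simulation scenario: true DLT probabilities with dose 2 at the target.
true_probs: [0.10, 0.25, 0.45, 0.60]
n_sims: 50
master_seed: 2026
followup_mode: tite
tox_time_model: uniform_conditional
accrual: poisson
accrual_rate: 0.05
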