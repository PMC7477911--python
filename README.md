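# titecrm

Bayesian dose-finding for phase I trials whose toxicities arrive late.

Classical model-based dose-finding (the continual reassessment method, CRM)
requires every participant to complete the full dose-limiting-toxicity (DLT)
observation window before the next dose decision. In radiotherapy oncology,
where the window is commonly 24 weeks to a year, that makes trials
impractically long. The time-to-event CRM (TiTE-CRM) instead lets every
enrolled participant contribute to each decision, weighted by how much of
the window they have completed — so recruitment continues during follow-up
and trials finish years sooner.

This package is for trial statisticians designing and running such studies:
it covers design calibration, live dose recommendation with escalation/
pause/stopping rules, auditable decision reports, and Monte-Carlo simulation
of operating characteristics.

## The model

Dose level `k` carries a calibrated label `d_k ∈ (0,1)` and the empiric
power curve models the DLT probability as

    F(d_k, β) = d_k^exp(β),        β ~ N(prior_mean, σ²)

Labels solve `F(d_k, E[β]) = π_0k` against the clinician skeleton
`π_01 < … < π_0K`, so the prior-mean model reproduces the skeleton exactly.
With `J` participants at labels `x_j`, DLT indicators `y_j`, and follow-up
weights `w_j`, inference uses the weighted likelihood

    L_J(β) = Π_j [F(x_j,β)·w_j]^{y_j} · [1 − F(x_j,β)·w_j]^{1−y_j}

where `w_j = t_j/T` for an event-free participant with follow-up `t_j` in a
window of length `T` (a piecewise-linear alternative front-loads weight into
an acute period), and `w_j = 1` whenever `y_j = 1`. The plug-in estimates
`π̂_k = d_k^exp(β̂)` at the posterior mean `β̂` determine the maximum
tolerated dose (MTD): either the highest dose with `π̂_k` below the target
toxicity level (TTL), or the dose closest to it.

## Worked example

```python
from titecrm import (DesignSpec, ParticipantRecord, TrialState, recommend_dose)

design = DesignSpec(skeleton=(0.05, 0.12, 0.22, 0.35), ttl=0.25,
                    dlt_window=168.0, n_max=21)
state = TrialState(
    participants=(
        ParticipantRecord("P1", 1, start_day=0,   last_contact_day=140),
        ParticipantRecord("P2", 2, start_day=35,  last_contact_day=140),
        ParticipantRecord("P3", 3, start_day=70,  last_contact_day=140, dlt_day=98),
        ParticipantRecord("P4", 2, start_day=126, last_contact_day=140),
    ),
    current_day=140,
)
rec = recommend_dose(state, design, with_interval=True)
print(rec.dose_index, rec.posterior.beta_hat, rec.posterior.pi_hat)
```

prints

```
1 -0.7188373359130704 [0.23226512 0.35585082 0.47813485 0.5995369 ]
```

Participant P3 had a DLT 28 days into the 168-day window and therefore
contributes full weight; the others carry weights 140/168, 105/168 and
14/168. One DLT among so little accumulated exposure pulls the posterior
mean of β to −0.72, lifting every fitted DLT probability above its skeleton
value; only dose 1 (π̂₁ = 0.232) remains below the 25% target, so the
engine recommends de-escalating to dose 1 for the next participant.

The `examples/` directory holds one narrative script per capability:
calibration, interim recommendation with a printed report, the best/worst
case recruitment-pause check, operating characteristics, and the paired
duration comparison against the complete-follow-up CRM. A thin CLI mirrors
the same workflow (`titecrm calibrate | recommend | pause-check | simulate |
fixture`) from YAML configs like those in `examples/configs/`.

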