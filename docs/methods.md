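# Methods

## Model and inference

The dose-toxicity relationship is the one-parameter empiric ("power")
model: dose level `k` has a calibrated label `d_k ∈ (0,1)` and DLT
probability `F(d_k, β) = d_k^exp(β)` with a normal prior on `β`. Labels are
obtained in closed form, `d_k = π_0k^(1/exp(E[β]))`, so the prior-mean
model reproduces the skeleton `π_0` exactly; this is verified to 1e-12 as a
package invariant. The model is deliberately single-parameter: with the
tiny sample sizes of phase I trials a richer curve is not estimable, and
the monotone transform guarantees the fitted probabilities stay ordered
across doses. Two-parameter (logistic) curves, overdose-control criteria
and ordinal-toxicity models are out of scope.

Participants who have not completed the DLT window contribute through the
weighted likelihood `Π [F·w]^y [1 − F·w]^{1−y}`. A DLT always carries
weight 1; an event-free participant carries the weight function evaluated
at their follow-up. With all weights 1 the likelihood reduces bitwise to
the classical CRM binomial likelihood, which the test suite asserts.

Posterior summaries use adaptive quadrature (Gauss–Kronrod via
`scipy.integrate.quad`, absolute tolerance 1e-10) of the unnormalized
posterior over `prior_mean ± 10σ`. The integrand is evaluated in the log
domain and shifted by its maximum over a 401-point scouting grid before
exponentiation: for ~100 participants the raw likelihood underflows double
precision, while the shifted integrand is O(1) and the shift cancels in
every reported ratio. The scouting grid also locates the posterior peak,
which is passed to the quadrature as a known feature. Credible intervals
are equal-tailed, found by Brent root-finding on the quadrature CDF
(xtol 1e-10). Truncating at ±10 prior standard deviations discards
negligible mass for any dataset a phase I trial can produce; if the
normalizing constant nonetheless vanishes numerically the code raises with
a message pointing at the integration bounds. `F·w` is clipped to
`[1e-300, 1 − 1e-16]` purely to keep logarithms finite; this never moves a
result at tolerance level.

The MTD estimate is the plug-in `π̂_k = d_k^exp(β̂)` at the posterior mean
`β̂` — not the posterior mean of `F`, which differs. Both common MTD
definitions are provided and neither is privileged: `highest_below` (the
highest dose with `π̂_k` under the target) and `closest` (minimum
`|π̂_k − TTL|`). Ties under `closest` break to the lower dose —
safety-first. When every `π̂_k` sits at or above the target,
`highest_below` returns dose 1 with an `all_doses_above_target` flag
rather than failing; whether to stop is the conduct layer's decision.

## Weight functions

The linear weight `w = t/T` is the default, appropriate when the DLT
hazard is roughly constant over the window. The piecewise-linear
alternative takes ordered `(duration, mass)` segments whose durations
partition the window and whose masses sum to one; the packaged
`WeightSpec.olaparib()` convenience builds the two-segment scheme used
when acute (haematological) and late (pneumonitis-like) toxicities are
expected in roughly equal measure — a 1-year window whose first 3 months
carry half the total weight. All times are days; calendar months must be
declared in days by the user (the olaparib scheme as 91 + 274 days here).
Whether such an acute boundary is exactly 91 days or a calendar quarter is
a configuration decision, not a package constant. Follow-up beyond `T` is
silently truncated to `T`, and a DLT recorded after the window closes is
treated as event-free with full weight — the window defines the endpoint.
Data-adaptive weight functions estimated from interim DLT timing are not
implemented.

The partial-treatment rule reproduces the evaluability weighting used in
practice: a DLT-free participant who received less than a threshold
fraction (default 80%) of the planned drug has follow-up credited only to
the last day of full treatment, reducing their weight; a participant with
a DLT keeps full weight regardless, so the fitted curve cannot become
overly optimistic. The rule never increases follow-up.

## Conduct rules

Until the initial cohort (default 3) is enrolled, the starting dose is
assigned. Afterwards the model's MTD is capped at one level above the
highest dose yet administered (no skipping), and escalation above the
highest administered dose requires at least `min_exposed_participants`
(default 3) with at least `min_exposure_days` (default 91) of follow-up at
or above that dose. "At or above" is chosen over "exactly at": exposure at
a higher dose is stronger evidence of tolerability, so the relaxation only
operates in the safe direction. Exposure is measured as time since
treatment start, the natural reading of "exposed" for concurrent
chemoradiotherapy regimens. Every recommendation reports the unrestricted
model choice alongside the final dose and the list of restrictions that
modified it, because the model's dose is never to be followed blindly;
dose reduction of participants already on treatment is deliberately left
to human review and is not automated.

Stopping: maximum sample size, plus a safety rule that stops when the
posterior probability that even the lowest dose exceeds the TTL passes a
threshold (default 0.9). The literature asks for such a rule without
fixing its form; the posterior-tail formulation reuses the same quadrature
as the posterior mean, since for the power model
`P[F(d₁,β) > TTL] = P[β < log(log TTL / log d₁)]` is a single CDF
evaluation.

The pause check implements the best/worst-case comparison: recompute the
recommendation assuming every incompletely followed participant has a DLT,
then assuming none does; if the decisions coincide, pausing recruitment
buys nothing. Recruitment slots (`max_pending_slots`) cap concurrent
incompletely followed participants and set the pause flag when reached.
Participants deemed non-evaluable are handled by the weighting adjustment
only; no replacement logic exists, mirroring how such trials actually
resolve the issue.

## Simulator

Trials are simulated event by event. Arrivals follow a Poisson process
(default rate 0.05/day ≈ 1.5 participants/month, typical of phase I
radiotherapy oncology) or fixed interarrival times; the first participant
arrives on day 0. Each arrival's dose comes from the decision engine run
on the state at that calendar day. DLTs are Bernoulli in the scenario's
per-dose true probabilities; onset within the window is uniform by default
(consistent with the constant-hazard rationale of the linear weight) or a
Weibull truncated to the window for late-onset stress tests of weight
mis-specification. Scenario truth need not be monotone across doses.

In complete-follow-up mode — the classical CRM comparator — each arrival
waits until every current participant has resolved (window complete or
DLT); queued arrivals are never lost. Waiting from slot limits or, when a
scenario opts in via `use_pause_check`, from the best/worst-case check,
works the same way and counts toward trial duration. The per-arrival pause
check is opt-in in simulation because it triples the posterior
computations per decision while the check is primarily a pre-trial design
aid; the slot limit, which is cheap, is always honoured when set.

Trial duration is the day the last participant's follow-up ends (window
end, or DLT if earlier). The declared MTD is the final complete-data model
estimate, capped at the highest dose actually administered — a dose never
given cannot be declared. A trial stopped by the safety rule is recorded
as `stopped_toxic`, its own category in the selection percentages.
Reproducibility uses one master seed spawning independent per-replicate
substreams (`numpy` `SeedSequence`), so growing `n_sims` leaves earlier
replicates unchanged, and the mode comparison pairs replicates through
common substreams.

## Default study conditions

The examples and heavier tests use one frozen reference design: four
doses, skeleton (0.05, 0.12, 0.22, 0.35), TTL 0.25, a 168-day (24-week)
DLT window, N = 21, prior `β ~ N(0, 1.34²)` — the conventional empiric-CRM
prior spread, user-overridable — starting at dose 1 with the default
conduct rules above. The reference simulation scenario places the true MTD
at dose 2 (truth 0.10/0.25/0.45/0.60). Simulation-backed checks use 200
paired replicates for the duration comparison and a shared batch of 500
replicates for rule-enforcement and selection checks; parameter-recovery
checks use 200 replicates at n = 10 versus n = 100.

## What the simulator does and does not emulate

The generator produces the structure the method consumes — staggered
accrual, within-window DLT timing, escalation dynamics — under exactly
known truth, which is what operating characteristics require. It does not
emulate data-entry delay, participant replacement, non-DLT toxicity
profiles, dose reductions on treatment, or between-site heterogeneity.
Passing tests therefore demonstrate the statistical machinery is correct
and the conduct rules are enforced, not that any particular clinical trial
will enjoy these operating characteristics; published numeric OC tables
for specific trials are not reproduced here, so simulator output is
validated by properties (conservation, determinism, degenerate scenarios,
onset-distribution checks) rather than against published tables.

## Known limitations

Single-group estimation only (concurrent/sequential treatment groups run
as independent engine instances); no multi-arm or platform ("flip-flop")
designs; no NTCP-based prior elicitation (priors are numeric inputs); no
closed-form accrual-suspension rules beyond the best/worst-case check; no
PDF report rendering (reports are Markdown-ish text plus JSON, with an
append-only digest-verified archive).
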