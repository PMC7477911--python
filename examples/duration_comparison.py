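"""Why use the time-to-event design at all?

The classical CRM must wait for every participant to complete the DLT
window before the next dose decision; with a 24-week window and continuous
accrual that multiplies trial duration.  The time-to-event weighting lets
recruitment continue during follow-up.  This script measures the saving by
paired simulation with common random numbers.
"""

from titecrm import DesignSpec, ScenarioSpec, compare_followup_modes

design = DesignSpec(
    skeleton=(0.05, 0.12, 0.22, 0.35), ttl=0.25, dlt_window=168.0, n_max=21
)
scenario = ScenarioSpec(
    true_probs=(0.10, 0.25, 0.45, 0.60),
    n_sims=20,          # raise for protocol-grade precision
    master_seed=7,
    accrual="poisson",
    accrual_rate=0.05,  # about 1.5 participants per month
)

tite, complete = compare_followup_modes(scenario, design)
print(f"mean duration, time-to-event weighting: {tite:8.0f} days"
      f"  (~{tite / 365.25:.1f} years)")
print(f"mean duration, complete follow-up CRM:  {complete:8.0f} days"
      f"  (~{complete / 365.25:.1f} years)")
print(f"saving: {complete - tite:.0f} days")
print(
    "\nBoth arms saw identical random inputs; the entire difference comes "
    "from letting accrual continue while follow-up accumulates."
)
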