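"""Fit the dyad model to a simulated demethylation time course.

Simulates a serum-to-2i-like experiment (days 0/1/3/6, two divisions per
day) with maintenance 0.8, de novo 0.1 and hydroxylation 0.05 per division
under the measured Afp conversion errors, then recovers the efficiencies
and 5hmC levels by maximum likelihood, and compares the model-based 5hmC
estimate with the naive BS-minus-oxBS subtraction.
"""

import numpy as np

from hpoxbs import presets
from hpoxbs.conversion import derive_emission_parameters
from hpoxbs.model import (
    DivisionSchedule,
    EnzymeEfficiencies,
    fit,
    hydroxylation_summary,
    strand_levels,
)
from hpoxbs.simulate import SimulationConfig, population_distributions, simulate_counts

emissions = derive_emission_parameters(
    {"unmodC": 0.996, "5mC": 0.0674, "5hmC": 0.0765},
    {"unmodC": 0.996, "5mC": 0.0636, "5hmC": 0.920},
)
schedule = DivisionSchedule(
    days=presets.DEFAULT_SCHEDULE_DAYS, divisions=presets.DEFAULT_SCHEDULE_DIVISIONS
)
truth = EnzymeEfficiencies(mu=0.8, delta=0.1, eta=0.05)
config = SimulationConfig(
    reference=presets.demo_reference(),
    efficiencies=truth,
    initial_distribution=presets.DEFAULT_INIT_DISTRIBUTION,
    schedule=schedule,
    emissions=emissions,
    n_molecules=5000,
    seed=8,
)
counts = simulate_counts(config)
result = fit(counts, schedule, emissions, mode="constant", n_starts=8, seed=0)

est = result.efficiencies[0]
print(f"true efficiencies:   mu={truth.mu:.3f}  delta={truth.delta:.3f}  eta={truth.eta:.3f}")
print(f"fitted efficiencies: mu={est[0]:.3f}  delta={est[1]:.3f}  eta={est[2]:.3f}")
print(f"log-likelihood {result.log_likelihood:.1f} over {result.n_starts} starts\n")

true_dists = population_distributions(config)
print("day   true 5hmC   model 5hmC   naive BS-oxBS")
for t, day in enumerate(schedule.days):
    true_h = strand_levels(true_dists[t])["5hmC"]
    model_h = hydroxylation_summary(result, t)["total_5hmc_per_strand"]
    lv = {}
    for tr in ("BS", "oxBS"):
        arr = counts.counts[tr][t].astype(float)
        lv[tr] = (2 * arr[0] + arr[1] + arr[2]) / (2 * arr.sum())
    naive = lv["BS"] - lv["oxBS"]
    print(f"{day:3g}   {true_h:9.4f}   {model_h:10.4f}   {naive:13.4f}")

h = hydroxylation_summary(result, len(schedule.days) - 1)
print("\n5hmC pairing at day 6: "
      f"with C {h['h_with_u']:.4f}, with 5mC {h['h_with_m']:.4f}, "
      f"symmetric {h['h_symmetric']:.4f}")
print("\nThe model corrects for conversion errors, so its per-day 5hmC "
      "estimates sit closer to the truth than the naive subtraction, which "
      "is biased low by the ~7% BS conversion of modified bases.")
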