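"""Per-probe survival screen and per-type survival-association fractions.

Attaches exponential survival outcomes to the Cancer arm, with five probes
planted to carry a log hazard ratio of 2 per unit beta, screens every
probe with a univariate Cox fit, and summarizes the significant fraction
per trajectory type — under the null each type's fraction sits near the
5% screening level, nowhere near a quarter.
"""

from methtraj import (
    call_dmps,
    classify_eight_types,
    fraction_survival_associated,
    screen_probes,
    stage_mean_betas,
)
from methtraj.simulate import SimConfig, SurvivalSimConfig, simulate_dataset

cfg = SimConfig(
    seed=6, n_probes=1500, n_cancer=200,
    planted={t: 50 for t in range(1, 9)},
    survival=SurvivalSimConfig(n_probes=5, coef=2.0, censoring_rate=0.3),
)
bm, sheet, *_, truth = simulate_dataset(cfg)
events = int(sheet.df["os_event"].sum())
print(f"{len(sheet.stage_samples('C'))} cancer samples, {events} events")

res = screen_probes(bm, sheet, alpha=0.05)
planted = truth.index[truth["survival_coef"] > 0]
hit = res.set_index("probe_id").loc[planted]
print(f"screen flags {int(res['significant'].sum())} of {len(res)} probes; "
      f"{int(hit['significant'].sum())}/5 planted prognostic probes found "
      f"(mean univariate log-HR estimate {hit['hazard_coef'].mean():.2f}; "
      f"one-probe-at-a-time fits attenuate the planted 2.0 when five "
      f"prognostic probes act jointly)")

pn = call_dmps(bm, sheet, "P")
cn = call_dmps(bm, sheet, "C")
means = stage_mean_betas(bm, sheet)
calls = classify_eight_types(pn, cn, means["C"] - means["P"])
frac = fraction_survival_associated(res, calls)
for _, row in frac.iterrows():
    if row["n_probes"]:
        print(f"  type {int(row['type'])}: {int(row['n_significant']):2d}/"
              f"{int(row['n_probes']):3d} significant ({100 * row['fraction']:.1f}%)")
print("Trajectory types carry no planted survival signal, so every type's "
      "fraction stays near the 5% false-positive floor.")
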