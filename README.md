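# herdsim

Stochastic, individual-animal simulation of the dairy-cow life cycle —
birth, growth, estrus-detection/AI breeding, pregnancy and its losses,
calving, lactation, and culling — on a daily time step, plus least-cost
ration formulation by linear programming. It is written for livestock
systems modellers and animal-science researchers who need a reproducible
Monte-Carlo herd engine whose every event is parameterized and audited.

## The model

Each animal is an agent advanced one day at a time:

- **Growth.** Body weight is linear in age, `W(a) = W0 + ADG·a` capped at a
  mature weight; defaults `W0 = 40.8 kg`, `ADG = 0.9 kg/d` (Holstein).
- **Sex at birth.** Bernoulli with the semen type's female probability
  (0.90 for sexed semen). Male calves are sold at birth.
- **Puberty and cycling.** The first-ovulation clock starts at 400 d of
  age; the delay to first ovulation is lognormal with arithmetic mean 19 d
  and SD 11 d (moment-matched). Estrus cycles are `N(21, 4)` days; heat is
  detected on the ovulation day with probability 0.60.
- **Conception.** Service `s` conceives with probability
  `0.339 − 0.026·(s − 1)`, clipped below at a floor.
- **Pregnancy.** Diagnoses on gestation days 32, 91 and 200. Between
  consecutive diagnoses a latent loss occurs with daily hazard 0.0096 then
  0.0017; a loss is revealed only at the next diagnosis, when the cow
  resumes cycling. Gestation length is `N(278, 6)` days.
- **Lactation.** From calving, milk follows Wood's curve
  `y(t) = a·t^b·e^(−ct)` or the MilkBot model
  `M(t) = a·(1 − e^((c−t)/b)/2)·e^(−dt)` with (breed, parity) parameters;
  pregnant cows are dried off 60 d before expected calving.
- **Culling.** Open heifers exit at 650 d of age; open cows past 300 days
  in milk. Independently, each female is screened once at birth for six
  lifetime culling reasons (lameness, injury, mastitis, other diseases,
  udder problems, unknown) by comparing `U(0,1)` draws with per-reason
  probabilities; an assigned cull's age is drawn by inverse transform of
  an empirical culling-age CDF. The earliest trigger wins.

Reproducibility is structural: every animal owns a PCG64 substream keyed
by (seed, replicate, animal id), so runs are bit-reproducible and adding
animals never perturbs existing trajectories.

The ration module solves `min Σ cost_f·x_f` over feed amounts subject to
nutrient minima/maxima, a dry-matter-intake window, and per-feed
inclusion/availability constraints (HiGHS via `scipy.optimize.linprog`).
Requirement vectors are assembled from a user-supplied coefficient table,
linear in body weight and milk yield.

## Worked example

```python
import herdsim as hs

cfg = hs.default_config()                     # Holstein, sexed semen, estrus-detection/AI
res = hs.run_simulation(
    cfg, n_days=3000,
    initial_herd_spec=hs.InitialHerdSpec(n_newborn_females=10),
    seed=42,
)[0]
events, summary = res.events, res.summary
print("events logged:", len(events))
print("calvings:", (events.event == "CALVING").sum())
print("exit reasons:", events[events.event == "EXIT"]
      .payload.map(lambda p: p["reason"]).value_counts().to_dict())
print("final herd size:", int(summary.herd_size.iloc[-1]))
print("peak daily milk (kg):", round(summary.milk_kg.max(), 1))
```

prints

```
events logged: 635
calvings: 11
exit reasons: {'reproductive_failure': 17, 'male_sold': 3}
final herd size: 1
peak daily milk (kg): 140.0
```

Ten newborn females and their descendants produce 11 calvings over
~8 years; most females eventually exit as reproductive failures because,
under the default hazards, only about 47% of conceptions survive both
loss windows to term ("0.9904^59 · 0.9983^109"), so open cows frequently
reach the 300-DIM cull threshold. Without replacement purchases the herd
declines — the engine conserves the herd ledger (size = yesterday +
entries − exits) every day, which the summary table exposes.

The same engine drives single-animal what-ifs, e.g. a heifer never seen
in heat exits at exactly 650 d of age, and a cow that never conceives is
never observed in the herd past 300 days in milk.

The CLI mirrors the library:

```bash
herdsim simulate --days 3000 --newborn-females 10 --seed 42 --out results/
herdsim formulate-ration --feeds feeds.csv --requirements reqs.csv \
    --milk-yield 30 --body-weight 650 --out diet.csv
```

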