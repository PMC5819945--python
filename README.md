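# hiberphys

Analysis pipeline for hibernation ecophysiology: classify activity and
torpor from temperature-logger traces, fit two-segment growth and torpor
trajectories, and compute respirometry, energy-intake and doubly-labelled
water (DLW) energetics.

Studies of small heterotherms (dormice, hamsters, ground squirrels)
routinely monitor juveniles through the pre-hibernation season with a nest
logger (T_nest, 1-min), an ambient logger (T_a, 30-min), weekly
mass/length/food measurements, open-flow respirometry, and DLW sampling,
then follow winter hibernation with an implanted body-temperature logger
(T_b, 0.5 °C resolution). `hiberphys` turns those streams into the
quantities such studies report:

* **Activity time** — the smoothed difference D = T_nest − T_a is
  thresholded at its mean (100-sample moving average), with a ±0.5 °C
  refinement for short nest exits and returns; samples below threshold are
  activity outside the nest.
* **Torpor bouts** — slow, deep declines of D inside in-nest episodes
  (a vacated nest cools within minutes; a torpid occupant's nest cools over
  hours), summarized per week as torpor frequency, total and mean torpor
  duration.
* **Hibernation patterns** — torpid means T_b < 30 °C; bouts ≥ 24 h mark
  hibernation; outputs are hibernation duration, arousal frequency, mean
  inter-bout euthermy, mean bout duration and minimal T_b.
* **Trajectories** — continuous two-segment linear fits
  y = a + b·min(t, τ) (or flat-then-change), with the breakpoint τ chosen
  by exhaustive profile-RSS search: slope, plateau and time of plateau /
  starting time per animal.
* **Energetics** — VO₂ = FD·(FiO₂−FeO₂)/(1−FiO₂·(1−RQ)) with STPD flow
  correction and ADMR/MR-day/MR-night summaries; gross energy intake from
  proximate composition (23.3/39.6/17.5 kJ/g for protein/fat/NFE); DLW
  body composition (FFM = TBW/0.732, FM by difference) and the two-pool
  TEE and water-turnover equations.

A synthetic-data generator (`hiberphys.simulate`) produces all six input
streams with programmed ground truth, so the entire pipeline is testable
without any animal data.

## Worked example

Run the bundled demo scenario (an 8-week late-born-style season: nightly
activity, daily torpor ramping up in weeks 6–8, growth to a week-5
plateau, 48-h respirometry, 6-day DLW):

```bash
hiberphys run --seed 1 --out demo_run
hiberphys energetics --seed 1 --out demo_run
```

which prints

```
wrote 17 outputs to demo_run
ADMR 135.1 ml O2/h (day 90.2, night 179.9); TEE 40.7 kJ/d
```

and writes, among other tables, the trajectory fits
(`demo_run/report_fits.csv`):

```
animal_id,response,mode,slope,plateau,breakpoint,slope_se,rss,n
demo,body_mass,rise_then_plateau,8.92904,84.0263,5.0,0.487246,49.8559,9
demo,body_length,rise_then_plateau,0.377533,12.3682,5.0,0.00920235,0.0177835,9
demo,total_torpor_duration,flat_then_change,897.722,,3.5,85.9216,575837.0,8
```

Reading the body-mass row: this animal gained 8.9 g/week until week 5.0,
then plateaued at 84 g (the generator's programmed values are 9.4 g/week,
week 5, plateau 85.8 g — the fit recovers them within the 2-g weekly
measurement noise). The energetics line says the animal consumed 135 ml
O₂/h averaged over the day, twice as much by night as by day (it is
nocturnal), and its DLW-derived total energy expenditure was 40.7 kJ/day.
`demo_run/weekly.csv` holds the per-week torpor frequency, torpor
durations and activity time; `demo_run/hibernation.json` the winter
metrics; `demo_run/manifest.json` a SHA-256 checksum per output, so a
rerun with the same seed is verifiably byte-identical.

Every stage is also a library call (`classify_activity`,
`detect_torpor_bouts`, `fit_segmented`, `dlw_energy_budget`, ...) and a
separate subcommand (`simulate`, `classify`, `fit`, `energetics`,
`report`) operating on plain CSVs, so stages can be scripted
independently.

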