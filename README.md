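# frailtykit

Composite frailty assessment for longitudinal mouse cohorts.

Preclinical aging studies assess frailty with two complementary
instruments: a **deficit-accumulation frailty index** (FI — the sum of
27 visually scored health-deficit items, each 0 / 0.5 / 1, divided
by 27) and a Fried-style **physical frailty phenotype** built from
performance tests. `frailtykit` implements a combined classifier for
two-timepoint (baseline/endpoint), two-sex, three-group
(adult reference, old vehicle-treated, old treated) intervention
cohorts, for researchers who need the scoring, thresholding and
transition bookkeeping to be reproducible and testable.

## The assessment

Six criteria are computed per animal and timepoint:

| field | criterion | reduction of raw data | units |
|-------|-----------|-----------------------|-------|
| `ws`  | walking speed | best of 3 rotarod trials | rpm |
| `gft` | grip strength | drop highest + lowest of 5 trials, mean of remaining 3 | g |
| `td`  | endurance | treadmill distance to exhaustion | m |
| `vrw` | voluntary activity | mean of 4 daily wheel distances | km/day |
| `fi`  | frailty index | Σ item scores / 27 | [0, 1] |
| `dbw` | weight change | mean weekly % change in body weight | %/week |

For each criterion *c* and sex *s*, a cutoff is the 20th percentile
(linear interpolation between order statistics at index (n−1)·p) of the
**old groups at baseline**, after orienting values so that lower always
means frailer (the FI is negated). An animal is *positive* for a marker
when its oriented value falls strictly below the sex-matched cutoff;
with tally *k* over the six markers:

- *k* ≥ 3 → **frail**, *k* = 2 → **prefrail**, *k* ≤ 1 → **robust**.

Classification is applied to all groups at both timepoints with the
baseline-derived cutoffs, and baseline→endpoint category transitions
are counted per (sex, group), with animals lost before endpoint tracked
separately. A calibrated synthetic cohort generator (latent-vigor
factor model, log-normal trial noise, geometric body-weight drift,
Bernoulli mortality) stands in for animal data; see
[docs/methods.md](docs/methods.md).

## Worked example

```bash
frailtykit all --seed 1 --outdir out
```

simulates the default cohort (15 adults, 19 old-vehicle, 14 old-treated
per sex), writes its raw tables under `out/cohort/`, and produces
`panel.csv`, `cutoffs.csv`, `classifications.csv`, `transitions.csv`,
`summary.csv`, `survival.csv` plus a seed/config manifest. Selected
output from that exact run:

```text
$ cat out/cutoffs.csv          # female rows, values rounded here
sex,criterion,cutoff,orientation,n_used
female,ws,24.27,lower_is_frailer,33
female,gft,202.20,lower_is_frailer,33
female,td,53.13,lower_is_frailer,33
female,vrw,2.73,lower_is_frailer,33
female,fi,-0.296,higher_is_frailer,33
female,dbw,-0.628,lower_is_frailer,33
```

Each row is the 20th percentile of the 33 old females at baseline on
the oriented scale — e.g. a female is positive for the endurance marker
if she runs < 53.1 m, and positive for the FI marker if her index
exceeds 0.296 (the stored cutoff is on the negated scale).

```text
$ grep 'female,old_vehicle' out/transitions.csv
from,to,count:  robust→robust 2, robust→prefrail 5, robust→frail 4,
                prefrail→frail 3, frail→frail 3, robust→lost 1,
                prefrail→lost 1   (19 baseline animals conserved)

$ cat out/survival.csv
female,old_vehicle: 89.5% survival (17/19); all other cells 100%
```

Untreated old females decline (9 of 11 surviving baseline-robust
animals leave the robust category) while adult animals classify 100%
robust at both timepoints — the pattern the classifier is designed to
resolve.

Every stage is also callable from Python (`generate_cohort`,
`build_criterion_panel`, `derive_cutoffs`, `classify_cohort`,
`track_transitions`, `run_pipeline`), and `simulate` / `score` /
`classify` / `report` run stages individually.

## Input tables

Cohorts are exchanged as four UTF-8 CSV files with header rows; missing
measurements are absent rows.

`animals.csv` — one row per animal:

```csv
animal_id,sex,group,alive_at_endpoint
f_ad_001,female,adult,True
```

`trials.csv` — one row per trial (`walking_speed`×3, `grip_strength`×5,
`endurance`×1, `activity`×4 per animal/timepoint):

```csv
animal_id,timepoint,test,trial_index,value
f_ad_001,baseline,activity,1,7.5154
```

`bodyweight.csv` — weekly weights, study weeks 1–13:

```csv
animal_id,week,weight_g
f_ad_001,1,22.8246
```

`deficits.csv` — 27 instrument items per animal/timepoint, scores in
{0, 0.5, 1}:

```csv
animal_id,timepoint,item,score
f_ad_001,baseline,alopecia,0.5
```

Validation is total: wrong trial counts, scores off the 0.5 grid,
duplicate ids, non-increasing weeks or unknown categories raise errors
naming the animal and field; nothing loads partially.

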