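# Methods

## The composite frailty assessment

Two instruments are combined into a single six-criterion classifier.

**Deficit-accumulation frailty index.** The index follows the
deficit-accumulation principle: health deficits, individually
uninformative, predict vulnerability when summed. The instrument is a
31-item visual deficit scale reduced to 27 items by excluding the four
instrumented measures (forelimb grip strength, tail stiffening, body
temperature, body weight) that enter the classifier through their own
criteria. Each item scores 0 (absent), 0.5 (mild) or 1 (severe); the
index is the sum divided by 27, so FI ∈ [0, 1] on a grid of 1/54. The
published description of the instrument names only example items, so
the default item list in `frailtykit.instrument` is a reconstruction of
the standard mouse clinical instrument, not a verbatim copy; any
27-name list can be substituted and every validator honours it.

**Physical frailty phenotype.** Four performance abilities are reduced
from raw trials exactly as administered at the bench: walking speed is
the best of three rotarod maxima (rpm); strength is the mean of five
grip trials after eliminating the single highest and single lowest
(with tied extremes, exactly one occurrence of each is removed);
endurance is the single treadmill distance to exhaustion (m); activity
is the mean of four daily wheel distances (km/day), the acclimation day
having been excluded upstream. The sixth criterion, ΔBW, is the mean of
week-over-week percent body-weight changes,
mean_i 100·(w_{i+1} − w_i)/w_i, with the earlier week as denominator.

**ΔBW windows.** A weight-loss value is needed at both assessments, but
weight change is naturally defined over the whole study. The package
computes baseline ΔBW over study weeks 1–4 (the data available when
baseline testing closes) and endpoint ΔBW over weeks 1–13. The baseline
window is a design choice of this package; with the default generator's
drift structure the two windows have the same expectation, so the
choice affects variance (three weekly steps instead of twelve), not
calibration.

## Cutoffs and classification

Cutoffs are derived per sex from the pooled old groups at baseline —
treatment assignment is randomized after baseline testing, so
vehicle- and treatment-assigned old animals are exchangeable there.
Values are first oriented so lower = frailer (FI is negated; a more
negative ΔBW already means faster loss), then the 20th percentile is
computed by linear interpolation between order statistics at index
(n−1)·p — numpy's default `linear` method, pinned for bit
reproducibility. An animal is marker-positive iff its oriented value is
*strictly* below the cutoff (a literal reading of "fell below"); on a
tie-free reference sample of 100 distinct values exactly 20 animals are
positive, and the general count matches a sort-and-count oracle for
5 ≤ n ≤ 200 (asserted in the test suite). Tally ≥ 3 → frail, = 2 →
prefrail, ≤ 1 → robust.

Two deliberate policies keep every surviving animal classifiable: a
missing criterion counts as not-positive (with a prominent warning),
and classification never excludes an animal for incomplete data.
Animals dead before endpoint are classified at baseline only and appear
in the transition matrix's `lost` column, so matrix cells plus losses
always conserve the baseline count.

An alternative reference population — all groups at baseline, the
"frailest quintile of the whole cohort" variant — is exposed as
`cutoff_reference="all_animals"`; sexes are processed independently
under both rules. The old-baseline rule is the primary one.

## Synthetic cohort generator

The generator emulates the study conditions the classifier targets:
two sexes × three groups (adult, old_vehicle, old_pdx) × two
timepoints, defaults of 15/19/14 animals per sex and group, thirteen
weekly body weights, and mortality confined to the old vehicle groups.

Structure, per animal:

- a latent standard-normal **vigor** factor loads (λ = 0.6) on the
  log-scale deviation of every performance test and negatively on the
  FI, so criteria co-decline and multi-marker positives arise the way
  they do in real cohorts; per-test residuals persist across
  timepoints, giving within-animal longitudinal correlation;
- performance values are **log-normal** (positive, right-skewed) with
  mean fixed at the configured group mean: animal-level CVs
  (ws 0.10, gft 0.10, td 0.25, vrw 0.30) set between-animal spread, and
  trial-level CVs (0.08, 0.06, 0.10, 0.15) wrap each trial around the
  animal's latent ability so the best-of-3 / trimmed-mean-of-5 / mean-of-4
  reductions are genuinely exercised;
- the **FI target** is log-normal (CV 0.30) around the group mean,
  clipped to [0, 1] and realized as item scores on the 0.5-point grid,
  mild deficits first (a moderately frail mouse accumulates many mild
  deficits before severe ones), deficit items drawn at random per
  assessment;
- **body weight** is a geometric random walk: group-specific start
  weights (adults 24/30 g f/m, old 30/38 g), weekly multiplicative
  drift (+0.25 %/week adult, −0.4 %/week old) and step noise
  (CV 0.008);
- **mortality** is Bernoulli between baseline and endpoint
  (old-vehicle females 0.10, males 0.05, zero elsewhere, matching the
  modelled 90%/95%/100% survival pattern), with the death week uniform
  on weeks 5–12; deaths are sampled independently of vigor, so endpoint
  group means carry no survivor bias.

**Calibration.** Default group means encode the reported values of the
modelled study: baseline treadmill distances 70/75 m (old females/males)
versus 116/126 m (adults); old-female strength 12.5% below adult at
baseline and 16% at endpoint; old-male strength 28% below adult at
endpoint; old activity two-thirds of adult at both timepoints; old FI
well above adult FI, with treated males starting lower than vehicle
males; walking speed identical across groups at baseline (no age effect
was reported for that test). Quantities the study does not print —
absolute grip forces (250/300 g adult f/m), absolute activity
(6.0/5.4 km/day adult), rotarod level (25 rpm), FI levels
(0.08 adult / 0.25 old), all CVs and the factor loading — are free
parameters chosen once as realistic for aged C57BL/6 mice and
documented here; the reported dispersions (SEM per figure) were not
extracted.

**What the generator does not emulate:** batch and rater effects,
learning/habituation across repeated testing, floor effects in very
frail animals (a mouse that cannot run at all), seasonal or circadian
structure, informative dropout (death correlated with frailty), and
treatment-by-vigor interactions. Passing tests therefore demonstrate
that the pipeline's rules are implemented correctly under the intended
statistical structure, not that the generator reproduces any individual
real cohort.

**Noise-free limit.** With all CVs at zero every performance criterion
equals its configured mean exactly and ΔBW equals the configured drift;
the FI equals its mean to within one grid step (0.5/27 ≈ 0.019) because
item scores are quantized. The test suite asserts exactly that.

## Numerical and design choices

- Quantile estimator pinned to linear interpolation at (n−1)·p; ties at
  the cutoff are not positive (strict inequality).
- Cutoff derivation requires ≥ 5 non-missing reference animals per
  (sex, criterion) and errors otherwise, naming both.
- CSV round-trips are exact: canonical row order, `\n` terminators,
  full-precision float repr on write and round-trip float parsing on
  read; re-running any stage on identical inputs is byte-identical (no
  timestamps or locale in artifacts; the run manifest records the seed
  and a config hash instead).
- Group summaries report mean and SEM = sd/√n (NaN for singleton cells,
  which are logged); endpoint rows carry the group-level delta
  (endpoint − baseline mean) and a two-point trapezoidal AUC over the
  assessment weeks (weeks 3→12 for performance tests, 4→13 for FI and
  ΔBW).
- Problem sizes: the calibration checks and the acceptance script use
  500 animals per (sex, group) — large enough that Monte-Carlo standard
  errors on group means are well under the effects being recovered,
  small enough to run in seconds.

## Known limitations

- The 27-item list is a reconstruction; studies using a different item
  subset must supply their own list (supported, untested against any
  published instrument text).
- Whether "maximal strength" in the modelled protocol is forelimb-only
  or combined fore+hindlimb is ambiguous in the source description; the
  panel stores a single grip value and the generator treats it as the
  combined measure.
- Baseline ΔBW over weeks 1–4 rests on three weekly intervals and is
  accordingly noisy; with few reference animals the dbw cutoff is the
  least stable of the six.
- Transition *rates* are reported as plain fractions; no inferential
  statistics (ANOVA, log-rank) are included by design.
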