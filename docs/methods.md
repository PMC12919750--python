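# Methods

This note documents the models, rules and numerical choices behind
`nutrikiosk`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Energy model

Basal metabolic rate uses the revised (1984, Roza–Shizgal) Harris–Benedict
coefficients; the original 1919 coefficients are available via
`variant="original"`. "Modified Harris-Benedict" is ambiguous in common
usage; the 1984 revision is the most widespread reading and the default
here. Total daily energy expenditure multiplies BMR by the conventional
activity factors 1.2 / 1.375 / 1.55 / 1.725 / 1.9 and is then **clamped** to
[1200, 2800] kcal/day rather than rejected: the triage model and the planner
are designed and trained inside that window, and the `clamped` flag lets a
caller warn the user. Rounding is fixed (BMI 2 d.p., energy 2 d.p., macro
grams 1 d.p.) so outputs are reproducible to the digit. Macro grams use the
Atwater densities 4/4/9 kcal/g; rounding each gram value to 0.1 g bounds the
energy-reconversion error by ~1.5 kcal/day.

The equations target non-pregnant adults; no pediatric or pregnancy variants
are included, and no hypocaloric adjustment is applied for high BMI (the
kiosk reports the maintenance requirement).

## Food database

The shipped 46-food table is an **illustrative, synthetic** regional fixture
in the style of Mexican food-composition references, not a copy of any
published table; serving sizes follow food-exchange conventions. Foods carry
one of eight groups (cereals/tubers, legumes, vegetables, fruits, animal
protein, dairy, fats/oils, sugars/sweets — the national plate-model
taxonomy). Every ingested record must satisfy the Atwater consistency check
within ±20%, a band wide enough to absorb fiber and rounding effects in real
composition tables. Glycemic index is optional; foods without GI sort after
all foods with GI in low-GI-priority orderings. Equivalents are defined by
the standard exchange convention: same group, energy per serving within a
10% default tolerance.

## Synthetic cohort

Each record carries 15 variables: age, sex, height, weight, BMI, diabetes
type, glycemic control, activity level, energy need, the three macro shares,
predominant food group, dietary adherence, and food preference. Strata
follow diabetes type with weights 0.80 / 0.08 / 0.12
(type 2 / type 1 / prediabetes) — plausible placeholders for the national
adult diabetes mix, fully configurable, not survey microdata. Heights are
normal by sex (1.58 ± 0.06 m women, 1.70 ± 0.07 m men); BMI is drawn
directly (N(29, 4.8) for type 2, lower for type 1) and weight derived, which
makes the BMI filter interpretable; energy need is computed through the
energy module, so it is automatically consistent with the anthropometrics
and clamped to [1200, 2800]. Macro shares are drawn uniformly inside the
AMDR windows with protein as the remainder (the sampling region guarantees
protein ∈ [10, 35]).

Glycemic control drives correlated behaviour: poorly controlled records
(32%) draw low adherence with probability 0.50 (vs 0.28) and a sugar- or
fat-predominant diet with probability 0.35 (vs 0.06). This correlation is
clinically motivated and is what makes multi-violation profiles — the
"requires consultation" class — reachable.

The triage label is a deterministic violation-point score: poor control 2,
type 1/prediabetes with CHO > 55% 1, low adherence 1, BMI outside
[18.5, 30] 1, sugar/fat-predominant diet 2; totals 0–1 / 2–3 / ≥4 map to
ADEQUATE / MINOR_ADJUSTMENT / REQUIRES_CONSULTATION. The sampling
distributions above were calibrated once so the rule yields ≈ (55, 30, 15)%
— the reference class ratio — and then frozen; across seeds the observed
proportions stay within ~1.5 points. Filters remove BMI outside the
inclusive [15, 40] band and any macro inconsistency, with per-stratum
resampling to the exact target count (a bounded retry budget turns an
infeasible stratum into an explicit error).

Label noise replaces each label, with probability 0.12 by default, by one of
the other two classes uniformly. The rate is a calibration device, not
ground truth: a model that learns the rule perfectly then agrees with noisy
test labels on about (1 − rate) of records, which is the published accuracy
regime. Note the marginals shift under uniform flipping (≈ (51, 31, 18)%),
so class-proportion checks refer to the rule labels.

What the generator does **not** emulate: measurement error in
anthropometrics, correlations between age/activity/BMI, longitudinal
structure, or real survey weighting. Passing tests therefore demonstrate the
pipeline's correctness and calibration under these stylized conditions, not
clinical validity on real patients.

## Triage classifier

The network is exactly the kiosk architecture: input 15, three hidden layers
of 64 (dense → batch-norm → ReLU → dropout 0.3), softmax output of 3;
categorical cross-entropy with L2 penalty 1e-4; Adam at learning rate 0.001,
batch 32; early stopping on validation loss with patience 10, ≤ 100 epochs,
best-loss weights restored. It is implemented directly in numpy: the model
is small enough that a framework adds nothing, and a self-contained
implementation makes training bit-reproducible from a single seeded
generator (initialization, shuffling and dropout masks included).

Two training details are the package's own choices:

- **Reduce-LR-on-plateau**: the learning rate halves after 3 epochs without
  validation-loss improvement (floor 2e-5). The labeling rule has sharp
  decision thresholds (BMI 18.5/30, CHO 55%); without late-stage LR decay
  the network underfits them and noiseless validation accuracy saturates
  near 0.97 instead of ≥ 0.98.
- **Encoding**: continuous variables are standardized with training-set
  statistics (zero-SD columns fall back to a unit divisor); categorical
  variables map to fixed ordinal scores in [0, 1], keeping the input at
  exactly 15 (no one-hot expansion). Scores are *risk-spaced* rather than
  equally spaced — e.g. food groups place the staples at 0–0.3 and
  fats/sweets at 0.8/1.0, glycemic control is good 0 / fair 0.4 / poor 1 —
  mirroring the clinical distance between categories. An unseen category at
  inference raises an error naming the variable.

Prediction is argmax with ties broken toward the more conservative class
(consultation > adjustment > adequate): for a health device the safe failure
mode is over-referral. The fixed-rule baseline deliberately uses only
glycemic control and BMI — the non-personalized module the AI engine is
compared against.

Under the default conditions (n = 10,000, noise 0.12) test accuracy lands in
the mid-80s (the theoretical ceiling against noisy labels is ≈ 0.88 × clean
accuracy); on noiseless cohorts (n = 5,000) best-epoch validation accuracy
is ≈ 0.97–0.98, varying by up to a point with the cohort and
initialization seeds. Determinism
holds per platform/numpy build; across BLAS builds, bit-level equality of
long trainings is not guaranteed.

## Meal-plan composer

Daily energy splits 25/10/30/10/25% over breakfast, two snacks, lunch and
dinner, rounded to whole kcal by largest remainder so slot targets sum
exactly. Each slot is filled greedily in a fixed candidate order —
diabetes-suitable first, then GI ascending (missing GI last), fiber
descending, food id — in half-serving increments (≤ 3 servings per food),
never exceeding the slot ceiling (target + 5%) or its carbohydrate cap
(60 g main meals, 25 g snacks), stopping once energy reaches target − 5%.
Before the fill, each main meal seeds one food from every essential group
assigned to it (fruit + cereal at breakfast; vegetable + legume-or-animal
protein + cereal at lunch; vegetable + cereal at dinner), which is what
guarantees day-level group coverage: a pure greedy pass would fill entire
slots with the lowest-GI vegetables.

Two bounded fallbacks keep the composer honest when constraints bind:
if the carbohydrate cap leaves a slot short of energy, the selected food
that spends the cap fastest is reduced by half a serving, barred from
further additions, and the fill resumes (at most one pass per food); if
that still fails **and** the candidate set has ≤ 10 foods, a deterministic
branch-and-bound over serving combinations (same order, same granularity)
finds a compliant combination whenever one exists. On realistic databases
the greedy path succeeds directly; the fallbacks exist so that on tiny
databases the composer's infeasibility flag is exact, which the test suite
verifies against an independent exhaustive search. Infeasibility is never
silent: the slot is returned flagged, with a reason (`cho_cap`,
`kcal_unreachable`, missing group).

The compliance audit checks daily energy within tolerance, per-slot CHO
caps, essential-group coverage across the day, and the realized macro shares
(computed from the Atwater energy of the composed foods) within the AMDR
windows widened by 5 percentage points — composed whole foods cannot hit an
exact prescription, so the audit allows that margin. Plans render to JSON
(stable key order, fixed rounding: byte-identical across runs) or text; a
consultation-labeled plan carries an explicit advisory naming food
categories to limit.

## Evaluation statistics

Percentages round half-up to one decimal — required so exact ratios such as
74/87 print as 85.1. Standard deviations are sample (n−1) SDs. Precision for
a class never predicted (tp + fp = 0) is reported as 0 with a warning flag
rather than NaN, keeping macro averages defined. The Wilson interval uses
the normal quantile from scipy; its endpoints snap to exactly 0/1 at k = 0
or k = n. SUS scores follow the standard rule (odd items response − 1, even
items 5 − response, × 2.5) and summaries carry the Sauro–Lewis curved grade
(≥ 84.1 is A+, the "excellent" band). The load harness launches each
concurrency level's requests in thread waves, records wall-clock latencies,
and reports mean/sample-SD plus best-effort CPU (process times over wall
time) and RSS-based memory readings; all of these are machine-dependent and
are reported, not asserted.

## Problem sizes in the shipped runs

The test suite trains two models (10,000-record noisy cohort; 5,000-record
noiseless cohort) shared across tests via session fixtures, and the
acceptance script repeats the same two runs from its own seed; each training
takes on the order of tens of seconds in numpy. The planner's
oracle-agreement checks sweep ≤ 8-food sub-databases of the shipped fixture
with an exhaustive-search oracle. These sizes keep a full run to a few
minutes while matching the study's stated conditions (the 10,000-record
cohort, the 80/20 split, the 1200–2800 kcal and AMDR windows).

## Known limitations

- The cohort is stylized (independent draws within strata, one correlation
  channel); real-data validity is out of scope.
- The labeling rule is the package's own auditable construction; the kiosk's
  human-expert reference standard is not recoverable.
- The food table is illustrative; micronutrients are not modeled.
- Recipes are stored and queried but the composer works at the food level.
- Load-harness timings, CPU and RAM depend entirely on the host.
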