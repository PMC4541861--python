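# Methods

This note records the model, its assumptions, the tunable parameters, what
the synthetic cohort does and does not emulate, and the design decisions
taken where more than one reasonable choice existed.  Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The decision-table model

The data structure is a rough-set *information system*: a universe *U* of
per-encounter records, condition attributes *C*, and one decision attribute
*d* (the diabetes type).  Records are grouped by patient (`PID`) and
ordered by a 1-based `EncounterID`, which is assumed chronological; input
files must either carry `EncounterID` or be pre-sorted per patient.
Missing cells use a dedicated `MISSING` sentinel rather than NaN so nominal
attributes can be missing too and `0` is never confused with absence.
A configurable alias map absorbs naming variants for the liver enzymes
(`SGPT`/`PT` → ALT, `SGOT`/`OT` → AST), which appear under different names
in different clinical listings.

## Missing-value protocol

Three deterministic tiers, applied per (patient, attribute):

1. **Dataset level.** An attribute missing in ≥ 20 % of all records is
   dropped (identifier and decision columns never are).
2. **Count rule.** At most two missing encounters for the patient: fill
   from the immediate previous observed encounter (or next, when no
   previous exists); when the two missing encounters are consecutive, the
   first takes the previous and the second the next observed value.  The
   count rule is checked *first*: a patient missing 2 of 4 encounters
   (50 %) still uses previous/next.
3. **Rate rule.** Missing in ≤ 20 % of the patient's encounters: fill with
   the patient's own mean (numeric) or most frequent value (nominal, ties
   broken by earliest encounter).  Above 20 %, fall back to the mean/mode
   over all patients of the same decision class.  Exactly 20 % is assigned
   to the patient-level rule, mirroring the explicit "≥ 20 %" asymmetry of
   the dataset-level drop rule in the opposite direction.

Observed cells are never altered; numeric fills are not rounded (only
interval membership matters downstream).  An attribute missing for an
entire class is an error — no deterministic fallback remains.

## Semantic discretization and gap closure

Each continuous attribute is mapped to ordered guideline intervals (WHO
BMI; JNC 7 SBP/DBP; ADA FBS/HbA1c; NCEP TC/TG/HDL/LDL; liver-enzyme
reference ranges; an age split at 30/50 with no external guideline).  The
printed guideline intervals occasionally leave real-valued gaps (BMI
"[18.5, 24.9]" then "[25, 30)"; ALT "[7, 56]" then "[57, ∞)") and an
unmapped left tail (HbA1c below 4).  Schemes are normalised by **gap
closure**: each interval extends half-open to the next cut-point and the
first interval extends to −∞, so every finite value maps to exactly one
interval.  Inclusivity at genuine cut-points is kept exactly as the
guidelines state it, per boundary (FBS is upper-inclusive at 99 and 126;
HbA1c upper-inclusive at 5.9/6.4/7.4; DBP's crisis interval is
lower-exclusive at 110).  Values far outside physiological range are still
mapped by the open-ended extreme intervals, with a warning.  Reference-range
interpretation ("3R") shares these scheme objects, so discretization and
interpretation can never disagree about a boundary.

## Reducts, core, LEM2

Decision-relative reducts are found by exhaustive bottom-up lattice search
with superset pruning; γ is monotone in the attribute set, so the minimal
full-quality subsets are exactly the reducts.  The search is capped at 20
condition attributes (the clinical table has 13); the positive-region size
is computed vectorised (mixed-radix row keys + occupancy counts), which
keeps the 2^13-subset search around a second.  The core is the exact
intersection of all reducts; rules are induced on the core by default
(flag for all attributes), and an empty core falls back to all attributes
with a warning.

LEM2 builds a local covering of each target region (a union of
indiscernibility blocks): grow a condition set by greedily adding the
attribute-value pair maximising overlap with the uncovered goal — ties
broken by smaller pair extent, then canonical attribute order, then
ascending value — until the block is inside the target; prune redundant
pairs; repeat until covered; drop condition sets subsumed by the union of
the rest.  **Limitation:** greedy local covering is not guaranteed to reach
the globally minimum number of rules; on small random tables it exceeds a
branch-and-bound optimum on the order of a few tables in a hundred.  What
it does guarantee — and what the suite asserts everywhere — is consistency
(certain rules match no foreign-class record), completeness (lower
approximations fully covered) and irredundancy (no droppable rule or
condition).

Approximate rules are induced from the boundary region only (not the full
upper approximation) and carry per-class support counts; rule significance
is 100 × support / |class|, rendered half-up to two decimals.

## Classification and validation

LERS-style voting with the reference parameter set: majority threshold
0.21 (the winner's share of total accrued support must exceed it, else
"None"), minimum similarity 0.50, partial matching enabled, rule support =
strength × similarity in the partial stage.  Approximate rules vote with
their per-class supports in both stages.  Score ties go to the larger
training prior — a deterministic choice that invents no asymmetry.

Cross-validation is stratified by class (largest-remainder quotas under
fold-capacity constraints), giving fold sizes that differ by at most one —
391 records at k = 10 yield one fold of 40 and nine of 39.  Per-fold
percent accuracy is exact (100 × correct/size); the average accuracy is the
unweighted mean of fold accuracies; the fold-error dispersion uses the
sample (n−1) standard deviation.  Balanced accuracy is computed from the
pooled confusion matrix with the minority class (T1DM) as positive;
unclassified ("None") predictions count as misses for the true class and
are never false positives, so TP+FN and TN+FP always sum to the class
totals.

## Synthetic cohort: what it emulates, and what it does not

The generator reproduces, exactly: 50 patients (20 T1DM / 30 T2DM), 391
encounters split 113:278, encounter counts in [2, 18] per patient (sampled
uniformly, then adjusted to hit the totals), one class and one gender per
patient with the 256:135 male:female encounter split (subset-sum
assignment), and per-attribute missing-cell counts at the published rates
(6/6/4/1/9/9/9/15/19/19 % for SBP/DBP/FBS/HbA1c/TC/TG/HDL/LDL/AST/ALT,
rounded to whole cells, missing completely at random).  FHx/SHx are
generated with 25 % missingness specifically to exercise the ≥ 20 % drop
rule.

Continuous marginals target the published mean/sd/min/max per attribute.
Two non-obvious choices:

- **Moment-matched truncation.** A truncated normal parameterised directly
  by the printed mean/sd is badly biased when the printed bounds are
  asymmetric (for TG the naive truncated mean is ≈ +22 above target).  The
  generator solves for the underlying (μ, σ) whose truncated moments equal
  the targets (multi-start least squares; heavily skewed attributes land in
  the near-exponential corner with μ far below the lower bound, which is
  numerically fine through the quantile transform).
- **Latent standardisation.** Values are produced through a Gaussian
  copula: latent z = patient effect (share 0.5) + AR(1) encounter process
  (coefficient 0.7), mapped through the truncated-normal quantile function.
  With only 50 patients the clustering makes the raw sample mean drift by
  multiples of the i.i.d. standard error, so the latent normals are
  re-standardised within each (attribute, class) group before the
  transform; correlation structure is unchanged (affine) and realised
  marginal moments track the targets.

Class signal is *injected*, not estimated from any real cohort: T1DM is
shifted younger (−20 y), leaner (−3.5 BMI) and higher in HbA1c (+1.2)
relative to T2DM, magnitudes chosen once for clinical plausibility.  Shifts
are mean-centred across classes and within-class variance is shrunk by the
induced between-class variance, so the overall marginals still match.

What the generator does **not** emulate: the true joint distribution of
any real cohort (only printed marginals and structural counts), visit
timing (encounter index is the only time axis), treatment effects, or
informative missingness.  Consequently, passing end-to-end tests
demonstrates that the pipeline recovers *injected* class structure above
the 71.1 % majority baseline — not that the specific published accuracy is
reproducible, which would require the private data.

One caveat worth stating plainly: encounter-level cross-validation places
encounters of the same patient in both training and test folds.  With the
default within-patient correlation this leaks patient identity and lifts
the no-signal control to ≈ 80 %; the no-signal control in the acceptance
run therefore also zeroes the patient effect and AR coefficient (i.i.d.
encounters), landing at ≈ 66 %, below the baseline.  Patient-level
validation splits would be the methodologically cleaner design for real
data.

## Trend analysis

Per observation series (one patient, one attribute, encounter index as x):
least-squares polynomial of order 3, capped at n−1 points; x is centred
before fitting to keep the cubic normal equations well conditioned, and
coefficients are reported in original coordinates.  R² = 1 − SS_res/SS_tot,
defined as 1 when both sums are zero (constant series fitted exactly).
Forecasts evaluate the polynomial at the next encounters (default horizon
3; no published horizon exists).  The "normal" overlay band per attribute
comes from the guideline interval whose label plays the normal role
(TC "desirable", LDL "optimal", HbA1c's 4–5.9 non-diabetic interval,
otherwise the literal "normal" row); one-sided intervals yield one-sided
bands.  Cubic extrapolation diverges quickly — forecasts more than a few
encounters out are decoration, not prognosis.

## Problem sizes used in tests and acceptance

Oracle-equivalence suites run the lattice reduct search against power-set
enumeration on 200 random tables (≤ 8 attributes, ≤ 30 records) and LEM2
against a brute-force minimum cover on 100 random tables (≤ 4 attributes,
≤ 12 records).  End-to-end checks use the default 391-encounter cohort with
10-fold cross-validation, plus the i.i.d. no-signal control cohort of the
same size.  The marginal-emulation property is checked across 8 seeds.
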