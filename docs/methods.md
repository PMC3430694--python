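# Methods

This note documents the models, algorithms and numerical choices behind
`voxeltune`, in the order the pipeline uses them.

## Artificial-grammar stimuli (`agstim`)

Stimuli are consonant–vowel syllables over the six plosives {b, d, g, p, t,
k} and vowels {e, i, o, u}. The vowel fixes the category: /e/, /i/ → A;
/o/, /u/ → B. A sequence of length 2n is grammatical iff it is n A-syllables
followed by n B-syllables and the consonant at position i is the
voiced/voiceless partner (b–p, d–t, g–k) of the consonant at mirror position
2n+1−i — centre embedding as bracket matching over a fixed involution. The
second judgement, count match, is true iff the sequence has equally many
/e/-final and /o/-final syllables. All study stimuli use n = 3.

Generator conventions:

* A-syllables draw voiced plosives {b, d, g} (with repetition), B-syllables
  are then forced by the mirror rule; this follows the grammar's canonical
  example (/be di ge ko tu pu/). The checkers themselves accept any
  consonant assignment that satisfies the pairing, so user-supplied stimuli
  with the opposite convention are judged correctly.
* Ungrammatical sequences keep the 3-A + 3-B block shape and differ from a
  grammatical one only by a rearrangement of the B consonants that leaves at
  least one mirrored pair broken (the printed violation pattern
  A1A2A3B3B1B2 is one such rearrangement). Consequently category structure
  alone never reveals the label. At n = 1 no such rearrangement exists and
  requesting an ungrammatical sequence raises.
* Vowels are the free degrees of freedom used to hit the requested
  count-match label; the assignment is drawn uniformly among all 2^(2n)
  assignments with that label (enumerated; n ≤ 8 enforced). This makes
  grammaticality and count match exactly independent across the generator's
  output when labels are requested in balance.

## Session design (`design`)

A session holds 4m trials (m = 48 by default) and m null events. Counts that
hold by construction: m trials per condition (CG, CC, EG, EC); m of each cue
symbol (square, diamond, triangle up, triangle down); 2m grammar and 2m
count tasks; 50/50 grammatical/ungrammatical within grammar-task trials and
50/50 match/mismatch within count-task trials (secondary labels are drawn
50/50 as well); the four task-to-task transition counts differ by at most
one; jitters {0, 500, 1000, 1500} ms are balanced within each condition.

The sampler is constructive, not rejection-based:

1. **Task sequence.** One of the two tasks is chosen (seeded) to carry the
   short self-transition count, giving the transition profile
   {m, m, m, m−1}; a sequence realising it starts and ends on that task and
   decomposes into alternating task blocks (m+1 blocks of the first task
   summing to 2m, m blocks of the other). Block sizes are drawn as uniform
   random compositions (stars and bars), which makes the task sequence
   uniform among all sequences with that transition profile.
2. **Cue kinds.** Non-initial positions fall into four classes by (task,
   repeat-of-previous?). Writing `a` for the number of episodic cues placed
   in one class, every other class's episodic count is forced by the
   constraints (m episodic cues per task; m repeat and m switch episodic
   cues — which is exactly what makes the episodic cues resolve to m EG and
   m EC trials). `a` is drawn with probability proportional to the number of
   concrete position assignments it admits, and positions within classes
   uniformly. The session-initial trial is forced contextual because an
   episodic cue has no predecessor to refer to.
3. **Timing.** Events are laid back to back: jitter → 1000 ms cue → six
   1000 ms syllables → 2000 ms response window → 500 ms feedback → 3000 ms
   fixation (12 500 ms plus jitter per event). Null events occupy
   trial-equivalent spans and are placed uniformly at random among the event
   slots. All onsets are integer milliseconds from session start; the
   scanner grid is derived at TR = 2 s. The GLM takes the *cue onset*
   (block onset + jitter) as the event onset.

m must be even (label splits); values not divisible by 4 spread the jitter
levels as evenly as possible.

## Synthetic data (`simulate`)

The generator emulates exactly the measurement model the analysis assumes —
deliberately, since its job is to let parameter recovery and calibration be
checked against known ground truth:

* **Voxels.** Each voxel has a 4-vector μ of condition means; a tuned
  voxel's preferred entry is elevated by `tuning_gain` (default 1.0, in the
  same arbitrary signal units as the noise), an untuned voxel is flat.
  Composition follows requested proportions under largest-remainder
  rounding.
* **Trials.** amplitude = baseline + μ[condition] + N(0, noise_sd²), i.i.d.
  across trials (default noise_sd 1.0).
* **BOLD.** Each trial contributes amplitude × canonical HRF at its cue
  onset. Impulses are placed on a 500 ms microtime grid (every legal onset
  is a multiple of 500 ms), convolved, and sampled at volume times 0, TR,
  2·TR, …; scanner noise is additive Gaussian (default sd 1.0), optionally
  AR(1) with innovation variance scaled to keep the marginal sd (default AR
  coefficient 0). The HRF is the double-gamma kernel (response gamma with
  shape 6, undershoot gamma with shape 16, both unit scale, undershoot ratio
  1:6, 32 s support) normalised to unit peak.
* **Behaviour.** Errors are Bernoulli per condition; RTs Gaussian truncated
  to (0, 2000] ms. Default rates derive from the additive (no-interaction)
  decomposition of the reported marginal means — errors CG 4.15 %, CC
  1.65 %, EG 6.85 %, EC 4.35 % (marginals: grammar 5.5 % vs count 3.0 %,
  episodic 5.6 % vs contextual 2.9 %); RT means 798 ms (grammar) and 812 ms
  (count) with no cue effect and a trial-level sd of 150 ms, a typical
  within-subject spread not reported in the source data. These are
  generator defaults, not fitted values.

What the generator does **not** emulate: spatial correlation or smoothness,
motion, physiological noise, slow drifts beyond what the high-pass removes,
learning or fatigue, and any dependence of the BOLD amplitude on accuracy.
Passing tests therefore certify the *procedure* — its selection logic,
cross-validation independence, calibration and recovery behaviour under the
assumed model — not robustness to realistic artefacts.

A beta-level shortcut (`simulate_betas`) draws run×condition betas directly
as μ + N(0, noise_sd/√8), the large-sample behaviour of the GLM path, and is
used where only the tuning stage is under study.

## Beta estimation (`glm`)

Per condition, the correct trials are randomly partitioned into 6 equal run
groups (8 × 48 at study scale); erroneous trials never enter condition
regressors, and when correct counts are not divisible by 6 the excess is
dropped at random (seeded) so runs stay equally sized. Two GLM variants are
implemented:

* **per-run** (default): one GLM per run partition — 4 condition regressors
  from that run's trials plus a *single* nuisance regressor holding every
  other event (other runs' trials, errors, dropped trials, null events).
  This is the closest reading of treating all not-assigned trials as one
  regressor of no interest. Its known cost: unassigned trials carry
  condition-specific amplitudes that one shared regressor cannot represent,
  so condition betas acquire a small projection bias even without noise.
  The bias is immaterial for tuning (it is shared across runs and removed
  by the per-voxel z-score up to noise), and the per-condition mean betas
  still correlate > 0.9 with the generating μ at default SNR.
* **single**: one GLM with a regressor per run×condition cell (24 at study
  scale) plus one nuisance regressor for errors/drops/nulls. This design
  spans the noiseless generating signal exactly, so it recovers amplitudes
  to numerical precision and is the variant used for exactness checks.

Both designs add discrete-cosine drift columns implementing the 128 s
high-pass (order ⌊2·T/128⌋, unit-norm DCT-II basis, constant term excluded)
and an intercept; regressors are built by the same microtime convolution
routine as the simulator, so simulation and analysis share one
discretisation. Fitting is ordinary least squares via QR; rank deficiency
raises an error naming the offending columns. Motion regressors are
accepted as extra columns but never simulated.

z-normalisation standardises each voxel across its n_runs × 4 cells to mean
0, sd 1 (population sd, ddof 0); it is idempotent, invariant to per-voxel
positive affine maps, and flags zero-spread voxels as excluded (NaN) rather
than dividing by zero. An alternative axis (per run×condition map across
voxels) is selectable but not the default, since the normalisation's purpose
is removing between-voxel mean-intensity differences.

## Voxel tuning (`tuning`)

For each analysis run a, classification uses the other k = 5 runs: the
preference is argmax over conditions of the across-run mean normalised beta;
an exact tie (measure-zero under continuous noise) marks the voxel untuned
for that fold, and any NaN beta excludes the voxel outright. Reliability
requires the preference to recur as the within-run argmax in ≥ ⌈k/2⌉ = 3
classification runs. Tuning curves come exclusively from run a. Per-fold
accounting (tuned over 4 conditions + untuned + excluded = n_voxels) is
asserted. Per-subject tuned counts are the *mean* over the 6 folds (keeping
the voxel-count scale; a sum variant is selectable), and mean curves average
over each fold's reliable voxels, then over folds with any.

**Null calibration.** Under exchangeable conditions the reliability event
is "the across-run-mean argmax is also the per-run argmax in ≥ 3 of 5
runs". Its probability is *not* the 4^5-pattern majority probability
P(some condition wins ≥ 3 runs) = 424/1024 ≈ 0.414: the across-run-mean
argmax coincides with the per-run majority only ~82 % of the time, giving a
true null rate ≈ 0.340 (≈ 0.085 per condition). The package therefore
provides both oracles: the exact pattern enumeration
(`null_reliability_enumeration`, an upper bound) and a direct Monte-Carlo
implementation of the actual event (`null_reliability_mc`), vectorised
independently of the pipeline code path. Calibration tests compare the
pipeline's empirical tuned fractions to the Monte-Carlo oracle within
99 % confidence bounds and assert the enumeration bound.

**Group statistics.** Tuning success for condition c is the paired t across
subjects of (mean analysis-run beta of c-tuned voxels at c) versus (those
voxels' mean beta over the other three conditions); subjects with no c-tuned
voxel in any fold are excluded with a warning and the degrees of freedom
shrink. Because selection never touches the analysis run, the test is
exactly calibrated under the null (verified at 1000 replicates).

## Group ANOVA (`stats`)

In a 2×2 within-subject design every effect has one numerator degree of
freedom, so each F equals the squared paired t on its within-subject
contrast (level means for the main effects, the double difference for the
interaction), with df (1, n−1) and identical two-tailed p; the ANOVA is
computed through that identity, cross-checked against a conventional
repeated-measures ANOVA implementation in the tests. Sphericity corrections
are moot with single-df effects. Zero-variance contrasts are flagged rather
than returned as NaN (t capped at ±10⁶), since near-ceiling accuracy data
make this case realistic. Pearson correlation (speed–accuracy check)
requires ≥ 3 points and non-zero spread.

## Pipeline and reproducibility

`RunConfig` defaults reproduce the study scale: 21 subjects, 48 trials per
condition, 48 nulls, 6 runs, one synthetic ROI of 585 voxels whose default
composition (35 % EG, 20 % CG, 10 % CC, 10 % EC, 25 % untuned) mirrors the
qualitative tuning profile the analysis is meant to recover — chosen once as
a realistic regime, with gain and both noise sds at 1.0. One master seed
spawns named substreams per subject (design, behaviour, population, scanner
noise, run assignment), so any stage can be re-run in isolation and two runs
with the same seed produce byte-identical bundles (fixed float formatting in
all TSV/JSON output; the config hash is embedded in the outputs). Reduced
problem sizes (fewer subjects/voxels/trials per condition) preserve every
count invariant and are what the test suite and the acceptance script use
for the heavier Monte-Carlo checks, at sizes chosen to keep the whole suite
in the low minutes on a single core.

## Known limitations

* The reliability threshold ⌈k/2⌉ assumes the "at least half" rule; with
  even k this is exactly half, which is the only integer reading but makes
  the filter slightly more permissive than with odd k.
* The per-run GLM variant's nuisance bias (above) is inherent to the
  single-nuisance design, not a bug; use the single variant when unbiased
  amplitude estimates matter.
* Tuned-voxel counts from a finite null rate are non-zero by construction;
  analyses of count *differences* between conditions are unaffected (the
  null inflation is condition-symmetric), but absolute counts should be
  read against the null rate the oracles provide.
* The behaviour and BOLD generators share no trial-level coupling: errors
  do not modulate amplitudes, they only re-route trials into the nuisance
  regressor, which is the only path the original analysis specifies.
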