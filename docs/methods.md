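# Methods

This note documents the models and procedures implemented in `ratcat`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Stimulus space and category tasks

Stimuli are gratings with spatial frequency f (cycles per visual degree)
and orientation θ (radians), mapped to a common 0–100 scale by

    x = f / 0.0097 − 26.10        y = θ · 180 / π .

The raw ranges 0.2532–1.2232 cpd and 0–1.75 rad map to ≈0–100 on both axes
(the orientation bound maps to 100.27; the normalized space is treated as
the authoritative coordinate system and the raw bound as advisory).

The base task places category A at (30, 50) and B at (70, 50), σ = 2.5
along the relevant axis and 20 along the orthogonal axis.  The other three
tasks are rigid rotations in 45° steps.  The rotation pivot is the centre
of the space, (50, 50): the pivot is a free choice, and centre rotation is
the only one that keeps all four tasks inside [0,100]².  Rotation preserves
the between-mean distance (40 units) and both covariance eigenvalues, so the
tasks differ only in how the distributions align with the stimulus axes.

Sampling draws the category as an independent fair coin per trial (an
exactly balanced "block" scheme is available) and rejection-resamples
coordinates outside [0,100]², so every stimulus is displayable; the
probability mass lost is < 1% per draw at these σ.  Testing distributions
widen the relevant-axis σ to 10 for all four tasks — for 2D tasks "the
relevant axis" means the rotated axis perpendicular to the elongated
distributions.  Testing exemplars are typed by their signed relevant-axis
coordinate u relative to their category's training mean (positive toward
the boundary): |u| ≤ 5 (two training σ) is Trained, u > 5 Proximal,
u < −5 Distal.

## The SUSTAIN network

The continuous-dimension supervised formulation is used throughout (model
coordinates are the normalized space divided by 100, so e^{−λµ} is
non-degenerate at λ ≈ 1):

* activation: H_j = Σ_i λ_i^r e^{−λ_i µ_ij} / Σ_i λ_i^r with city-block
  component distances µ_ij;
* competition: the most active cluster wins (ties to the lowest index) and
  projects out_w = H_w^β / Σ_k H_k^β · H_w; all other clusters are silenced;
* decision: category-unit activations C_z = w_{w,z}·out_w feed a softmax
  with gain d_dec; the behavioural choice is sampled from it;
* updates: the winner's position moves toward the stimulus (rate η), the
  attention weights follow the receptive-field gradient
  Δλ_i = η_λ e^{−λ_i µ_i}(1 − λ_i µ_i) — fixed point at λµ = 1, floored at
  zero — and the winner's association weights follow a humble-teacher
  delta rule (no error on overshoot), also at rate η;
* recruitment: a *misclassified* stimulus (the category unit with the
  larger activation disagrees with feedback) whose winning activation
  exceeds τ recruits a new cluster at the stimulus with zero weights; the
  new cluster becomes the winner for that trial's update.  The trial that
  seeds the very first cluster skips the recruitment check.

Two deliberate design choices need flagging.  First, the attention learning
rate η_λ is a separate parameter from η, so the feature-tuning mechanism
can be manipulated (and fitted) independently; setting η_λ = η recovers the
classic single-rate form.  Second, the recruitment error signal defaults to
the model's classification (argmax of the category units), not the sampled
behavioural choice (`recruit_on="choice"` selects the sampled-choice
variant).  With the sampled choice, behavioural lapses at the accuracy
plateau (~15–20% of trials) recruit clusters indefinitely and the cluster
count grows without bound on 2D tasks; with the classification signal,
recruitment stops organically once every stimulus region is classified
correctly, which is what produces the prototype-vs-exemplar contrast
between 1D and 2D tasks (two clusters vs several per category).

### Default (control) parameters

r = 6, β = 4, d_dec = 4.5, η = 0.03, η_λ = 0.0125, τ = 0.5.  These were
calibrated once, by simulation, to jointly reproduce the study conditions
the package emulates: learning curves rising from near chance to ≥ 0.85;
1D and 2D control accuracy within 0.1 of each other at the end of training;
a modal count of two clusters on 1D tasks and ≥ 3 clusters per category on
2D tasks; growing relevant-dimension attention on 1D tasks and balanced
attention on 2D tasks; and, with the default lesion variant (shuffled
attention + τ_lesion = 0.55), an early-training deficit confined to the 1D
tasks with reduced 2D cluster counts.  The slow learning rates are the load-
bearing choice: η and η_λ of this size spread acquisition over hundreds of
trials, as rat curves require — note that λ then equilibrates rather than
ratcheting upward (large η_λ narrows the receptive fields without bound and
collapses 2D performance).

### Known limitations of the dynamics

* **Cluster count is not globally monotone in τ on 1D tasks.**  Raising τ
  thins recruitment on 2D tasks monotonically, but on 1D tasks a very high
  threshold (τ ≈ 0.9) blocks the second category's cluster early; the lone
  cluster then misclassifies chronically and occasional very-close errors
  recruit late, inflating the final count.
* **The lag-1 recency effect is small.**  With learning spread over 1200
  trials, a single trial's update is necessarily a small fraction of total
  learning; the high-similarity recency score of an intact agent is
  ≈ +0.0015 (per-subject SD ≈ 0.009).  Detecting it needs hundreds of
  simulated subjects; test sizes were chosen by power analysis at these
  measured effect sizes.

## Lesion variants

The control model plus five variants over three manipulations: static
attention (r = η_λ = 0), per-trial uniform permutation of the λ vector
(applied before activation and left in place afterwards, so the weights
keep updating in their shuffled slots), and a raised recruitment threshold
τ_lesion.  The variant table — 1: static, 2: shuffle, 3: threshold,
4: static+threshold, 5: shuffle+threshold — is config-driven, so alternate
compositions are one-line changes.  τ_lesion is a free parameter during
fitting, parameterized as τ + δ·(1−τ) with δ ∈ [0,1]; the closed lower
bound makes the control model an exact special case of every
raised-threshold variant, which the fitting machinery exploits (see below).

## Fitting and model comparison

Each variant is fitted to the per-session group-mean accuracy curves of
both groups and both task classes at once.  Control-group predictions come
from the shared parameters; the variant's manipulations shape only the
lesion group's predictions.  The objective is the binomial negative
log-likelihood of per-session success counts (observed accuracy ×
trials/session × subjects, rounded) under the model's Monte-Carlo mean
accuracy, clamped to [1e-4, 1−1e-4]; AIC = 2k + 2·NLL with k = 6 shared
parameters plus one (δ) per raised-threshold variant.  A Gaussian
sum-of-squares objective (AIC = n·ln(SSE/n) + 2k) is a config switch.

The Monte-Carlo objective is made quasi-deterministic by common random
numbers: every evaluation reuses the same per-rotation seed sequences, so
identical seed + configuration give bit-identical fits.  The default search
is differential evolution (Sobol initialization; the population is the
multi-start) at a reduced simulation count, followed by a Nelder-Mead
polish at full fidelity; η and η_λ are searched in log10 units because the
slow-learning regime occupies a vanishing corner of linear parameter space.
Warm starts can seed a variant's polish with another model's optimum — used
to enforce exact nesting (control ⊆ raised-threshold) in the tests.

Three identifiability findings from the recovery experiments are worth
stating plainly.  First, the likelihood of mean learning curves pins
d_dec, η and η_λ sharply and r to within roughly ±50%, but is nearly flat
in τ below ~0.6 (a few nats, strongly compensated by d_dec and η); point
estimates of τ from curve-only fits scatter widely and should not be
interpreted.  Second, a lesion threshold raise small enough to spare 2D
performance contributes at most a few nats of fit improvement, so
distinguishing the shuffle+threshold variant from shuffle-only (or even
from the control model on some cohort realizations) by AIC is not reliable
at 8-subject cohort scale.  Third, model comparisons are only as fair as
the optimization effort behind them: because the lesion variants receive
nested warm starts, the comparison machinery in the tests re-polishes the
control model from the best lesion model's shared parameters before
ranking, which removes a systematic bias against the simpler model.

## Behavioural measures

Session accuracy is the proportion of correct **first attempts**:
correction trials replay a stimulus the subject just got wrong until the
correct key is pressed, are counted separately, and would bias the
denominator (the source protocol does not state its denominator; this
choice is documented prominently for that reason).  Perseverative errors
are repeated presses of the same incorrect key within a trial's correction
loop.  Reaction times from incorrect trials are excluded, then a single
2-SD pass (no re-estimation) per subject and measure removes outliers;
zero-variance and <3-value edge cases return the data unfiltered, the
latter with a warning.  Touch separation mean-centres the three Cue-phase
touch x-coordinates per trial and signs them toward the correct side; the
third touch is the headline value, computed on correct first attempts.

## Recency analysis

Similarity between consecutive first-attempt training trials is
s = e^{−d} with d the attention-weighted city-block distance on model
coordinates (on the 0–100 scale virtually all similarities would collapse
to zero), using the model's λ at the current trial normalized to sum to 1.
Accuracy is binned by similarity (quantile bins, default 8, plus a median
split) and referenced to the mean over trial-order permutations that
shuffle whole (stimulus, outcome, weights) triplets, preserving marginal
accuracy exactly.  Bin edges and the median are recomputed inside every
permutation.  Correction trials are excluded — they repeat the same
stimulus mechanically and would flood the top similarity bin.  Group-level
inference is a one-sample t-test of per-subject median-split scores
against zero; binary first-attempt correctness is the accuracy variable.
Shuffling is performed across a subject's full training sequence (a
per-session option exists).

## Synthetic cohorts

`generate_cohort` simulates 8 subjects per group × task-class cell (split
over the class's two rotations), each an independent SUSTAIN agent seeded
from the master seed.  Lesion subjects run the model-5 variant by default —
generator and fitted family coincide, which makes model recovery a
meaningful experiment rather than a guarantee.  On training errors the
agent re-samples its decision on the same stimulus (state frozen) until
correct, capped at 10 repeats; testing sessions use the widened
distributions with no corrections, and learning continues there.

Reaction times and touch coordinates are generated by simple noise models
of the package's own design whose only purpose is to exercise the
behavioural pipeline: log-normal cue RT with a median shrinking over
training and a ×1.3 factor for lesion subjects on 1D tasks; group-
independent log-normal choice RT; and three centre-jittered touches whose
third drifts toward the chosen side in proportion to choice confidence
(mean third-touch separation = ⅔ · gain · confidence).  They are not models
of rat motor behaviour.

### What the synthetic data do and do not show

The generator reproduces the study's design counts exactly and its
qualitative signatures (1D-specific lesion deficit, spared 2D performance,
reduced lesion cluster counts, recency present only with intact updating).
It does not emulate motivational drift, session-level autocorrelation,
individual differences beyond seed noise, stimulus-repetition effects of
correction loops on learning, or any real motor/RT structure.  Passing
tests establish that the pipeline measures what it claims on data with
known structure — not that the model parameters describe any particular
animal.

## Problem sizes used in the tests

Module tests run at reduced scale (20–50 seeds per property; 5-session
training where full runs are unnecessary).  The acceptance suite uses the
full 15 × 80 design: 24 seeds for cluster-count readouts, 200 synthetic
subjects for the permutation-null calibration, 400 intact + 400 frozen
agents for the recency contrast (sizes from the power analysis above), five
replicates for each recovery experiment, and reduced Monte-Carlo fidelity
(n_sim 12–100) for the fitting stages.
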