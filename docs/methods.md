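# Methods

## Stimulus model

A stimulus is a pitch contour defined by shifts, in cents, at K
breakpoints: K = 8 equally spaced time points for the speech and
complex-tone conditions (250 ms, base F0 210 Hz), K = 3 note onsets for
the melody condition (1380 ms, base F0 260 Hz). Shifts are drawn i.i.d.
from Normal(0, σ²) with σ = 70 cents and *winsorized* at ±2.2 σ:
out-of-bound draws are set to the bound, not redrawn. Winsorizing
versus redrawing is genuinely open for this stimulus family; we default
to winsorizing and record the choice in `NoiseConfig.clip_mode`, with a
`redraw` mode available. The winsorized-normal SD has the closed form

    E[X²]/σ² = (2Φ(z) − 1) − 2zφ(z) + 2z²(1 − Φ(z)),   z = 2.2,

giving 68.25 cents at the default configuration; the generator's
empirical SD matches it.

Breakpoint placement within the sound is not uniquely determined by the
stimulus description. Linear mode anchors breakpoints at normalized
times t_k = (k−1)/(K−1) and interpolates piecewise-linearly (held flat
outside the anchors). Square-BPF (melody) mode divides the stimulus
into K equal note segments, holds each note's shift as a plateau, and
ramps linearly over 0.1 s centred on each note onset. Real sung notes
are unequal in length (the last note of the target phrase is longer);
equal thirds is a deliberate simplification — group contrasts operate
on breakpoint values, which are unaffected.

Each session draws a fresh pool of 2N distinct stimuli and pairs them
without replacement into N 2AFC trials (speech/tone: 800 → 400;
melody: 600 → 300), so no stimulus repeats within a session; pairings
and A/B assignment are randomized per participant from their seed. An
i.i.d. pairing mode (`iid_pair_trials`) exists for simulations that
need unlimited trials.

## Rendering

Audio is additive synthesis of the fundamental and its seven odd
harmonics (partial numbers 1, 3, …, 15), equal amplitude, sine phase at
onset, with the instantaneous fundamental f(t) = F0·2^(c(t)/1200)
integrated to a continuous phase. The experiment's 80 dB SPL playback
level has no file-domain counterpart; waveforms are peak-normalized to
−3 dBFS with 5 ms raised-cosine onset/offset ramps (ramps suppress
spectral splatter; not part of the stimulus definition). F0 estimation
for validation uses frame-wise autocorrelation (60 ms frames, 10 ms
hop, parabolic peak interpolation) aggregated by the frame median;
whole-stimulus estimates for flat contours are accurate to well under
0.5 Hz. The analysis pipeline never consumes audio — kernels and all
statistics operate on breakpoint shift vectors, which carry the same
information up to a fixed linear map.

## Observer model

The synthetic participant is a linear template observer. With unit-norm
template w over breakpoints, trial decision variable

    d = w·(s_A − s_B) + ε,   ε ~ N(0, (σ_int · σ_ext)²),

choose A iff d ≥ 0; with probability λ (lapse rate) the choice is
replaced by a fair coin. σ_ext is the analytic SD of w·(s_A − s_B)
under the stimulus distribution — √2 times the winsorized-normal SD,
independent of w's direction — so σ_int is a dimensionless
internal-to-external noise ratio, the standard convention for late
additive decision noise. Setting d = 0 → A keeps a measure-zero event
deterministic for testability.

Named templates (`linear` … `quartic`) are discrete orthogonal
polynomials on the breakpoint grid (QR of the Vandermonde matrix, sign
fixed so the last element is positive): the pure degree-d shape with
zero projection onto lower degrees. A raw monomial such as t⁴ is
dominated by its quadratic component and would make "a quartic-template
cohort" unrecoverable as quartic by any model-selection procedure; the
orthogonalized shapes make the generating degree a well-posed ground
truth. The melody prototype template is the notation-derived contour
[0, −500, 0] cents (note 2 five semitones down, note 3 five semitones
up), mean-centred and unit-normalized.

Cohorts draw observer i's template as normalize(base + δ·z_i) with
standard-normal z_i and dispersion δ, internal noise and lapse rates
from truncated normal distributions, and give every observer a fresh
pool and pairing; all reproducible from one master seed via spawned
child seeds.

### Default study conditions

Cohort defaults target the per-participant statistics reported for
human listeners in this paradigm: internal-noise ratio 4.0 ± 1.0
(yielding agreement ≈ 0.55–0.60 and kernel RMS ≈ 6–10 cents at 400
trials), lapse rate 0.02 ± 0.02, template dispersion 0.5 (pairwise
kernel correlations ≈ 0.1–0.3). These are generator properties fixed
once, not tuning knobs; heterogeneity contrasts in the examples use
δ = 0.8 vs 0.4.

## Kernel estimation and reliability

The first-order temporal kernel is K_k = mean(chosen_k) −
mean(unchosen_k) in cents, computed on breakpoint shifts. No
normalization is applied at estimation time. Reliability follows the
pilot definition: Pearson correlation between the kernel from the first
n trials (nested prefix) and the kernel from all N trials, with
r ≥ 0.8 the conventional adequacy bar; a random-subset mode is
available. For a pure-noise responder the nested construction gives
E[r] ≈ √(n/N) (the prefix mean is a component of the full mean), which
the tests confirm at √(300/400) ≈ 0.866.

## Metrics

- **RMS**: √(mean K_k²), in cents; scalar sensitivity index.
- **Agreement**: per trial, each stimulus's shifts are Pearson-correlated
  with the participant's kernel; the higher correlation defines the
  objectively correct choice, and agreement is the fraction of trials
  where the logged choice matches. Pearson correlation (not the dot
  product) is used as the similarity measure, which is well-defined from
  3 points (melody: df = 1). Trials with an undefined correlation
  (zero-variance contour or kernel) or an exact tie are excluded from
  the denominator; `n_scored_trials` records the denominator actually
  used. The in-sample kernel is the default scorer (matching how the
  quantity is defined for human data); it is optimistically biased for
  noisy observers — bounded near 0.55 for pure guessers at 400 trials —
  so a leave-one-out scorer, unbiased at 0.5, is provided
  (`method="leave_one_out"`).
- **Exceptional sensitivity**: a participant is flagged when their RMS
  strictly exceeds mean + 2·SD of the reference group, with the sample
  SD (n−1); the denominator choice is not stated in the source analyses,
  and n−1 is the field default. Percentages are rounded half-up to 2 dp.
- **Prototype correlation**: Pearson r between a kernel and
  [0, −500, 0].

## Shape models

Kernels (participant-level, K points) or pooled group kernels (one
observation per participant per time point) are fit by OLS with
polynomials of degree 1–4 on the normalized time axis; the midpoint is
t = 0.5 and the tangent slope there is the analytic derivative of the
fitted polynomial (no finite differences). Nested models are compared
with the OLS F-test, the exact likelihood-ratio test under Gaussian
errors:

    F = ((SSE_s − SSE_b)/Δdf) / (SSE_b/(n − p_b)),  α = 0.05.

The selection ladder is sequential: linear vs quadratic; when not
significant, linear vs cubic; a winning cubic is challenged by the
quartic; when linear vs cubic is also not significant, linear vs
quartic decides. When linear vs quadratic *is* significant — uncommon
for kernels of this family, which are near zero-mean — the same logic
continues upward from the quadratic. Melody kernels (3 points) are excluded from the
ladder: a quartic has no residual degrees of freedom there.

## Group statistics

- Per-breakpoint group contrasts: Welch two-sample t-tests with
  Bonferroni correction over the K breakpoints. This deliberately
  replaces a by-subject random-intercept mixed model: with exactly one
  kernel value per participant per time point, the fixed-effects group
  contrast at each time point coincides, and the substitution is noted
  in the report header. The correction family is the breakpoints of one
  condition.
- RMS and agreement: Welch t-tests (Welch–Satterthwaite df), two-sided,
  with pooled-SD Cohen's d.
- Intra-group variability: all C(n,2) pairwise Pearson correlations
  between participants' kernels within each group, compared across
  groups with Student's two-sample t (df = m₁ + m₂ − 2, i.e. 990 for
  two groups of 32); a Fisher-z variant is available since correlations
  are bounded. Undefined correlations (zero-variance kernels) are
  dropped and counted.
- Subgroup analysis: the 2 SD rule against a designated reference
  group, reported per condition for both groups.

`run_pipeline` chains simulation → kernels → metrics → shape selection
→ group tables, writes CSV/JSON artifacts, and is byte-reproducible
from its seed; `analyze_sessions` applies the identical analysis to
session logs loaded from CSV.

## Problem sizes and numerical choices

The test suite and acceptance script run at the experiment's native
scale (400-trial sessions, 32-observer cohorts) where the quantity
under test demands it, and at reduced scale (60–200 trials, 6–16
observers) for pipeline plumbing checks; Monte Carlo suites use 20–500
replicates chosen so that the property tested is resolved within its
stated tolerance. Seeds are fixed throughout. Ladder and power checks
generate kernels directly from polynomial signal + Gaussian noise where
only the fitting machinery is under test, and from full observer
simulation where the claim involves the whole pipeline.

## Known limitations

- The simulator's internal noise is late, additive and Gaussian; real
  listeners may show early (stimulus-level) noise, serial dependence,
  or criterion drift, none of which are modelled. Passing tests
  establish the correctness of the analysis machinery, not the realism
  of any particular observer.
- Equal-length melody notes and equally spaced breakpoints are
  simplifications of the recorded materials.
- The rendered "melody" is a harmonic-complex analogue, not a sung
  voice; speech is not synthesized at all.
- Group-level test statistics from any particular human cohort are not
  reproduction targets — they depend on data that is not distributed
  with the package; the pipeline reproduces the analysis structure and
  its arithmetic, verified on simulated cohorts.
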