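# Methods

## Problem setting

During explosive overhead movements such as the badminton forehand
smash, the nervous system coordinates ~15 shoulder and arm muscles.
The muscle-synergy hypothesis holds that this coordination is
low-dimensional: a few fixed nonnegative muscle weightings (synergy
vectors) recruited by shared time-varying coefficients. This package
implements the full analysis chain for testing that hypothesis on two
parallel data sources — activation envelopes derived from surface EMG,
and activations predicted by static optimization of a musculoskeletal
model — and for quantifying the agreement between them.

## Signal conditioning

Raw EMG-like signals (1000 Hz assumed; any rate > 900 Hz works for the
default band) pass through, in order: a zero-phase 4th-order Butterworth
band-pass at 20–450 Hz; a zero-phase notch at 50 Hz with 1 Hz bandwidth
(Q = 50); full-wave rectification followed by a zero-phase 4th-order
20 Hz low-pass (the linear envelope); division by an MVIC reference
amplitude supplied by the caller (MVIC collection is a lab protocol, not
a computation); and cubic-spline resampling of a caller-supplied
onset–offset window onto 101 points spanning 0–100% of the movement
cycle (101 so both endpoints are included at 1% spacing; the default
window is the full trial, since movement-phase segmentation requires
kinematics outside this package's scope). All filters run
forward–backward, so the chain is phase-neutral; the effective
attenuation order is twice the design order. A 20 Hz low-pass is also
approximately a 25 ms moving average; we implement the filter form only.
An SNR estimator (10·log₁₀(RMS²_active/RMS²_quiet)) supports the
conventional > 20 dB inclusion screen.

## Factorization

`nmf_decompose` implements Lee–Seung multiplicative updates for the
Frobenius objective, with 10⁻¹² added to update denominators to guard
divisions. Convergence is declared when the relative change in
‖M − WC‖_F between iterations falls below 10⁻⁶ (the monitored quantity
had to be chosen; the objective itself is the natural one), with a
100-iteration cap. Each factorization is restarted 50 times from
entrywise Uniform(0,1] factors scaled by mean(M); restart r uses seed
`master + r`, so results are reproducible and the best (lowest-error)
run is returned. The scale ambiguity of NMF is fixed by normalizing W
columns to unit Euclidean norm with the inverse scale absorbed into C;
all-zero columns cannot be normalized and are flagged instead. Trials
can be factorized singly or concatenated along time; cohort-level
routines concatenate a subject's trials, which stabilizes the weight
estimates and is the default.

## Synergy-number selection

Global VAF is the uncentered 1 − ‖M − M̂‖_F²/‖M‖_F²; local VAF is the
same quantity per muscle row, with all-zero rows reported as undefined
(NaN) rather than raising. The selected order is the smallest k in the
scanned range (default 1–6) satisfying, conjunctively: global VAF >
0.90, all defined local VAFs > 0.75, and global-VAF improvement from k
to k+1 below 5 percentage points (the largest scanned k has no
successor; its slope is taken as 0). Conjunction, rather than majority
vote, is the stricter and more common reading of multi-criterion rules;
undefined local VAFs are excluded from the conjunction. If no k
qualifies, the largest k is returned with an explicit not-selected flag.

Two cross-validation views support the choice. Leave-one-out: weights
are extracted from the n−1 remaining trials, coefficients for the
held-out trial are refit by nonnegative least squares per time sample
(W fixed), and the generalization gap ΔVAF = held-out VAF −
within-sample VAF is reported as mean ± SD. Split-half: trials are
randomly halved, synergies extracted per half, matched, and compared by
weight cosine and by Pearson correlation of trial-averaged coefficient
waveforms; an ICC(3,1) over the muscles × {half A, half B} weight table
and its SEM are averaged across components and splits. Split-half is
advisory (reported, not gated), since no numeric threshold accompanies
it in standard practice.

## Static optimization

The model modality of a real study comes from an OpenSim-class pipeline;
here a self-contained desk-scale stage plays that role. Muscle force is
rigid-tendon and nominal-length: F = a·Fmax·cos(pennation), with
optional force-length/velocity multipliers in [0, 1.8] (default 1) as
extension hooks. The per-frame program min Σa² s.t. Σ rᵢⱼFᵢ(aᵢ) = Mⱼ,
0 ≤ a ≤ 1 is strictly convex: the closed-form least-norm solution
a = Aᵀ(AAᵀ)⁺M is used whenever it respects the bounds (then it is exact
to machine precision), otherwise feasibility is certified by a linear
program (naming the violated joint and its moment shortfall on failure)
and the QP is solved by SLSQP polished to an equilibrium residual below
10⁻⁶. The bundled 15-muscle Hill parameter table is stored verbatim as
printed in its source, including its internally inconsistent length
columns (trapezius fiber lengths ~0.1 vs deltoid ~9.8 under one "cm"
header); only peak force and pennation enter the default computation, so
the inconsistency is quarantined. The default task spans elevation and
internal rotation with hand-authored signed moment arms under three
phase-specific moment bumps, making the trapezius group, the
pectoralis/anterior-deltoid group and the posterior group the efficient
actuators of the early, middle and late cycle respectively — so the
optimizer's output is itself approximately rank-3 and the synergy
pipeline can be exercised on it.

## Similarity metrics

Weight vectors are compared by the scalar product (u·v)/(‖u‖‖v‖), which
lies in [0,1] for nonnegative inputs and equals 1 only for parallel
vectors; coefficients by Pearson correlation. Components of two
decompositions are paired by the one-to-one assignment maximizing total
weight similarity (solved exactly by linear assignment; verified against
exhaustive permutation in tests). Per-muscle similarity — how consistently
a muscle is apportioned across synergies — is the scalar product of the
muscle's k-vector of weights (its row of W, columns ordered by the
matching) between the two sets; comparing per-muscle reconstructed
signals instead is available via the matched coefficients but the
row-profile form is the default because it isolates the weighting
structure.

## Reliability

CV = 100·SD/mean per subject (sample SD), summarized as mean ± SD over
subjects. ICC(3,1) is the two-way mixed, single-measure consistency form
(BMS − EMS)/(BMS + (k−1)·EMS) from explicit ANOVA mean squares; the
absolute-agreement variant is available by flag. SEM = SD·√(1 − ICC)
with SD taken as the between-subject SD of subject means (the SD
entering SEM is not standardized in the field; this choice is
conservative and documented). Acceptability is flagged at CV < 10% and
ICC > 0.80.

## Synthetic cohorts

The generator emulates the study conditions: 15 labelled muscles, 101
cycle samples, 3 ground-truth synergies, 20 subjects × 5 trials per
modality, 20 dB SNR. Ground-truth weights draw dominant-group entries
from U(0.6, 1.0) and background from U(0, 0.2) (dominant mean ≥ 2× the
rest by construction) over three functional groups — trapezius portions;
pectoralis portions, anterior deltoid, triceps, biceps; posterior
deltoid, infraspinatus, latissimus, serratus — and coefficients are
Gaussian bumps centered at 20/50/80% of the cycle with SD half the
`envelope_width` fraction (0.15 by default), mirroring preparation,
impact and follow-through. A trial is M = W′(C⊙g) + ε clipped at zero:
per-synergy lognormal gains (σ = 0.1; trial-to-trial effort variability
is not documented anywhere we know of, so this is an explicit stand-in),
and Gaussian noise scaled to the target SNR exactly, pre-clipping (SNR
defined as 10·log₁₀(‖signal‖²/‖noise‖²)). The model modality perturbs W
entrywise by ×(1 + U(−p, p)), p = 0.10, re-normalized, with the
perturbation held fixed across a subject's trials (a model's bias is
systematic, not per-trial); subjects receive an analogous 5% weight
jitter. Note a consequence of this noise model: a 10% entrywise
perturbation moves unit-norm cosines only to ≈ 0.998, so synthetic
EMG-vs-model weight similarities are much higher than those reported for
real data (~0.8–0.9), where anatomical and electrode-placement variation
dominates. Passing similarity tests therefore validate the metrics and
matching, not realistic effect sizes.

Kinematic scalars (shoulder abduction 45.2°, elbow flexion 85.6°,
scapular protraction 12.3°) are drawn from mean + subject offset + trial
noise, with the published total SD split by the published ICC
(between = SD·√ICC, within = SD·√(1−ICC)); the printed CV, SD and ICC of
the source table are mutually inconsistent under any split, so the
generator reproduces mean, SD and ICC exactly in expectation and lets CV
fall where it may (~1–5%, still under the 10% screen).

What the generator does not emulate: raw interference EMG (trials are
generated directly at the envelope stage), electromechanical delay,
muscle crosstalk, fatigue drift across trials, and any kinematic
coupling between the activation and kinematic tables. Tests passing on
these cohorts demonstrate correctness of the algorithms and the
recoverability of a known low-rank structure under the stated noise —
not performance on real recordings.

## Problem sizes and numerical choices

Cohort-level analyses factorize 15 × 505 matrices (5 concatenated
trials) over k = 1–6 with 50 restarts; the parameter-recovery study uses
single-subject cohorts over k_true ∈ {2,3,4} × SNR ∈ {15,20,30} dB × 50
replicates with 10 restarts, which leaves recovery rates unchanged on
these cohorts while keeping the study quick on one CPU. Degenerate
inputs are contracts, not crashes: all-zero matrices give undefined
global VAF (error) and zero-row local VAF gives NaN flags; zero vectors
make similarity undefined; all-equal reliability tables make ICC
undefined. Ties in NMF restarts resolve to the first-found minimum
(restart order is seed-determined, so this is reproducible).

## Known limitations

The static-optimization stage is a two-joint toy, not a validated
shoulder model: its role is generating Eq.-consistent activations with
planted structure. Multiplicative-update NMF finds local minima;
restarts mitigate but do not guarantee the global optimum (the
VAF-monotone-in-k property is asserted only to 10⁻⁶ for this reason).
The per-muscle similarity definition is one of several in use; both
variants are computable here but cross-study comparability of that
column is limited. Group inferential statistics (MANOVA, post-hoc
corrections) are out of scope.
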