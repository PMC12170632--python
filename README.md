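# musclesyn

Muscle-synergy analysis for high-velocity overhead movements, built
around the comparison of surface-EMG-derived and musculoskeletal-model-
predicted coordination patterns during the badminton forehand overhead
smash.

## Who this is for

Biomechanists and motor-control researchers who want a tested, scriptable
pipeline for the standard synergy workflow — envelope conditioning,
non-negative matrix factorization, synergy-number selection, EMG-vs-model
similarity, and inter-trial reliability — without depending on any
particular motion-capture or modeling toolchain. Because no public
dataset of shoulder envelopes during the smash exists, the package ships
a first-class synthetic-cohort generator with known ground truth, so
every stage is verifiable end to end.

## The model

A muscle activation matrix **M** (muscles × time) is decomposed as

```
min_{W,C ≥ 0}  ‖M − W C‖_F²
```

where the columns of **W** (muscles × k) are synergy weight vectors —
fixed nonnegative muscle groupings — and the rows of **C** (k × time)
their activation coefficients. The factorization uses Lee–Seung
multiplicative updates (100-iteration cap, 10⁻⁶ relative tolerance, best
of 50 random restarts). The synergy number k is the smallest order
satisfying all of: global VAF > 90%, every muscle's local VAF > 0.75,
and < 5 percentage-point VAF gain from the next synergy, where
VAF = 1 − ‖M − WC‖_F² / ‖M‖_F² (uncentered; rowwise for local).

Model-predicted activations come from frame-wise static optimization,

```
min Σᵢ aᵢ²   s.t.   Σᵢ rᵢⱼ Fᵢ(aᵢ) = Mⱼ  ∀ joints j,   0 ≤ aᵢ ≤ 1,
```

with rigid-tendon Hill muscles Fᵢ(aᵢ) = aᵢ·Fmaxᵢ·cos(pennationᵢ) on a
desk-scale two-joint shoulder task. Decompositions are compared after
optimal component matching: scalar-product similarity (u·v)/(‖u‖‖v‖) for
weight vectors, Pearson r for coefficients. Reliability uses CV,
ICC(3,1) (two-way mixed, single-measure, consistency) and
SEM = SD·√(1 − ICC).

## Worked example

```
python examples/extract_synergies.py
```

prints, for one synthetic subject's five concatenated EMG-like trials:

```
 k   global VAF   min local VAF   slope (pp)  criteria
 1      0.526          0.393        24.48      nnn
 2      0.770          0.461        22.26      nnn
 3      0.993          0.982         0.06      yyy
 4      0.994          0.983         0.05      yyy
 5      0.994          0.988         0.04      yyy
 6      0.994          0.988         0.00      yyy
selected k = 3 (all criteria satisfied: True)
```

The VAF curve saturates at three synergies — the generator's embedded
dimensionality — with 99.3% of the signal variance explained; adding a
fourth synergy buys less than 0.1 percentage points. The other scripts in
`examples/` walk through cohort generation, EMG conditioning, static
optimization, EMG-vs-model similarity and kinematic reliability the same
way, and `musclesyn.run_pipeline(RunConfig(...))` runs everything into a
CSV run directory.

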