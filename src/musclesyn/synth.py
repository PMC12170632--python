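"""Synthetic two-modality activation cohorts with known ground truth.

No public dataset of shoulder-muscle envelopes during the badminton
forehand overhead smash exists, so every downstream stage is exercised on
synthetic cohorts built from a known low-rank generative model:

    M = W' (C * gains) + noise,  clipped at 0,

where W (muscles x k_true, unit-norm columns) encodes k_true functional
muscle groups — trapezius-dominant scapular stabilization, pectoralis /
anterior-deltoid power generation, posterior-muscle deceleration — and C
holds smooth unimodal activation bumps centered in the early, middle and
late movement cycle.  Two modalities are emitted per trial: ``emg`` uses W
as-is; ``model`` applies a multiplicative entrywise perturbation to W
(re-normalized), emulating the systematic weight discrepancies between
surface-EMG-derived and musculoskeletal-model-predicted synergies.  Noise
is zero-mean Gaussian scaled to an exact signal-to-noise ratio before
clipping; per-trial lognormal gains emulate effort variability.

A companion generator emits per-trial scalar kinematic variables
(shoulder abduction, elbow flexion, scapular protraction) from a
between/within-subject variance model with a controllable intraclass
correlation, used to exercise the reliability metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ActivationMatrix
from .errors import DomainError, InvalidConfigError

#: EMG montage of the 15 shoulder/arm muscles (standard abbreviations):
#: deltoid heads, infraspinatus, pectoralis major portions, latissimus
#: dorsi, triceps heads, biceps long head, trapezius portions, serratus.
DEFAULT_MUSCLE_LABELS = (
    "TRP1", "TRP3", "TRP4", "SRA",
    "PECM1", "PECM2", "PECM3", "DELT1",
    "DELT2", "DELT3", "INFSP", "LAT2",
    "TRILat", "TRImed", "BIClong",
)

# Functional groups backing the default three-synergy ground truth:
# scapular stabilizers / power generators / decelerators.
_DEFAULT_GROUPS = {
    0: ("TRP1", "TRP3", "TRP4"),
    1: ("PECM1", "PECM2", "PECM3", "DELT1", "TRILat", "TRImed", "BIClong"),
    2: ("DELT2", "DELT3", "INFSP", "LAT2", "SRA"),
}


@dataclass
class KinematicVar:
    """One scalar kinematic variable: total SD split by a target ICC.

    ``total_sd**2`` is partitioned into between-subject variance
    ``icc * total_sd**2`` and within-subject (trial) variance
    ``(1 - icc) * total_sd**2``, so the generating model's closed-form
    ICC(3,1) equals ``icc`` exactly.
    """

    name: str
    mean: float
    total_sd: float
    icc: float

    @property
    def between_sd(self) -> float:
        return self.total_sd * np.sqrt(self.icc)

    @property
    def within_sd(self) -> float:
        return self.total_sd * np.sqrt(1.0 - self.icc)


def default_kinematic_vars() -> list[KinematicVar]:
    """Shoulder abduction / elbow flexion / scapular protraction defaults."""
    return [
        KinematicVar("shoulder_abduction", 45.2, 2.1, 0.92),
        KinematicVar("elbow_flexion", 85.6, 3.4, 0.89),
        KinematicVar("scapular_protraction", 12.3, 1.8, 0.85),
    ]


@dataclass
class SynthConfig:
    """Cohort-generation parameters.

    Defaults emulate the study conditions: 15 muscles, 101 normalized
    time samples (0-100%), 3 ground-truth synergies, 20 subjects x 5
    trials, 20 dB SNR, 10% model-modality weight perturbation.
    """

    n_muscles: int = 15
    muscle_labels: tuple[str, ...] = DEFAULT_MUSCLE_LABELS
    n_time: int = 101
    k_true: int = 3
    n_subjects: int = 20
    n_trials: int = 5
    snr_db: float = 20.0
    modality_perturb: float = 0.10
    envelope_width: float = 0.15
    subject_jitter: float = 0.05
    gain_sigma: float = 0.10
    kinematic_vars: list[KinematicVar] = field(default_factory=default_kinematic_vars)
    seed: int = 42

    def __post_init__(self):
        if self.k_true < 1 or self.k_true > self.n_muscles:
            raise InvalidConfigError(f"k_true={self.k_true} outside [1, {self.n_muscles}]")
        if self.n_time < 2:
            raise InvalidConfigError("n_time must be >= 2")
        if not np.isfinite(self.snr_db) and self.snr_db != np.inf:
            raise InvalidConfigError("snr_db must be finite or +inf (noise disabled)")
        if not 0 <= self.modality_perturb < 1:
            raise InvalidConfigError("modality_perturb must lie in [0, 1)")
        if len(self.muscle_labels) != self.n_muscles:
            raise InvalidConfigError(
                f"{len(self.muscle_labels)} labels for n_muscles={self.n_muscles}"
            )


@dataclass
class GroundTruth:
    """Ground-truth factors: W (muscles x k, unit-norm columns), C (k x time)."""

    w_true: np.ndarray
    c_true: np.ndarray
    muscle_labels: tuple[str, ...]


def _muscle_groups(config: SynthConfig) -> list[list[int]]:
    """Partition muscle indices into k_true dominance groups.

    The default 15-label, k=3 configuration uses the named functional
    groups; otherwise the label list is split into contiguous blocks.
    """
    labels = list(config.muscle_labels)
    if config.k_true == 3 and set(labels) == set(DEFAULT_MUSCLE_LABELS):
        return [
            [labels.index(name) for name in _DEFAULT_GROUPS[j]]
            for j in range(3)
        ]
    blocks = np.array_split(np.arange(config.n_muscles), config.k_true)
    return [list(b) for b in blocks]


def make_ground_truth(config: SynthConfig) -> GroundTruth:
    """Draw a ground-truth synergy set with clear dominance structure.

    Each synergy's dominant muscles draw weights from U(0.6, 1.0) and the
    remaining muscles from U(0.0, 0.2), guaranteeing a dominant-group mean
    at least twice the non-dominant mean; columns are normalized to unit
    Euclidean norm.  Coefficients are raised-Gaussian bumps on the
    normalized cycle with centers evenly spaced between 20% and 80%
    (preparation through follow-through) and SD ``envelope_width / 2``.
    """
    rng = np.random.default_rng(config.seed)
    groups = _muscle_groups(config)

    w = rng.uniform(0.0, 0.2, size=(config.n_muscles, config.k_true))
    for j, grp in enumerate(groups):
        w[grp, j] = rng.uniform(0.6, 1.0, size=len(grp))
    w /= np.linalg.norm(w, axis=0)

    t = np.linspace(0.0, 1.0, config.n_time)
    if config.k_true == 1:
        centers = np.array([0.5])
    else:
        centers = np.linspace(0.2, 0.8, config.k_true)
    sigma = config.envelope_width / 2.0
    c = np.exp(-((t[None, :] - centers[:, None]) ** 2) / (2.0 * sigma**2))
    return GroundTruth(w_true=w, c_true=c, muscle_labels=tuple(config.muscle_labels))


def _perturb_weights(w: np.ndarray, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Entrywise multiplicative perturbation, clipped at 0 and re-normalized."""
    if magnitude == 0:
        return w.copy()
    factors = 1.0 + magnitude * rng.uniform(-1.0, 1.0, size=w.shape)
    out = np.clip(w * factors, 0.0, None)
    norms = np.linalg.norm(out, axis=0)
    return out / np.where(norms == 0, 1.0, norms)


def generate_trial(
    gt: GroundTruth,
    config: SynthConfig,
    modality: str = "emg",
    trial_seed=0,
    perturb_seed=None,
    subject_id: str = "S00",
    trial_id: str = "T00",
) -> ActivationMatrix:
    """Generate one trial: M = W'(C * gains) + noise, clipped at 0.

    ``emg`` trials use the ground-truth weights directly; ``model`` trials
    perturb them by ``modality_perturb`` (seeded by ``perturb_seed`` so a
    subject's model bias can be held systematic across trials).  Gains are
    per-synergy lognormal scalars; Gaussian noise is scaled so the
    pre-clipping SNR, 10 log10(||signal||^2 / ||noise||^2), equals
    ``snr_db`` exactly.
    """
    if modality not in ("emg", "model"):
        raise DomainError(f"unknown modality '{modality}'")
    rng = np.random.default_rng(trial_seed)
    if modality == "model":
        prng = np.random.default_rng(
            perturb_seed if perturb_seed is not None else trial_seed
        )
        w = _perturb_weights(gt.w_true, config.modality_perturb, prng)
    else:
        w = gt.w_true

    gains = np.exp(rng.normal(0.0, config.gain_sigma, size=gt.c_true.shape[0]))
    signal = w @ (gt.c_true * gains[:, None])

    if np.isinf(config.snr_db):
        m = signal
    else:
        noise = rng.standard_normal(signal.shape)
        target = np.linalg.norm(signal) * 10.0 ** (-config.snr_db / 20.0)
        noise *= target / np.linalg.norm(noise)
        m = np.clip(signal + noise, 0.0, None)

    return ActivationMatrix(
        values=m,
        muscle_labels=list(gt.muscle_labels),
        subject_id=subject_id,
        trial_id=trial_id,
        modality=modality,
    )


def generate_cohort(config: SynthConfig) -> list[ActivationMatrix]:
    """Generate the full two-modality cohort (n_subjects x n_trials each).

    Each subject receives a jittered copy of the ground-truth weights
    (multiplicative ``subject_jitter`` noise, re-normalized) emulating
    inter-subject variability, and a fixed model-modality perturbation
    shared by that subject's model trials.  Fully deterministic given
    ``config.seed``.
    """
    gt = make_ground_truth(config)
    out: list[ActivationMatrix] = []
    for s in range(config.n_subjects):
        srng = np.random.default_rng([config.seed, 101, s])
        w_subj = _perturb_weights(gt.w_true, config.subject_jitter, srng)
        gt_subj = GroundTruth(w_subj, gt.c_true, gt.muscle_labels)
        perturb_seed = [config.seed, 211, s]
        for t in range(config.n_trials):
            for modality in ("emg", "model"):
                out.append(
                    generate_trial(
                        gt_subj,
                        config,
                        modality=modality,
                        trial_seed=[config.seed, 307, s, t, 0 if modality == "emg" else 1],
                        perturb_seed=perturb_seed,
                        subject_id=f"S{s:02d}",
                        trial_id=f"T{t:02d}",
                    )
                )
    return out


def generate_kinematic_trials(config: SynthConfig):
    """Per-trial scalar kinematic variables as a tidy DataFrame.

    Columns: subject, trial, one column per variable.  Each subject draws
    a persistent offset ~ N(0, between_sd); each trial adds N(0, within_sd),
    so the population ICC(3,1) of each column equals the variable's
    configured ``icc`` in expectation.
    """
    import pandas as pd

    rng = np.random.default_rng([config.seed, 401])
    rows = []
    offsets = {
        v.name: rng.normal(0.0, v.between_sd, size=config.n_subjects)
        for v in config.kinematic_vars
    }
    for s in range(config.n_subjects):
        for t in range(config.n_trials):
            row = {"subject": f"S{s:02d}", "trial": f"T{t:02d}"}
            for v in config.kinematic_vars:
                row[v.name] = v.mean + offsets[v.name][s] + rng.normal(0.0, v.within_sd)
            rows.append(row)
    return pd.DataFrame(rows)
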