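"""Core in-memory containers shared across the pipeline.

The central object is :class:`ActivationMatrix`: a nonnegative
muscles x time matrix of activation envelopes for one trial, tagged with
its subject, trial and modality (``"emg"`` for envelopes derived from
surface recordings, ``"model"`` for activations predicted by static
optimization of a musculoskeletal model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, LabelMismatchError

MODALITIES = ("emg", "model")


@dataclass
class ActivationMatrix:
    """Nonnegative muscles x time activation matrix for a single trial.

    Parameters
    ----------
    values : ndarray, shape (n_muscles, n_time)
        Activation envelopes, all entries >= 0.
    muscle_labels : sequence of str
        Unique label per row.
    subject_id, trial_id : str
        Identifiers used by cohort-level routines.
    modality : {"emg", "model"}
    """

    values: np.ndarray
    muscle_labels: list[str]
    subject_id: str = "S00"
    trial_id: str = "T00"
    modality: str = "emg"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.muscle_labels = list(self.muscle_labels)
        if self.values.ndim != 2:
            raise DomainError("activation matrix must be 2-D (muscles x time)")
        if len(self.muscle_labels) != self.values.shape[0]:
            raise LabelMismatchError(
                f"{len(self.muscle_labels)} labels for {self.values.shape[0]} rows"
            )
        if len(set(self.muscle_labels)) != len(self.muscle_labels):
            raise LabelMismatchError("muscle labels must be unique")
        if self.modality not in MODALITIES:
            raise DomainError(f"modality must be one of {MODALITIES}")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise DomainError(
                f"negative activation at muscle '{self.muscle_labels[i]}', sample {j}"
            )

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]

    def check_labels(self, other: "ActivationMatrix | SynergySet"):
        if list(self.muscle_labels) != list(other.muscle_labels):
            raise LabelMismatchError("muscle label order differs between operands")


@dataclass
class SynergySet:
    """Result of a nonnegative factorization M ~ W C.

    ``w`` holds one synergy weight vector per column (muscles x k, columns
    unit Euclidean norm by convention); ``c`` the matching activation
    coefficients (k x time).  ``objective`` is the Frobenius reconstruction
    error ||M - WC||_F of the best restart; ``objective_history`` its
    per-iteration trace (used to verify monotonicity of the updates).
    """

    w: np.ndarray
    c: np.ndarray
    muscle_labels: list[str]
    objective: float = np.nan
    restarts_used: int = 0
    converged: bool = False
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    zero_columns: tuple[int, ...] = ()

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.muscle_labels = list(self.muscle_labels)
        if self.w.ndim != 2 or self.c.ndim != 2 or self.w.shape[1] != self.c.shape[0]:
            raise DomainError("w (m x k) and c (k x t) must be conformable")
        if np.any(self.w < 0) or np.any(self.c < 0):
            raise DomainError("synergy factors must be nonnegative")

    @property
    def k(self) -> int:
        return self.w.shape[1]
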