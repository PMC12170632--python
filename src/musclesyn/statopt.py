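"""Toy static optimization: model-predicted activations from joint moments.

Muscle redundancy is resolved frame by frame by the classic static
optimization criterion

    min sum_i a_i^2   subject to   sum_i r_ij F_i(a_i) = M_j  for all joints j,
                                   0 <= a_i <= 1,

with a rigid-tendon, nominal-length Hill muscle: F_i(a_i) = a_i * Fmax_i *
cos(pennation_i) * f_l * f_v, where the force-length and force-velocity
factors default to 1.  With F linear in a this is a strictly convex
quadratic program with a unique solution; unconstrained frames admit the
closed-form least-norm solution a = A^T (A A^T)^{-1} M.

The default desk-scale task spans two shoulder degrees of freedom
(elevation and internal rotation) actuated by the 15 muscles of a
published Hill-type shoulder parameter table, with hand-authored signed
moment arms arranged so that three functional groups (scapular
elevators, internal rotators/flexors, posterior external rotators) are
the efficient actuators of three phase-specific moment demands — the
coordination structure the synergy pipeline is meant to recover.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize

from .containers import ActivationMatrix
from .errors import DomainError, InfeasibleFrameError

# Hill-type muscle-tendon parameters of the 15-muscle shoulder set, stored
# verbatim as printed in the source table.  Caveat: the fiber/tendon length
# columns mix scales under a single "cm" header (trapezius ~0.1 vs deltoid
# ~9.8); only peak_force and pennation_angle enter the default computation.
_PARAM_TABLE_CSV = """\
name,optimal_fiber_length,peak_force,tendon_slack_length,pennation_angle
TRPL1,0.1127,1043,0.027,0
TRPL2,0.0832,470.4,0.032,0
TRPL3,0.1264,414.4,0.035,0
TRPL4,0.1116,201.6,0.027,0
DELT1,9.8,1218.9,9.3,22
DELT2,10.8,1103.5,11,15
DELT3,13.7,201.6,3.8,18
SUPRA,6.8,499.2,4,7
INFRA,7.6,1075.8,3.1,19
SUBSCAP,8.7,1306.9,3.3,20
TMIN,7.4,269.5,7.1,24
TMAJ,16.2,144,2,16
PECM1,14.4,444.3,0.3,17
PECM2,13.8,658.3,8.9,26
PECM3,13.8,498.1,13.2,25
"""


@dataclass
class MuscleParams:
    """Hill-type parameters for one muscle (lengths in units as printed)."""

    name: str
    optimal_fiber_length: float
    peak_force: float
    tendon_slack_length: float
    pennation_angle: float  # degrees

    def __post_init__(self):
        if self.peak_force <= 0:
            raise DomainError(f"{self.name}: peak force must be positive")
        if not 0 <= self.pennation_angle < 90:
            raise DomainError(f"{self.name}: pennation must lie in [0, 90) degrees")


def default_muscle_params() -> list[MuscleParams]:
    """The 15-muscle shoulder parameter set."""
    import pandas as pd

    df = pd.read_csv(_io.StringIO(_PARAM_TABLE_CSV))
    return [MuscleParams(**row) for row in df.to_dict(orient="records")]


def load_muscle_params(path) -> list[MuscleParams]:
    """Read a parameter table CSV with the standard column names."""
    import pandas as pd

    df = pd.read_csv(path)
    return [MuscleParams(**row) for row in df.to_dict(orient="records")]


def muscle_force(p: MuscleParams, activation: float, f_l: float = 1.0, f_v: float = 1.0) -> float:
    """Rigid-tendon force: a * Fmax * cos(pennation) * f_l * f_v.

    ``f_l`` / ``f_v`` are optional force-length / force-velocity factors in
    [0, 1.8]; both default to the nominal state 1.
    """
    if not 0.0 <= activation <= 1.0:
        raise DomainError(f"activation {activation} outside [0, 1]")
    for name, f in (("f_l", f_l), ("f_v", f_v)):
        if not 0.0 <= f <= 1.8:
            raise DomainError(f"{name}={f} outside [0, 1.8]")
    return float(activation * p.peak_force * np.cos(np.deg2rad(p.pennation_angle)) * f_l * f_v)


@dataclass
class ToyJointTask:
    """A joints x muscles moment-arm matrix plus required joint moments over time."""

    moment_arms: np.ndarray  # (n_joints, n_muscles), signed
    required_moments: np.ndarray  # (n_joints, n_time)
    joint_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.moment_arms = np.atleast_2d(np.asarray(self.moment_arms, dtype=float))
        self.required_moments = np.atleast_2d(np.asarray(self.required_moments, dtype=float))
        if self.moment_arms.shape[0] != self.required_moments.shape[0]:
            raise DomainError("moment_arms and required_moments disagree on joint count")
        if not self.joint_names:
            self.joint_names = [f"J{j}" for j in range(self.moment_arms.shape[0])]


def _gain_matrix(task: ToyJointTask, params: list[MuscleParams], f_l=1.0, f_v=1.0) -> np.ndarray:
    """A[j,i] = r_ji * Fmax_i * cos(penn_i) * f_l * f_v, so that A @ a = M."""
    gains = np.array(
        [p.peak_force * np.cos(np.deg2rad(p.pennation_angle)) * f_l * f_v for p in params]
    )
    return task.moment_arms * gains[None, :]


def _check_feasible(a_mat: np.ndarray, b: np.ndarray, joint_names, frame, tol=1e-8):
    """LP feasibility certificate: does a in [0,1]^n with A a = b exist?"""
    n_joints, n_muscles = a_mat.shape
    # min sum of slacks s+ + s-  s.t.  A a + s+ - s- = b
    c = np.concatenate([np.zeros(n_muscles), np.ones(2 * n_joints)])
    a_eq = np.hstack([a_mat, np.eye(n_joints), -np.eye(n_joints)])
    bounds = [(0, 1)] * n_muscles + [(0, None)] * (2 * n_joints)
    res = linprog(c, A_eq=a_eq, b_eq=b, bounds=bounds, method="highs")
    if not res.success or res.fun > 1e-6:
        if res.success:
            slack = res.x[n_muscles : n_muscles + n_joints] + res.x[n_muscles + n_joints :]
            worst = int(np.argmax(slack))
            shortfall = float(slack[worst])
        else:
            worst, shortfall = 0, np.nan
        raise InfeasibleFrameError(
            f"frame {frame}: required moment at joint '{joint_names[worst]}' "
            f"unreachable (shortfall {shortfall:.4g})",
            joint=joint_names[worst],
            shortfall=shortfall,
            frame=frame,
        )


def solve_frame(
    task: ToyJointTask,
    t: int,
    params: list[MuscleParams],
    f_l: float = 1.0,
    f_v: float = 1.0,
    tol: float = 1e-12,
) -> np.ndarray:
    """Minimum-sum-of-squared-activations solution for one time frame.

    Tries the closed-form equality-constrained least-norm solution first;
    if any bound is active, falls back to a numerically polished convex QP
    (SLSQP).  The returned vector satisfies the moment equilibrium to
    better than 1e-6 and the bounds exactly.
    """
    a_mat = _gain_matrix(task, params, f_l, f_v)
    b = task.required_moments[:, t]

    # Closed form: a = A^T (A A^T)^+ b (minimum Euclidean norm).
    gram = a_mat @ a_mat.T
    a_ln = a_mat.T @ np.linalg.pinv(gram) @ b
    if np.all(a_ln >= -1e-12) and np.all(a_ln <= 1.0 + 1e-12):
        a_ln = np.clip(a_ln, 0.0, 1.0)
        if np.max(np.abs(a_mat @ a_ln - b)) < 1e-6:
            return a_ln

    _check_feasible(a_mat, b, task.joint_names, t)
    n = a_mat.shape[1]
    x0 = np.clip(a_ln, 0.0, 1.0)
    res = minimize(
        lambda a: float(a @ a),
        x0,
        jac=lambda a: 2.0 * a,
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a_mat @ a - b, "jac": lambda a: a_mat}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": tol},
    )
    a = np.clip(res.x, 0.0, 1.0)
    resid = np.max(np.abs(a_mat @ a - b))
    if resid >= 1e-6:
        raise InfeasibleFrameError(
            f"frame {t}: equilibrium residual {resid:.3g} exceeds 1e-6",
            frame=t,
        )
    return a


def simulate_model_activations(
    task: ToyJointTask,
    params: list[MuscleParams],
    subject_id: str = "S00",
    trial_id: str = "T00",
) -> ActivationMatrix:
    """Solve every frame and assemble the model-modality activation matrix."""
    n_time = task.required_moments.shape[1]
    cols = []
    for t in range(n_time):
        cols.append(solve_frame(task, t, params))
    values = np.column_stack(cols)
    return ActivationMatrix(
        values=values,
        muscle_labels=[p.name for p in params],
        subject_id=subject_id,
        trial_id=trial_id,
        modality="model",
    )


def default_toy_task(n_time: int = 101, scale: float = 1.0) -> ToyJointTask:
    """Two-joint (elevation, internal rotation) task over a normalized cycle.

    Moment arms (signed, in the table's length units) make the trapezius
    group the efficient elevator, the pectoralis / anterior-deltoid group
    the efficient internal rotator, and the posterior group the efficient
    external rotator.  Demands are three phase-specific bumps: elevation
    early (preparation), internal rotation mid-cycle (acceleration/impact),
    external rotation plus slight depression late (follow-through).
    """
    # Column order matches default_muscle_params():
    # TRPL1 TRPL2 TRPL3 TRPL4 DELT1 DELT2 DELT3 SUPRA INFRA SUBSCAP TMIN TMAJ PECM1 PECM2 PECM3
    elevation = np.array(
        [0.045, 0.040, 0.035, 0.030, 0.012, 0.010, -0.008, 0.020, -0.005, 0.0, -0.006, -0.015, 0.008, 0.0, -0.004]
    )
    int_rot = np.array(
        [0.0, 0.0, 0.002, 0.0, 0.025, -0.006, -0.022, 0.004, -0.028, 0.024, -0.020, 0.008, 0.030, 0.028, 0.022]
    )
    arms = np.vstack([elevation, int_rot])

    t = np.linspace(0.0, 1.0, n_time)
    bump = lambda c, s: np.exp(-((t - c) ** 2) / (2 * s**2))
    m_elev = 18.0 * bump(0.2, 0.08) - 5.0 * bump(0.8, 0.08)
    m_rot = 25.0 * bump(0.5, 0.08) - 18.0 * bump(0.8, 0.08)
    moments = scale * np.vstack([m_elev, m_rot])
    return ToyJointTask(
        moment_arms=arms,
        required_moments=moments,
        joint_names=["elevation", "internal_rotation"],
    )
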