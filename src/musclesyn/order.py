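"""Synergy-number selection and cross-validation of the chosen order.

The number of synergies k is chosen by a conjunction of three criteria
evaluated on VAF curves over a contiguous k range:

* global VAF > 90% (uncentered, whole matrix),
* every defined per-muscle (local) VAF > 0.75,
* adding the (k+1)-th synergy improves global VAF by < 5 percentage
  points ("dimensional analysis" / elbow criterion).

The smallest k satisfying all three is selected; if none qualifies the
largest tested k is returned with ``selected`` flagged False.  Split-half
reliability is computed as an advisory criterion (reported, not gated),
and a leave-one-out procedure quantifies how well synergies extracted
from n-1 trials reconstruct the held-out trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .containers import ActivationMatrix, SynergySet
from .errors import DomainError
from .nmf import global_vaf, local_vaf, nmf_decompose, normalize_synergies, reconstruct


def concatenate_trials(trials: list[ActivationMatrix]) -> ActivationMatrix:
    """Concatenate trials along time (shared muscle label order required)."""
    if not trials:
        raise DomainError("no trials to concatenate")
    first = trials[0]
    for t in trials[1:]:
        first.check_labels(t)
    return ActivationMatrix(
        values=np.concatenate([t.values for t in trials], axis=1),
        muscle_labels=first.muscle_labels,
        subject_id=first.subject_id,
        trial_id="concat",
        modality=first.modality,
    )


@dataclass
class OrderSelectionResult:
    """VAF curves, per-k criteria flags and the selected synergy number."""

    k_range: list[int]
    global_vaf_by_k: dict[int, float]
    local_vaf_by_k: dict[int, np.ndarray]
    slope_by_k: dict[int, float] = field(default_factory=dict)
    criteria_passed: dict[int, dict[str, bool]] = field(default_factory=dict)
    k_selected: int | None = None
    selected: bool = False
    split_half_by_k: dict[int, dict] = field(default_factory=dict)
    synergies_by_k: dict[int, SynergySet] = field(default_factory=dict)


def vaf_curve(
    m: ActivationMatrix,
    k_range=range(1, 7),
    n_restarts: int = 50,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrderSelectionResult:
    """Global and local VAF per k, sharing one master seed across orders."""
    k_range = list(k_range)
    g, loc, syn = {}, {}, {}
    for k in k_range:
        s = nmf_decompose(m, k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=seed)
        m_hat = reconstruct(s)
        g[k] = global_vaf(m, m_hat)
        loc[k] = local_vaf(m, m_hat)
        syn[k] = s
    return OrderSelectionResult(
        k_range=k_range, global_vaf_by_k=g, local_vaf_by_k=loc, synergies_by_k=syn
    )


def select_order(
    curves: OrderSelectionResult,
    global_thresh: float = 0.90,
    local_thresh: float = 0.75,
    slope_thresh: float = 5.0,
) -> OrderSelectionResult:
    """Apply the conjunctive three-criterion rule to precomputed curves.

    ``slope_thresh`` is in percentage points of global VAF improvement
    from k to k+1; the largest tested k has no successor and its slope is
    taken as 0 (trivially satisfied).  Local VAF of muscles with zero
    activity is undefined (NaN) and excluded from the conjunction.
    """
    ks = sorted(curves.k_range)
    for k in ks:
        g = curves.global_vaf_by_k[k]
        loc = curves.local_vaf_by_k[k]
        if k + 1 in curves.global_vaf_by_k:
            slope = 100.0 * (curves.global_vaf_by_k[k + 1] - g)
        else:
            slope = 0.0
        curves.slope_by_k[k] = slope
        defined = loc[~np.isnan(loc)]
        curves.criteria_passed[k] = {
            "global": g > global_thresh,
            "local": bool(np.all(defined > local_thresh)) if defined.size else True,
            "slope": slope < slope_thresh,
        }
    for k in ks:
        if all(curves.criteria_passed[k].values()):
            curves.k_selected = k
            curves.selected = True
            return curves
    curves.k_selected = ks[-1]
    curves.selected = False
    return curves


def fit_coefficients(w: np.ndarray, m: ActivationMatrix) -> np.ndarray:
    """Nonnegative least-squares fit of coefficients with W held fixed.

    Solved columnwise: for each time sample t, min ||w c_t - m_t||_2 over
    c_t >= 0.
    """
    values = m.values if isinstance(m, ActivationMatrix) else np.asarray(m, float)
    c = np.empty((w.shape[1], values.shape[1]))
    for t in range(values.shape[1]):
        c[:, t] = nnls(w, values[:, t])[0]
    return c


def leave_one_out_vaf(
    trials: list[ActivationMatrix],
    k: int,
    n_restarts: int = 20,
    seed: int = 0,
) -> dict:
    """Leave-one-out generalization of the k-synergy structure.

    For each held-out trial, weights are extracted from the remaining
    trials concatenated along time, coefficients for the held-out trial
    are refit by nonnegative least squares, and the generalization gap
    dVAF = held-out VAF - within-sample VAF (the VAF of a factorization
    fitted on the held-out trial itself) is recorded.
    """
    if len(trials) < 2:
        raise DomainError("leave-one-out needs at least 2 trials")
    first = trials[0]
    for t in trials[1:]:
        first.check_labels(t)
    deltas, heldout_vafs = [], []
    for i, held in enumerate(trials):
        rest = concatenate_trials([t for j, t in enumerate(trials) if j != i])
        s = nmf_decompose(rest, k, n_restarts=n_restarts, seed=seed + i)
        c_out = fit_coefficients(s.w, held)
        v_out = global_vaf(held, s.w @ c_out)
        s_in = nmf_decompose(held, k, n_restarts=n_restarts, seed=seed + i)
        v_in = global_vaf(held, reconstruct(s_in))
        heldout_vafs.append(v_out)
        deltas.append(v_out - v_in)
    deltas = np.asarray(deltas)
    return {
        "delta_vaf": deltas,
        "mean": float(deltas.mean()),
        "sd": float(deltas.std(ddof=1)) if len(deltas) > 1 else 0.0,
        "heldout_vaf": np.asarray(heldout_vafs),
    }


def split_half_consistency(
    trials: list[ActivationMatrix],
    k: int,
    n_splits: int = 10,
    seed: int = 0,
    n_restarts: int = 20,
) -> dict:
    """Random split-half consistency of the k-synergy structure.

    Each split partitions the trials into two halves; synergies are
    extracted from each half (trials concatenated along time), matched by
    maximal total weight similarity, and compared: scalar-product (cosine)
    similarity of matched W columns, Pearson correlation of matched
    trial-averaged coefficient waveforms, plus ICC(3,1) of the matched
    weight table (muscles x two halves) and its SEM, averaged over splits.
    """
    from .compare import match_synergies, pearson_similarity, scalar_product_similarity
    from .reliability import icc_3_1, sem_from_icc

    if len(trials) < 2:
        raise DomainError("split-half needs at least 2 trials")
    rng = np.random.default_rng(seed)
    n = len(trials)
    n_time = trials[0].n_time

    w_sims, c_sims, iccs, sems = [], [], [], []
    for split in range(n_splits):
        perm = rng.permutation(n)
        half_a = [trials[i] for i in perm[: n // 2]]
        half_b = [trials[i] for i in perm[n // 2 :]]
        sa = nmf_decompose(concatenate_trials(half_a), k, n_restarts=n_restarts, seed=seed + 7 * split)
        sb = nmf_decompose(concatenate_trials(half_b), k, n_restarts=n_restarts, seed=seed + 7 * split + 3)
        pairs = match_synergies(sa, sb)
        w_row = [scalar_product_similarity(sa.w[:, i], sb.w[:, j]) for i, j in pairs]
        ca = sa.c.reshape(k, len(half_a), n_time).mean(axis=1)
        cb = sb.c.reshape(k, len(half_b), n_time).mean(axis=1)
        c_row = [pearson_similarity(ca[i], cb[j]) for i, j in pairs]
        w_sims.append(w_row)
        c_sims.append(c_row)
        icc_row, sem_row = [], []
        for i, j in pairs:
            table = np.column_stack([sa.w[:, i], sb.w[:, j]])
            icc = icc_3_1(table)
            if np.isnan(icc):
                continue
            icc = min(max(icc, 0.0), 1.0)
            sd = float(np.std(table.mean(axis=1), ddof=1))
            icc_row.append(icc)
            sem_row.append(sem_from_icc(sd, icc))
        iccs.append(np.mean(icc_row) if icc_row else np.nan)
        sems.append(np.mean(sem_row) if sem_row else np.nan)

    w_sims = np.asarray(w_sims)
    c_sims = np.asarray(c_sims)
    return {
        "w_similarity": w_sims,
        "c_similarity": c_sims,
        "w_mean": float(w_sims.mean()),
        "w_sd": float(w_sims.std(ddof=1)) if w_sims.size > 1 else 0.0,
        "c_mean": float(c_sims.mean()),
        "c_sd": float(c_sims.std(ddof=1)) if c_sims.size > 1 else 0.0,
        "icc": float(np.nanmean(iccs)),
        "sem": float(np.nanmean(sems)),
    }
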