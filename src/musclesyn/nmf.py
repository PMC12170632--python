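"""Non-negative matrix factorization of muscle activation matrices.

A muscle activation matrix M (muscles x time) is decomposed into a synergy
weight matrix W (muscles x k) and a coefficient matrix C (k x time),

    min_{W,C >= 0}  || M - W C ||_F^2,

fitted by Lee-Seung multiplicative updates for the Frobenius objective.
The optimizer is restarted from multiple random initializations and the
factorization with the lowest reconstruction error is kept; each run stops
when the relative change in objective between iterations falls below a
tolerance or an iteration cap is reached.

Reconstruction quality is quantified by the uncentered variance accounted
for (VAF): globally, 1 - ||M - WC||_F^2 / ||M||_F^2, and per muscle row.
"""

from __future__ import annotations

import numpy as np

from .containers import ActivationMatrix, SynergySet
from .errors import DomainError, InvalidOrderError, UndefinedVAFError

# Guard added to multiplicative-update denominators to avoid division by zero.
_EPS = 1e-12


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ActivationMatrix) else np.asarray(m, dtype=float)


def nmf_decompose(
    m: ActivationMatrix,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 100,
    tol: float = 1e-6,
    seed: int | None = None,
) -> SynergySet:
    """Factorize ``m`` into ``k`` synergies by best-of-restarts multiplicative updates.

    Parameters
    ----------
    m : ActivationMatrix or nonnegative ndarray
    k : int
        Number of synergies, ``1 <= k <= min(n_muscles, n_time)``.
    n_restarts : int
        Random initializations; the lowest-error run is returned.
    max_iter : int
        Iteration cap per run.
    tol : float
        Relative objective-change convergence tolerance.
    seed : int
        Master seed; restart r uses ``seed + r`` so runs are reproducible.

    Returns
    -------
    SynergySet
        Normalized (unit-norm W columns), with the winning run's objective
        trace in ``objective_history``.
    """
    values = _as_values(m)
    labels = (
        m.muscle_labels
        if isinstance(m, ActivationMatrix)
        else [f"m{i}" for i in range(values.shape[0])]
    )
    if np.any(values < 0):
        raise DomainError("NMF input must be nonnegative")
    n_rows, n_cols = values.shape
    if not (1 <= k <= min(n_rows, n_cols)):
        raise InvalidOrderError(f"k={k} outside [1, {min(n_rows, n_cols)}]")

    if seed is None:
        seed = 0
    scale = float(values.mean()) or 1.0

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        # Uniform(0,1] init scaled by the matrix mean.
        w = (1.0 - rng.random((n_rows, k))) * scale
        c = (1.0 - rng.random((k, n_cols))) * scale
        w, c, history, converged = _multiplicative_updates(values, w, c, max_iter, tol)
        obj = history[-1]
        if best is None or obj < best[2][-1]:
            best = (w, c, history, converged)

    w, c, history, converged = best
    s = SynergySet(
        w=w,
        c=c,
        muscle_labels=labels,
        objective=float(history[-1]),
        restarts_used=n_restarts,
        converged=converged,
        objective_history=np.asarray(history),
    )
    return normalize_synergies(s)


def _multiplicative_updates(values, w, c, max_iter, tol):
    """One run of Lee-Seung Frobenius updates; returns factors and objective trace."""
    history = [float(np.linalg.norm(values - w @ c))]
    converged = False
    for _ in range(max_iter):
        c *= (w.T @ values) / (w.T @ w @ c + _EPS)
        w *= (values @ c.T) / (w @ (c @ c.T) + _EPS)
        obj = float(np.linalg.norm(values - w @ c))
        history.append(obj)
        prev = history[-2]
        if prev > 0 and abs(prev - obj) / prev < tol:
            converged = True
            break
    return w, c, history, converged


def reconstruct(s: SynergySet) -> np.ndarray:
    """Return the nonnegative reconstruction W @ C."""
    return s.w @ s.c


def global_vaf(m, m_hat) -> float:
    """Uncentered global VAF: 1 - ||M - M_hat||_F^2 / ||M||_F^2."""
    values = _as_values(m)
    m_hat = np.asarray(m_hat, dtype=float)
    if values.shape != m_hat.shape:
        raise DomainError(f"shape mismatch {values.shape} vs {m_hat.shape}")
    denom = float(np.sum(values**2))
    if denom == 0.0:
        raise UndefinedVAFError("VAF undefined for an all-zero matrix")
    return 1.0 - float(np.sum((values - m_hat) ** 2)) / denom


def local_vaf(m, m_hat) -> np.ndarray:
    """Per-muscle (rowwise) uncentered VAF; NaN flags all-zero rows."""
    values = _as_values(m)
    m_hat = np.asarray(m_hat, dtype=float)
    if values.shape != m_hat.shape:
        raise DomainError(f"shape mismatch {values.shape} vs {m_hat.shape}")
    denom = np.sum(values**2, axis=1)
    out = np.full(values.shape[0], np.nan)
    ok = denom > 0
    out[ok] = 1.0 - np.sum((values - m_hat) ** 2, axis=1)[ok] / denom[ok]
    return out


def normalize_synergies(s: SynergySet) -> SynergySet:
    """Rescale each W column to unit Euclidean norm, moving the scale into C.

    The product W @ C is unchanged.  All-zero columns cannot be normalized;
    they are left as-is and their indices recorded in ``zero_columns``.
    """
    norms = np.linalg.norm(s.w, axis=0)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return SynergySet(
        w=s.w / safe,
        c=s.c * safe[:, None],
        muscle_labels=s.muscle_labels,
        objective=s.objective,
        restarts_used=s.restarts_used,
        converged=s.converged,
        objective_history=s.objective_history,
        zero_columns=tuple(np.flatnonzero(zero)),
    )
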