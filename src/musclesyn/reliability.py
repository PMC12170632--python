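"""Inter-trial reliability metrics: CV, ICC(3,1) and SEM.

Movement consistency across repeated trials is summarized by the
coefficient of variation per subject, the two-way mixed-effects,
single-measure, consistency intraclass correlation ICC(3,1), and the
standard error of measurement SEM = SD * sqrt(1 - ICC).  Acceptable
reliability is conventionally CV < 10% and ICC > 0.80.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD / mean.  NaN if the mean is zero."""
    values = np.asarray(values, dtype=float)
    mean = values.mean()
    if mean == 0:
        return np.nan
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    return float(100.0 * sd / mean)


def icc_3_1(table, variant: str = "consistency") -> float:
    """ICC(3,1) from a subjects x trials table via two-way ANOVA mean squares.

    consistency: (BMS - EMS) / (BMS + (k-1) EMS)
    agreement:   (BMS - EMS) / (BMS + (k-1) EMS + k (JMS - EMS) / n)

    where BMS/JMS/EMS are the between-subject, between-trial and residual
    mean squares, n subjects, k trials.  Degenerate tables (zero total
    variance) return NaN.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DomainError("ICC needs a 2-D table with >= 2 subjects and >= 2 trials")
    n, k = table.shape
    grand = table.mean()
    if np.allclose(table, grand):
        return np.nan
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if variant == "consistency":
        denom = bms + (k - 1) * ems
    elif variant == "agreement":
        denom = bms + (k - 1) * ems + k * (jms - ems) / n
    else:
        raise DomainError(f"unknown ICC variant '{variant}'")
    if denom == 0:
        return np.nan
    return float((bms - ems) / denom)


def sem_from_icc(sd: float, icc: float) -> float:
    """Standard error of measurement: SD * sqrt(1 - ICC)."""
    if not 0.0 <= icc <= 1.0:
        raise DomainError(f"ICC must lie in [0, 1], got {icc}")
    if sd < 0:
        raise DomainError("SD must be nonnegative")
    return float(sd * np.sqrt(1.0 - icc))


def reliability_report(
    kinematics,
    cv_thresh: float = 10.0,
    icc_thresh: float = 0.80,
):
    """Per-variable CV / ICC / SEM table with acceptability flags.

    ``kinematics`` is a tidy DataFrame with ``subject``, ``trial`` and one
    column per kinematic variable (as emitted by the synthetic cohort
    generator).  CV is computed per subject and summarized as mean +/- SD;
    ICC(3,1) is computed on the subjects x trials table; SEM uses the
    between-subject SD of subject means.  Acceptable: CV < 10% and
    ICC > 0.80.  Zero within-subject variance yields CV = 0 and ICC = 1.
    """
    import pandas as pd

    variables = [c for c in kinematics.columns if c not in ("subject", "trial")]
    rows = []
    for var in variables:
        wide = kinematics.pivot(index="subject", columns="trial", values=var)
        if wide.isna().any().any():
            raise DomainError(f"unbalanced table for variable '{var}'")
        table = wide.to_numpy()
        cvs = np.array([coefficient_of_variation(row) for row in table])
        icc = icc_3_1(table)
        sd_between = float(np.std(table.mean(axis=1), ddof=1))
        icc_clipped = min(max(icc, 0.0), 1.0) if not np.isnan(icc) else np.nan
        sem = sem_from_icc(sd_between, icc_clipped) if not np.isnan(icc) else np.nan
        rows.append(
            {
                "variable": var,
                "mean": float(table.mean()),
                "sd": sd_between,
                "cv_mean": float(np.nanmean(cvs)),
                "cv_sd": float(np.nanstd(cvs, ddof=1)) if len(cvs) > 1 else 0.0,
                "icc": icc,
                "sem": sem,
                "acceptable": bool(
                    not np.isnan(icc)
                    and np.nanmean(cvs) < cv_thresh
                    and icc > icc_thresh
                ),
            }
        )
    return pd.DataFrame(rows)
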