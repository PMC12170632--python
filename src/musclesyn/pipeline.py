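"""Config-driven end-to-end pipeline and CSV interchange.

One call — :func:`run_pipeline` — takes a :class:`RunConfig` and produces
a run directory holding, per modality: activation envelopes, VAF curves,
the order-selection decision, synergy weight/coefficient matrices at the
selected order, the EMG-vs-model similarity report, the kinematic
reliability report, and a manifest echoing the configuration, seed and a
hash of the parameters that produced every table.

The interchange format is CSV throughout: activation matrices are stored
time-sample-per-row (first column the 0-100% time index, one column per
muscle label), so a trial file opens directly in any spreadsheet or
plotting tool.  Every written table begins with a ``# config_hash:``
comment line tying it to its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import ActivationMatrix
from .errors import DomainError, InvalidConfigError, LabelMismatchError, PipelineStageError
from .nmf import nmf_decompose
from .order import concatenate_trials, select_order, vaf_curve
from .compare import compare_decompositions
from .reliability import reliability_report
from .synth import SynthConfig, generate_cohort, generate_kinematic_trials

log = logging.getLogger("musclesyn")

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Pipeline parameters with the study-protocol defaults."""

    output_dir: str = "musclesyn_run"
    seed: int = 42
    # synthetic cohort
    n_muscles: int = 15
    n_time: int = 101
    k_true: int = 3
    n_subjects: int = 20
    n_trials: int = 5
    snr_db: float = 20.0
    modality_perturb: float = 0.10
    # factorization protocol
    n_restarts: int = 50
    max_iter: int = 100
    tol: float = 1e-6
    k_min: int = 1
    k_max: int = 6
    # order-selection thresholds
    global_thresh: float = 0.90
    local_thresh: float = 0.75
    slope_thresh: float = 5.0
    # reliability thresholds
    cv_thresh: float = 10.0
    icc_thresh: float = 0.80

    def __post_init__(self):
        if not 1 <= self.k_min <= self.k_max:
            raise InvalidConfigError("need 1 <= k_min <= k_max")
        if self.n_restarts < 1 or self.max_iter < 1 or self.tol <= 0:
            raise InvalidConfigError("n_restarts, max_iter must be >= 1 and tol > 0")
        for name in ("global_thresh", "local_thresh"):
            if not 0 < getattr(self, name) < 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a config file, rejecting unknown keys."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        # analysis parameters only — output location does not affect results
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]

    def synth_config(self) -> SynthConfig:
        return SynthConfig(
            n_muscles=self.n_muscles,
            n_time=self.n_time,
            k_true=self.k_true,
            n_subjects=self.n_subjects,
            n_trials=self.n_trials,
            snr_db=self.snr_db,
            modality_perturb=self.modality_perturb,
            seed=self.seed,
        )


# ---------------------------------------------------------------------------
# CSV interchange


def write_activation_csv(m: ActivationMatrix, path, config_hash: str | None = None) -> None:
    """Write a trial as CSV: rows = time samples, first column the time index."""
    path = Path(path)
    df = pd.DataFrame(m.values.T, columns=m.muscle_labels)
    df.insert(0, "time", np.arange(m.n_time))
    with open(path, "w", newline="") as fh:
        if config_hash:
            fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_activation_csv(
    path, subject_id: str = "S00", trial_id: str = "T00", modality: str = "emg"
) -> ActivationMatrix:
    """Read a trial CSV written by :func:`write_activation_csv`.

    Rejects empty files, duplicate labels, ragged rows, non-numeric cells
    and negative values, naming the offending cell where applicable.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise DomainError(f"{path}: empty input file")
    with open(path) as fh:
        header = ""
        for line in fh:
            if not line.startswith("#"):
                header = line.strip()
                break
    raw_labels = header.split(",")[1:]
    if raw_labels and len(set(raw_labels)) != len(raw_labels):
        raise LabelMismatchError(f"{path}: duplicate muscle labels in header")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise DomainError(f"{path}: empty input file") from None
    except pd.errors.ParserError as exc:
        raise DomainError(f"{path}: malformed CSV ({exc})") from None
    if df.shape[1] < 2:
        raise DomainError(f"{path}: expected a time column plus muscle columns")
    labels = list(df.columns[1:])
    if len(set(labels)) != len(labels):
        raise LabelMismatchError(f"{path}: duplicate muscle labels in header")
    body = df.iloc[:, 1:]
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~body.isna()
    if bad.any().any():
        r = int(bad.any(axis=1).idxmax())
        c = bad.columns[bad.loc[r].argmax()]
        raise DomainError(f"{path}: non-numeric cell at row {r}, column '{c}'")
    if numeric.isna().any().any():
        raise DomainError(f"{path}: missing values in body")
    values = numeric.to_numpy().T
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise DomainError(
            f"{path}: negative value at row {j}, column '{labels[i]}'"
        )
    return ActivationMatrix(
        values=values,
        muscle_labels=labels,
        subject_id=subject_id,
        trial_id=trial_id,
        modality=modality,
    )


def write_synergy_csv(s, w_path, c_path, config_hash: str | None = None) -> None:
    """Persist a SynergySet as a (W, C) CSV pair with labelled rows/columns."""
    w_df = pd.DataFrame(
        s.w, index=s.muscle_labels, columns=[f"W{i+1}" for i in range(s.k)]
    )
    c_df = pd.DataFrame(s.c, index=[f"C{i+1}" for i in range(s.k)])
    for df, path, index_label in ((w_df, w_path, "muscle"), (c_df, c_path, "component")):
        with open(path, "w", newline="") as fh:
            if config_hash:
                fh.write(f"# config_hash: {config_hash}\n")
            df.to_csv(fh, index_label=index_label, float_format=_FLOAT_FMT)


def _write_table(df: pd.DataFrame, path, config_hash: str) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def write_cohort(trials: list[ActivationMatrix], out_dir, config_hash: str = "") -> pd.DataFrame:
    """Write one CSV per trial plus a manifest mapping file -> identifiers."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for m in trials:
        fname = f"{m.subject_id}_{m.trial_id}_{m.modality}.csv"
        write_activation_csv(m, out_dir / fname, config_hash or None)
        records.append(
            {
                "file": fname,
                "subject": m.subject_id,
                "trial": m.trial_id,
                "modality": m.modality,
            }
        )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


# ---------------------------------------------------------------------------
# Orchestration


def _group_by_subject(trials):
    by_subject: dict[str, dict[str, list[ActivationMatrix]]] = {}
    for m in trials:
        by_subject.setdefault(m.subject_id, {}).setdefault(m.modality, []).append(m)
    return by_subject


def run_pipeline(config: RunConfig, trials: list[ActivationMatrix] | None = None) -> Path:
    """Run the full analysis and return the populated run directory.

    With ``trials=None`` a synthetic cohort is generated from the config;
    otherwise the provided trials (both modalities) are analyzed.  Output
    is deterministic for a fixed config and seed.
    """
    chash = config.config_hash()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        if trials is None:
            trials = generate_cohort(config.synth_config())
            kinematics = generate_kinematic_trials(config.synth_config())
        else:
            kinematics = None
    except Exception as exc:  # pragma: no cover - config errors surface earlier
        raise PipelineStageError("synth", str(exc)) from exc

    log.info("cohort: %d trials", len(trials))
    write_cohort(trials, out / "envelopes", chash)

    by_subject = _group_by_subject(trials)
    curve_rows, decision_rows, sim_rows = [], [], []
    syn_dir = out / "synergies"
    syn_dir.mkdir(exist_ok=True)
    selected: dict[tuple[str, str], object] = {}

    for subject in sorted(by_subject):
        for modality in ("emg", "model"):
            if modality not in by_subject[subject]:
                continue
            try:
                concat = concatenate_trials(by_subject[subject][modality])
                curves = vaf_curve(
                    concat,
                    k_range=range(config.k_min, config.k_max + 1),
                    n_restarts=config.n_restarts,
                    max_iter=config.max_iter,
                    tol=config.tol,
                    seed=config.seed,
                )
                curves = select_order(
                    curves,
                    global_thresh=config.global_thresh,
                    local_thresh=config.local_thresh,
                    slope_thresh=config.slope_thresh,
                )
            except Exception as exc:
                raise PipelineStageError(
                    "order_select", f"subject {subject} ({modality}): {exc}"
                ) from exc
            for k in curves.k_range:
                curve_rows.append(
                    {
                        "subject": subject,
                        "modality": modality,
                        "k": k,
                        "global_vaf": curves.global_vaf_by_k[k],
                        "min_local_vaf": float(np.nanmin(curves.local_vaf_by_k[k])),
                        "slope_pp": curves.slope_by_k[k],
                    }
                )
            ksel = curves.k_selected
            decision_rows.append(
                {
                    "subject": subject,
                    "modality": modality,
                    "k_selected": ksel,
                    "selected": curves.selected,
                    "global_vaf_at_k": curves.global_vaf_by_k[ksel],
                }
            )
            s = curves.synergies_by_k[ksel]
            selected[(subject, modality)] = s
            write_synergy_csv(
                s,
                syn_dir / f"{subject}_{modality}_W.csv",
                syn_dir / f"{subject}_{modality}_C.csv",
                chash,
            )

        if (subject, "emg") in selected and (subject, "model") in selected:
            a = selected[(subject, "emg")]
            b_sel = selected[(subject, "model")]
            # Compare at the EMG-selected order: refit the model modality at
            # that k if its own selection differs.
            if b_sel.k != a.k:
                concat = concatenate_trials(by_subject[subject]["model"])
                b_sel = nmf_decompose(
                    concat, a.k, n_restarts=config.n_restarts,
                    max_iter=config.max_iter, tol=config.tol, seed=config.seed,
                )
            try:
                report = compare_decompositions(a, b_sel)
            except Exception as exc:
                raise PipelineStageError("compare", f"subject {subject}: {exc}") from exc
            for _, row in report.to_frame().iterrows():
                sim_rows.append(
                    {"subject": subject, "feature": row["feature"], "similarity": row["similarity"]}
                )

    _write_table(pd.DataFrame(curve_rows), out / "vaf_curves.csv", chash)
    _write_table(pd.DataFrame(decision_rows), out / "order_selection.csv", chash)
    if sim_rows:
        sim_df = pd.DataFrame(sim_rows)
        _write_table(sim_df, out / "similarity.csv", chash)
        summary = (
            sim_df.groupby("feature")["similarity"].agg(["mean", "std"]).reset_index()
        )
        _write_table(summary, out / "similarity_summary.csv", chash)
    if kinematics is not None:
        rel = reliability_report(
            kinematics, cv_thresh=config.cv_thresh, icc_thresh=config.icc_thresh
        )
        _write_table(rel, out / "reliability.csv", chash)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": chash,
        "n_trials_analyzed": len(trials),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
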