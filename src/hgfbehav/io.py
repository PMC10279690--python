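"""Tab-separated on-disk formats for schedules, responses and results.

The canonical per-trial table has one row per trial and columns
(session, run, trial, tone, contingency, trial_type, rotation, prediction,
perception, confidence).  A sidecar metadata block of ``# key<TAB>value``
comment lines (seed, generator version) precedes the header.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import pandas as pd

from . import __version__ as _pkg_version
from .task import TaskSchedule, TrialResponses, TrialSpec

__all__ = [
    "trials_frame",
    "write_trials",
    "read_trials",
    "write_evidence",
    "read_evidence",
    "read_zenodo_deposit",
]

_COLUMNS = ("session", "run", "trial", "tone", "contingency", "trial_type",
            "rotation", "prediction", "perception", "confidence")


def trials_frame(schedule: TaskSchedule,
                 responses: Optional[TrialResponses] = None) -> pd.DataFrame:
    rows = []
    slices = schedule.run_slices or [(schedule.run_id, 0, len(schedule))]
    for run_id, start, stop in slices:
        for i in range(start, stop):
            tr = schedule.trials[i]
            row = {
                "session": schedule.session_id,
                "run": run_id,
                "trial": tr.index,
                "tone": tr.tone,
                "contingency": tr.contingency,
                "trial_type": tr.trial_type,
                "rotation": tr.rotation,
                "prediction": "",
                "perception": "",
                "confidence": "",
            }
            if responses is not None:
                row["prediction"] = responses.prediction[i]
                row["perception"] = responses.perception[i]
                if responses.confidence is not None \
                        and responses.confidence[i] is not None:
                    row["confidence"] = responses.confidence[i]
            rows.append(row)
    return pd.DataFrame(rows, columns=list(_COLUMNS))


def write_trials(path, schedule: TaskSchedule,
                 responses: Optional[TrialResponses] = None,
                 metadata: Optional[Dict[str, str]] = None) -> None:
    meta = {"generator": f"hgfbehav {_pkg_version}",
            "seed": "" if schedule.seed is None else str(schedule.seed)}
    meta.update(metadata or {})
    df = trials_frame(schedule, responses)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}\t{v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_trials(path) -> Tuple[TaskSchedule, TrialResponses, Dict[str, str]]:
    """Read a canonical per-trial TSV back into schedule + responses."""
    meta: Dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                body = line[1:].strip()
                if "\t" in body:
                    k, v = body.split("\t", 1)
                    meta[k.strip()] = v.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)

    trials = []
    run_slices = []
    predictions, percepts, confidences = [], [], []
    current_run = None
    start = 0
    block = 0
    for i, row in df.iterrows():
        run = int(row["run"])
        if current_run is None:
            current_run = run
        elif run != current_run:
            run_slices.append((current_run, start, i))
            current_run, start = run, i
        idx = int(row["trial"])
        trials.append(TrialSpec(
            index=idx, tone=row["tone"], contingency=row["contingency"],
            trial_type=row["trial_type"], rotation=row["rotation"],
            block_index=(idx - 1) // 8,
        ))
        predictions.append(row["prediction"] or "missing")
        percepts.append(row["perception"] or "missing")
        c = row.get("confidence", "")
        confidences.append(int(c) if c not in ("", "missing") else None)
    if current_run is not None:
        run_slices.append((current_run, start, len(trials)))
    single_run_id = run_slices[0][0] if len(run_slices) == 1 else 0
    if len(run_slices) == 1:
        run_slices = []

    session = int(df["session"].iloc[0]) if len(df) else 1
    seed = int(meta["seed"]) if meta.get("seed") else None
    schedule = TaskSchedule(
        trials=trials,
        run_id=single_run_id,
        session_id=session, seed=seed, run_slices=run_slices,
    )
    responses = TrialResponses(
        prediction=predictions, perception=percepts,
        confidence=confidences if any(c is not None for c in confidences)
        else None,
    )
    return schedule, responses, meta


def write_evidence(path, evidence, model_names, subject_ids=None) -> None:
    df = pd.DataFrame(evidence, columns=list(model_names))
    df.insert(0, "subject", subject_ids if subject_ids is not None
              else range(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)


def read_evidence(path):
    df = pd.read_csv(path, sep="\t")
    subjects = df["subject"].tolist()
    models = [c for c in df.columns if c != "subject"]
    return df[models].to_numpy(dtype=float), models, subjects


def read_zenodo_deposit(path):
    """Adapter for the original study's deposited behavioral data.

    The deposit's file layout and column semantics are not documented in
    machine-readable form; this adapter must be completed against the
    actual files.  Until then it raises, so that analyses cannot silently
    run on a misread layout.
    """
    raise NotImplementedError(
        "The deposited-data layout is undocumented; map its columns onto "
        "the canonical per-trial TSV (see write_trials) and use read_trials."
    )
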