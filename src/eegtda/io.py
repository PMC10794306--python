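"""On-disk study layout: recordings, events, participants, epochs.

Per-subject recordings live in a single compressed array container
(``sub-XX_recording.npz``: data in uV, channel names, sampling rate) next
to a BIDS-inspired events TSV (onset_sample, session, role, category,
image_id). Study-level metadata goes in ``participants.csv``
(subject_id, group, moca, age_years, severity). Cleaned epochs are one
``.npz`` per subject plus a JSON sidecar recording the preprocessing
parameters and the drop log.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Epoch, EpochSet
from .synthetic import Recording, SubjectProfile

__all__ = ["write_study", "read_study", "write_epochs", "read_epochs"]


def write_study(study, out_dir) -> Path:
    """Write (profile, recording) pairs; returns the study directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants = []
    for profile, rec in study:
        participants.append({
            "subject_id": profile.subject_id,
            "group": profile.group,
            "moca": profile.moca,
            "age_years": round(profile.age_years, 2),
            "severity": round(profile.severity, 6),
        })
        np.savez_compressed(
            out / f"{rec.subject_id}_recording.npz",
            data=rec.data,
            channel_names=np.array(rec.channel_names),
            sampling_rate_hz=rec.sampling_rate_hz,
        )
        rec.events.to_csv(out / f"{rec.subject_id}_events.tsv",
                          sep="\t", index=False)
    pd.DataFrame(participants).to_csv(out / "participants.csv", index=False)
    return out


def read_study(study_dir):
    """Read a written study back as (SubjectProfile, Recording) pairs."""
    study_dir = Path(study_dir)
    participants = pd.read_csv(study_dir / "participants.csv")
    study = []
    for _, row in participants.iterrows():
        sid = row["subject_id"]
        with np.load(study_dir / f"{sid}_recording.npz") as npz:
            data = npz["data"]
            channels = tuple(str(c) for c in npz["channel_names"])
            fs = float(npz["sampling_rate_hz"])
        events = pd.read_csv(study_dir / f"{sid}_events.tsv", sep="\t")
        profile = SubjectProfile(
            subject_id=sid, group=row["group"],
            severity=float(row.get("severity", 0.0)),
            moca=int(row["moca"]), age_years=float(row["age_years"]))
        rec = Recording(
            subject_id=sid, channel_names=channels, sampling_rate_hz=fs,
            data=data, events=events,
            meta={"group": profile.group, "moca": profile.moca,
                  "severity": profile.severity})
        study.append((profile, rec))
    return study


def write_epochs(epoch_set: EpochSet, out_dir, params: dict | None = None) -> Path:
    """One compressed container + JSON sidecar per subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sid = epoch_set.subject_id
    stack = np.stack([ep.data for ep in epoch_set.epochs]) if epoch_set.epochs \
        else np.empty((0, 0, 0))
    np.savez_compressed(
        out / f"{sid}_epochs.npz",
        epochs=stack,
        condition=np.array([ep.condition for ep in epoch_set.epochs]),
        session=np.array([ep.session_index for ep in epoch_set.epochs],
                         dtype=int),
    )
    sidecar = {
        "subject_id": sid,
        "group": epoch_set.group,
        "moca": epoch_set.moca,
        "epoch_length_s": epoch_set.epoch_length_s,
        "sampling_rate_hz": epoch_set.sampling_rate_hz,
        "n_epochs": len(epoch_set),
        "dropped": list(epoch_set.dropped),
        "parameters": params or {},
    }
    (out / f"{sid}_epochs.json").write_text(json.dumps(sidecar, indent=2))
    return out


def read_epochs(out_dir, subject_id: str) -> EpochSet:
    out = Path(out_dir)
    sidecar = json.loads((out / f"{subject_id}_epochs.json").read_text())
    with np.load(out / f"{subject_id}_epochs.npz") as npz:
        stack = npz["epochs"]
        conditions = [str(c) for c in npz["condition"]]
        sessions = [int(s) for s in npz["session"]]
    epochs = [Epoch(data=stack[i], condition=conditions[i],
                    session_index=sessions[i]) for i in range(len(conditions))]
    moca = sidecar["moca"]
    return EpochSet(
        subject_id=subject_id, group=sidecar["group"],
        moca=int(moca) if moca is not None else None,
        epochs=epochs,
        epoch_length_s=sidecar["epoch_length_s"],
        sampling_rate_hz=sidecar["sampling_rate_hz"],
        dropped=list(sidecar["dropped"]),
    )
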