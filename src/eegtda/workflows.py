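"""In-memory convenience workflows (no on-disk artifacts).

Glue for scripts and tests that want a feature table straight from a
study configuration without the staged pipeline's file layout.
"""

from __future__ import annotations

import pandas as pd

from .preprocess import preprocess_recording
from .synthetic import StudyConfig, generate_study
from .tda import feature_table

__all__ = ["study_features"]


def study_features(config: StudyConfig, epoch_length_s: float = 2.0,
                   threshold_uv: float = 100.0, low_hz: float = 1.0,
                   high_hz: float = 40.0, zscore: bool = False):
    """Generate a study and return (profiles, per-epoch feature table)."""
    study = generate_study(config)
    profiles = [p for p, _ in study]
    table = feature_table(
        (preprocess_recording(rec, low_hz=low_hz, high_hz=high_hz,
                              epoch_length_s=epoch_length_s,
                              threshold_uv=threshold_uv)
         for _, rec in study),
        zscore=zscore)
    return profiles, table


def profiles_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id, "group": p.group, "moca": p.moca,
        "severity": p.severity, "age_years": p.age_years,
    } for p in profiles])
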