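"""Band-pass filtering, epoching, and EMD-based artifact rejection.

Fixed pipeline order: filter the continuous recording (zero-phase
4th-order Butterworth, 1-40 Hz by default), cut 2-s epochs from stimulus
onsets, then clean each epoch channel-wise by empirical mode
decomposition with a 100 uV component threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .emd import emd_clean
from .synthetic import Recording

__all__ = ["Epoch", "EpochSet", "bandpass", "segment_epochs",
           "clean_epochs", "preprocess_recording"]

logger = logging.getLogger(__name__)


@dataclass
class Epoch:
    data: np.ndarray        # (n_channels, n_samples) uV
    condition: str          # "TGT" | "IGN"
    session_index: int


@dataclass
class EpochSet:
    """All usable epochs of one subject, with subject metadata."""

    subject_id: str
    group: str | None
    moca: int | None
    epochs: list
    epoch_length_s: float
    sampling_rate_hz: float
    dropped: list = field(default_factory=list)  # drop log (reason strings)

    def __post_init__(self):
        shapes = {ep.data.shape for ep in self.epochs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent epoch shapes: {shapes}")
        bad = {ep.condition for ep in self.epochs} - {"TGT", "IGN"}
        if bad:
            raise ValueError(f"unknown epoch conditions: {bad}")

    def __len__(self):
        return len(self.epochs)

    def condition_mask(self, condition: str) -> np.ndarray:
        if condition == "ALL":
            return np.ones(len(self.epochs), dtype=bool)
        return np.array([ep.condition == condition for ep in self.epochs])


def bandpass(recording: Recording, low_hz: float = 1.0,
             high_hz: float = 40.0, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass of a continuous recording.

    Forward-backward filtering (no group delay); returns a new Recording.
    """
    nyq = recording.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for fs="
            f"{recording.sampling_rate_hz}")
    sos = butter(order, [low_hz, high_hz], btype="bandpass",
                 fs=recording.sampling_rate_hz, output="sos")
    filtered = sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=filtered, events=recording.events.copy())


def segment_epochs(recording: Recording, epoch_length_s: float = 2.0,
                   cue_as_target: bool = True) -> EpochSet:
    """Cut [onset, onset + epoch_length) windows at each stimulus event.

    Cue displays are counted as targets by default (``cue_as_target``),
    otherwise excluded. Events whose window overruns the recording end
    are dropped and logged. An empty event list yields an empty EpochSet.
    """
    n_samp = int(round(epoch_length_s * recording.sampling_rate_hz))
    epochs, dropped = [], []
    for _, ev in recording.events.iterrows():
        onset = int(ev["onset_sample"])
        role = ev["role"]
        if role == "cue":
            if not cue_as_target:
                continue
            condition = "TGT"
        elif role == "target":
            condition = "TGT"
        elif role == "ignored":
            condition = "IGN"
        else:
            raise ValueError(f"unknown event role {role!r}")
        if onset + n_samp > recording.n_samples:
            msg = (f"event at sample {onset} (session {ev['session']}) "
                   f"overruns recording end; dropped")
            dropped.append(msg)
            logger.warning("%s: %s", recording.subject_id, msg)
            continue
        epochs.append(Epoch(
            data=recording.data[:, onset:onset + n_samp].copy(),
            condition=condition,
            session_index=int(ev["session"]),
        ))
    meta = recording.meta or {}
    return EpochSet(
        subject_id=recording.subject_id,
        group=meta.get("group"),
        moca=meta.get("moca"),
        epochs=epochs,
        epoch_length_s=epoch_length_s,
        sampling_rate_hz=recording.sampling_rate_hz,
        dropped=dropped,
    )


def clean_epochs(epoch_set: EpochSet, threshold_uv: float = 100.0) -> EpochSet:
    """EMD-clean every epoch (per channel, per epoch); returns a new set."""
    cleaned = [
        Epoch(data=emd_clean(ep.data, threshold_uv=threshold_uv),
              condition=ep.condition, session_index=ep.session_index)
        for ep in epoch_set.epochs
    ]
    return replace(epoch_set, epochs=cleaned)


def preprocess_recording(recording: Recording, low_hz: float = 1.0,
                         high_hz: float = 40.0, epoch_length_s: float = 2.0,
                         threshold_uv: float = 100.0,
                         cue_as_target: bool = True) -> EpochSet:
    """Full preprocessing chain: band-pass -> epoch -> EMD-clean."""
    filtered = bandpass(recording, low_hz=low_hz, high_hz=high_hz)
    segmented = segment_epochs(filtered, epoch_length_s=epoch_length_s,
                               cue_as_target=cue_as_target)
    return clean_epochs(segmented, threshold_uv=threshold_uv)
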