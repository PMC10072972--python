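"""Recording containers and the preprocessing chain.

The processing order is notch → band-pass → common-average reference →
downsample → epoching.  All filters are applied forward–backward
(zero-phase), which matters downstream: the phase-lag index is built on
instantaneous phase, and a causal filter would add a frequency-dependent
phase shift to every channel.

Epochs are event-locked to the right-paw contact (RC) gait event: each
epoch spans ``[RC - 1.0 s, RC + 1.5 s)``, i.e. 1,250 samples at 500 Hz,
covering two full preparation phases and one full walking phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

#: Gait events in cycle order.  RO/RC = right hind paw off/contacting the
#: ground, LO/LC = the same for the left paw.  A full cycle is
#: LC → RO → RC → LO → (LC), with the 750-ms double-support interval
#: LC→RO called the preparation phase.
GAIT_EVENTS = ("LC", "RO", "RC", "LO")

#: Locomotion-task condition labels: flat→flat, flat→uneven, uneven→flat.
CONDITIONS = ("FF", "FU", "UF")

#: Cortical region labels used for the 32-channel grid.
REGIONS = ("LMO", "RMO", "LSS", "RSS", "RSP", "VIS")

_NEXT_EVENT = {"LC": "RO", "RO": "RC", "RC": "LO", "LO": "LC"}


class GaitEventError(ValueError):
    """A gait-event table violates the cyclic event grammar."""


@dataclass
class Recording:
    """Multichannel electrophysiology recording.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, arbitrary signal units.
    rate
        Sampling rate in Hz.
    channel_names
        Unique channel labels, one per row of ``data``.
    region_map
        Mapping channel name → cortical region label.
    """

    data: np.ndarray
    rate: float
    channel_names: list[str]
    region_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one channel name per data row required")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate


class GaitEventTable:
    """Ordered gait events with their locomotion condition.

    Wraps a DataFrame with columns ``time_s`` (strictly increasing),
    ``event`` (one of LC/RO/RC/LO, following the cyclic grammar) and
    ``condition`` (FF/FU/UF).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        required = ["time_s", "event", "condition"]
        if not all(c in df.columns for c in required):
            raise GaitEventError(f"event table needs columns {required}")
        self.df = df.loc[:, required].reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        t = self.df["time_s"].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise GaitEventError(f"event times not strictly increasing at row {bad}")
        ev = self.df["event"].tolist()
        for i, e in enumerate(ev):
            if e not in GAIT_EVENTS:
                raise GaitEventError(f"unknown event {e!r} at row {i}")
            if i and ev[i - 1] in _NEXT_EVENT and _NEXT_EVENT[ev[i - 1]] != e:
                raise GaitEventError(
                    f"event {e!r} at row {i} breaks the LC→RO→RC→LO cycle"
                )
        for i, c in enumerate(self.df["condition"]):
            if c not in CONDITIONS:
                raise GaitEventError(f"unknown condition {c!r} at row {i}")

    def __len__(self) -> int:
        return len(self.df)

    def events(self, label: str) -> pd.DataFrame:
        return self.df[self.df["event"] == label]

    def shifted(self, delta_s: float) -> "GaitEventTable":
        df = self.df.copy()
        df["time_s"] = df["time_s"] + delta_s
        return GaitEventTable(df)


@dataclass
class EpochSet:
    """Event-locked epochs: ``(n_epochs, n_channels, n_samples)``.

    ``t0_offset_s`` is the epoch start relative to the RC event
    (−1.0 s by default), so sample ``k`` sits at
    ``t0_offset_s + k / rate`` seconds relative to RC.
    """

    data: np.ndarray
    rate: float
    conditions: np.ndarray
    channel_names: list[str]
    region_map: dict[str, str] = field(default_factory=dict)
    t0_offset_s: float = -1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        if len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def condition_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.conditions.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def apply_filters(
    rec: Recording,
    notch_hz: float | None = 50.0,
    band: tuple[float, float] = (3.0, 50.0),
    notch_q: float = 30.0,
    order: int = 4,
) -> Recording:
    """Notch then band-pass filter, both zero-phase.

    A 2nd-order IIR notch (quality factor ``notch_q``) removes the mains
    tone; a Butterworth band-pass of the given ``order`` keeps the 3–50 Hz
    band the analysis lives in.  Both run forward–backward so the phase
    response is identically zero.
    """
    low, high = band
    nyq = rec.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyq}) Hz")
    data = rec.data
    if notch_hz is not None:
        if not (0 < notch_hz < nyq):
            raise ValueError(f"notch frequency {notch_hz} outside (0, {nyq}) Hz")
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=-1)
    sos = signal.butter(order, band, btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=-1)
    return replace(rec, data=data)


def rereference_car(rec: Recording) -> Recording:
    """Common-average reference: subtract the across-channel mean per sample."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return replace(rec, data=data)


def downsample(rec: Recording, target_hz: float = 500.0) -> Recording:
    """Decimate by an integer factor (signal must already be band-limited).

    The 3–50 Hz band-pass guarantees no content above the 250-Hz target
    Nyquist, so plain sample picking is alias-free and exactly preserves
    the retained samples.
    """
    factor = rec.rate / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"rate {rec.rate} Hz is not an integer multiple of target {target_hz} Hz"
        )
    factor = int(round(factor))
    if factor == 1:
        return replace(rec, data=rec.data.copy())
    n_keep = (rec.n_samples // factor) * factor
    data = rec.data[:, :n_keep:factor]
    return replace(rec, data=data, rate=float(target_hz))


def extract_epochs(
    rec: Recording,
    events: GaitEventTable,
    pre_s: float = 1.0,
    total_s: float = 2.5,
    lock_event: str = "RC",
) -> EpochSet:
    """Cut one epoch per interior lock event (default RC).

    The epoch window is half-open, ``[t_ev - pre_s, t_ev - pre_s + total_s)``,
    with the event time snapped to the nearest sample.  Events whose window
    sticks out of the recording are skipped and counted in a warning.
    """
    n_samp = int(round(total_s * rec.rate))
    pre_samp = int(round(pre_s * rec.rate))
    rows = events.events(lock_event)
    if rows.empty:
        warnings.warn(f"no {lock_event} events; returning empty EpochSet")
        return EpochSet(
            np.empty((0, rec.n_channels, n_samp)),
            rec.rate,
            np.empty(0, dtype=object),
            rec.channel_names,
            rec.region_map,
            t0_offset_s=-pre_s,
        )
    epochs, conds, skipped = [], [], 0
    for _, row in rows.iterrows():
        start = int(round(row["time_s"] * rec.rate)) - pre_samp
        if start < 0 or start + n_samp > rec.n_samples:
            skipped += 1
            continue
        epochs.append(rec.data[:, start : start + n_samp])
        conds.append(row["condition"])
    if skipped:
        warnings.warn(f"skipped {skipped} {lock_event} events too close to the edges")
    data = (
        np.stack(epochs)
        if epochs
        else np.empty((0, rec.n_channels, n_samp))
    )
    return EpochSet(
        data,
        rec.rate,
        np.asarray(conds, dtype=object),
        rec.channel_names,
        rec.region_map,
        t0_offset_s=-pre_s,
    )


def preprocess_recording(
    rec: Recording,
    events: GaitEventTable,
    notch_hz: float | None = 50.0,
    band: tuple[float, float] = (3.0, 50.0),
    target_hz: float = 500.0,
    car: bool = True,
    cleaner=None,
) -> EpochSet:
    """Full chain: notch → band-pass → CAR → downsample → epoch.

    ``cleaner`` is a pluggable hook ``Recording -> Recording`` run after
    re-referencing, in the position an artifact-removal step (e.g. ICA
    component rejection) would occupy; the default is a no-op.  ``car``
    can be disabled for controlled few-channel inputs, where subtracting
    the across-channel mean is degenerate (with 2 channels it forces the
    two signals to be exact negatives of each other).
    """
    rec = apply_filters(rec, notch_hz=notch_hz, band=band)
    if car:
        rec = rereference_car(rec)
    if cleaner is not None:
        rec = cleaner(rec)
    rec = downsample(rec, target_hz)
    return extract_epochs(rec, events)
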