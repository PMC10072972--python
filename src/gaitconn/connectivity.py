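"""Sliding-window phase-lag index and gait-phase-collapsed connectivity.

The phase-lag index (PLI) between two signals x, y is

    PLI = | (1/N) * sum_n sign(dphi(t_n)) |,

where ``dphi`` is the instantaneous phase difference from the analytic
(Hilbert) signals, wrapped to (-pi, pi], and ``sign(0) = 0``.  A value of
0 means no coupling or coupling with a phase difference centred on 0 mod
pi; 1 means complete phase locking at a nonzero lag.  Because a common
source contributes with zero lag, consistent *nonzero*-lag coupling is
what the index rewards — which is why it is popular for EEG, where volume
conduction produces exactly the zero-lag confound.

Windowing follows the gait-cycle geometry: 250-ms windows with 50 %
overlap scan each 2.5-s RC-locked epoch, giving 19 windows; the 750-ms
preparation phase is covered by 5 of them, and its connectivity is
summarized by averaging the three non-overlapping ones (1st, 3rd, 5th).
Each 250-ms walking sub-phase coincides exactly with one window.

The analytic signal is computed once over the full epoch and then sliced
into windows, so Hilbert edge artifacts affect only the epoch ends, not
every window boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .preprocess import EpochSet
from .synth import PHASES

__all__ = [
    "WindowGrid",
    "ConnectivityTensor",
    "PhaseConnectivity",
    "instantaneous_phase",
    "wrap_phase",
    "pli_pair",
    "pli_matrix",
    "sliding_pli",
    "collapse_phases",
    "condition_average",
]


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window layout over an epoch.

    ``start_offsets_s`` are window starts relative to the epoch start;
    sample indices are ``round(offset * rate)``, which for the standard
    2.5-s/500-Hz epoch (125-sample window, 62.5-sample step) yields
    19 windows at samples 0, 62, 125, ..., 1125.
    """

    win_len_s: float = 0.250
    step_s: float = 0.125
    epoch_len_s: float = 2.5

    def __post_init__(self) -> None:
        if self.win_len_s <= 0 or self.step_s <= 0:
            raise ValueError("window length and step must be positive")
        if self.epoch_len_s < self.win_len_s - 1e-12:
            raise ValueError("window longer than the epoch")

    @property
    def n_windows(self) -> int:
        return int(np.floor((self.epoch_len_s - self.win_len_s) / self.step_s + 1e-9)) + 1

    @property
    def start_offsets_s(self) -> np.ndarray:
        return np.arange(self.n_windows) * self.step_s

    def start_samples(self, rate: float) -> np.ndarray:
        return np.round(self.start_offsets_s * rate).astype(int)

    def win_samples(self, rate: float) -> int:
        return int(round(self.win_len_s * rate))

    def is_standard(self, rate: float) -> bool:
        """The 2.5-s epoch / 250-ms window / 50 %-overlap grid at 500 Hz."""
        return (
            abs(self.win_len_s - 0.250) < 1e-9
            and abs(self.step_s - 0.125) < 1e-9
            and abs(self.epoch_len_s - 2.5) < 1e-9
            and abs(rate - 500.0) < 1e-9
        )


# window indices on the standard 19-window grid
PREPARATION_WINDOWS = (0, 2, 4)  # the 1st, 3rd, 5th of the 5 covering LC→RO
WALKING_WINDOWS = {"RO_RC": 6, "RC_LO": 8, "LO_LC": 10}


@dataclass
class ConnectivityTensor:
    """PLI values, ``(n_epochs, n_windows, n_channels, n_channels)``."""

    values: np.ndarray
    grid: WindowGrid
    conditions: np.ndarray
    rate: float = 500.0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.values.ndim != 4:
            raise ValueError("tensor must be 4-D (epochs x windows x ch x ch)")


@dataclass
class PhaseConnectivity:
    """Gait-phase-collapsed PLI, ``(n_epochs, 4, n_channels, n_channels)``.

    Phase order is LC→RO (preparation), RO→RC, RC→LO, LO→LC.
    """

    values: np.ndarray
    conditions: np.ndarray
    phases: tuple[str, ...] = PHASES
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if self.values.ndim != 4 or self.values.shape[1] != len(self.phases):
            raise ValueError("phase connectivity must be (epochs x phases x ch x ch)")


def instantaneous_phase(epoch: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians) of each channel via the analytic signal.

    ``epoch`` is ``(..., n_samples)``; the Hilbert transform runs along the
    last axis.  Phase is amplitude-invariant: scaling a channel leaves its
    phase untouched.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.shape[-1] < 8:
        raise ValueError("need at least 8 samples for a meaningful phase estimate")
    if not np.all(np.isfinite(epoch)):
        raise ValueError("non-finite values in input")
    return np.angle(hilbert(epoch, axis=-1))


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap phase differences to the interval (-pi, pi]."""
    out = np.mod(dphi, 2.0 * np.pi)
    out = np.where(out > np.pi, out - 2.0 * np.pi, out)
    return out


def pli_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLI of one signal pair from their instantaneous-phase series."""
    phase_x = np.asarray(phase_x, dtype=float)
    phase_y = np.asarray(phase_y, dtype=float)
    if phase_x.shape != phase_y.shape:
        raise ValueError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValueError("need at least 2 samples")
    dphi = wrap_phase(phase_x - phase_y)
    return float(np.abs(np.mean(np.sign(dphi))))


def pli_matrix(phases: np.ndarray) -> np.ndarray:
    """All-pairs PLI from a ``(n_channels, n_samples)`` phase array.

    Vectorized over channel pairs; the result is symmetric with a zero
    diagonal and entries in [0, 1].
    """
    dphi = wrap_phase(phases[:, None, :] - phases[None, :, :])
    pli = np.abs(np.mean(np.sign(dphi), axis=-1))
    np.fill_diagonal(pli, 0.0)
    return pli


def sliding_pli(epochs: EpochSet, grid: WindowGrid | None = None) -> ConnectivityTensor:
    """Windowed PLI tensor over all epochs.

    The analytic phase is computed once per full epoch, then sliced by the
    window grid; each slice yields one ``n_channels x n_channels`` PLI
    matrix.
    """
    if grid is None:
        grid = WindowGrid(epoch_len_s=epochs.n_samples / epochs.rate)
    win = grid.win_samples(epochs.rate)
    starts = grid.start_samples(epochs.rate)
    if win > epochs.n_samples:
        raise ValueError("window longer than the epoch")
    n_ep, n_ch = epochs.data.shape[0], epochs.data.shape[1]
    out = np.zeros((n_ep, len(starts), n_ch, n_ch))
    for e in range(n_ep):
        phases = instantaneous_phase(epochs.data[e])
        for w, s in enumerate(starts):
            out[e, w] = pli_matrix(phases[:, s : s + win])
    return ConnectivityTensor(
        values=out,
        grid=grid,
        conditions=epochs.conditions.copy(),
        rate=epochs.rate,
        channel_names=list(epochs.channel_names),
    )


def collapse_phases(tensor: ConnectivityTensor) -> PhaseConnectivity:
    """Collapse the 19-window tensor to the four gait phases.

    Preparation (LC→RO, −1,000…−250 ms relative to RC) is the mean of the
    1st, 3rd and 5th of the five windows covering it — the three
    non-overlapping ones.  Each walking sub-phase (RO→RC, RC→LO, LO→LC)
    is the single window exactly coincident with it (starts at −250, 0,
    +250 ms).  Requires the standard grid; anything else raises.
    """
    if not tensor.grid.is_standard(tensor.rate) or tensor.values.shape[1] != 19:
        raise ValueError(
            "phase collapse requires the standard grid: 2.5-s epochs at "
            "500 Hz scanned by 250-ms windows with 50% overlap (19 windows)"
        )
    v = tensor.values
    prep = v[:, list(PREPARATION_WINDOWS)].mean(axis=1)
    walking = [v[:, WALKING_WINDOWS[p]] for p in PHASES[1:]]
    out = np.stack([prep] + walking, axis=1)
    return PhaseConnectivity(
        values=out,
        conditions=tensor.conditions.copy(),
        channel_names=list(tensor.channel_names),
    )


def condition_average(
    phase_conn: PhaseConnectivity, conditions: tuple[str, ...] | None = None
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Element-wise mean over epochs sharing a condition.

    Returns ``(n_conditions, 4, n_channels, n_channels)`` and the
    condition labels actually present (a requested condition with zero
    epochs is omitted with a warning).
    """
    import warnings

    labels = np.asarray(phase_conn.conditions, dtype=str)
    if conditions is None:
        from .preprocess import CONDITIONS

        conditions = tuple(c for c in CONDITIONS if c in set(labels))
        extra = tuple(sorted(set(labels) - set(CONDITIONS)))
        conditions = conditions + extra
    kept = []
    mats = []
    for cond in conditions:
        mask = labels == cond
        if not mask.any():
            warnings.warn(f"condition {cond!r} has no epochs; omitted from average")
            continue
        kept.append(cond)
        mats.append(phase_conn.values[mask].mean(axis=0))
    if not mats:
        raise ValueError("no epochs in any requested condition")
    return np.stack(mats), tuple(kept)
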