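"""Synthetic phase-lag-coupled oscillator recordings with gait schedules.

The generator emulates the statistical structure of gait-phase-aligned
multichannel cortical EEG: 32 channels grouped into 6 regions, narrow-band
oscillatory sources shared across designated channel pairs with a fixed
nonzero time lag, coupling strengths that switch with the gait phase
(LC→RO, RO→RC, RC→LO, LO→LC) and the locomotion condition (FF, FU, UF),
and additive white noise.

Source model
------------
Two kinds of sources are mixed:

* every *coupled pair* owns a shared narrow-band oscillator
  ``s(t) = cos(2*pi*f*t + W(t))`` — a fixed carrier ``f`` plus a Wiener
  phase drift ``W`` with diffusion ``drift_sd`` (rad/sqrt(s)).  Seen
  through two channels with a constant nonzero lag it keeps a
  near-constant phase difference and drives the pair's phase-lag index
  toward 1, predictably;
* every channel additionally carries a *private background*: Gaussian
  noise band-limited to ``background_band`` (the analysis band,
  3–50 Hz), scaled to the RMS of a unit oscillator.

The broadband background is what keeps the *null* phase-lag index low:
the instantaneous-phase difference of two independent band-limited noise
channels decorrelates within a few tens of milliseconds, so its sign
mixes inside every 250-ms window (measured null level ~0.19 per window).
A narrow-band background cannot do this — any phase drift fast enough to
mix the sign inside one window broadens the source far beyond the
analysis band.

Coupling
--------
``coupling_profiles[condition][phase]`` lists ``(chan_i, chan_j, strength)``
triples.  Each coupled pair owns a dedicated source: channel ``i`` sees it
with zero lag, channel ``j`` delayed by ``lag_s`` (a quarter carrier cycle
by default, centring the pair's phase difference at pi/2).  The shared
source enters with amplitude equal to the coupling strength of the gait
phase/condition active at that instant; each channel's private source
amplitude shrinks correspondingly, keeping total amplitude near 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    CONDITIONS,
    GAIT_EVENTS,
    GaitEventTable,
    Recording,
    REGIONS,
)

import pandas as pd

#: Gait phases in cycle order; the first is the 750-ms preparation
#: (double-support) phase, the other three are 250-ms walking sub-phases.
PHASES = ("LC_RO", "RO_RC", "RC_LO", "LO_LC")

#: Idealized durations of the four gait phases, seconds.
PHASE_DURATIONS_S = (0.750, 0.250, 0.250, 0.250)

CYCLE_S = float(sum(PHASE_DURATIONS_S))  # 1.5 s


class ConfigurationError(ValueError):
    """A simulation config references unknown channels, phases or conditions."""


def default_region_map(n_channels: int = 32) -> dict[str, str]:
    """Channel → region assignment for the standard 32-channel grid.

    Six cortical regions: left/right somatomotor (LMO, RMO; 6 channels
    each), left/right somatosensory (LSS, RSS; 6 each), retrosplenial
    (RSP; 4) and visual (VIS; 4).
    """
    if n_channels != 32:
        raise ConfigurationError("the default region map is defined for 32 channels")
    sizes = {"LMO": 6, "RMO": 6, "LSS": 6, "RSS": 6, "RSP": 4, "VIS": 4}
    out: dict[str, str] = {}
    ch = 0
    for region in REGIONS:
        for _ in range(sizes[region]):
            out[f"ch{ch:02d}"] = region
            ch += 1
    return out


def default_coupling_profiles() -> dict[str, dict[str, list[tuple[int, int, float]]]]:
    """Phase- and condition-dependent coupling structure.

    Qualitative shape: strong somatomotor–retrosplenial coupling during the
    preparation phase identically in all conditions, sustained RMO–RSP
    coupling during the right-paw swing, and condition-differentiated
    somatosensory coupling in the two late walking sub-phases (strongest
    left-somatosensory involvement after unexpected uneven-terrain contact,
    weakest coupling when the upcoming terrain is predictable).  Channel
    indices refer to the default region map (LMO 0–5, RMO 6–11, LSS 12–17,
    RSS 18–23, RSP 24–27, VIS 28–31).
    """
    prep = [(6, 24, 0.9), (0, 25, 0.7), (1, 7, 0.6)]  # RMO-RSP, LMO-RSP, LMO-RMO
    swing_r = [(6, 24, 0.8)]  # RMO-RSP
    profiles: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        "FF": {
            "LC_RO": prep,
            "RO_RC": swing_r,
            "RC_LO": [(12, 26, 0.3)],  # LSS-RSP, mild
            "LO_LC": [(13, 27, 0.7)],  # LSS-RSP
        },
        "FU": {
            "LC_RO": prep,
            "RO_RC": swing_r,
            "RC_LO": [(12, 26, 0.9), (14, 2, 0.7)],  # LSS-RSP burst, LSS-LMO
            "LO_LC": [(8, 25, 0.8)],  # RMO-RSP
        },
        "UF": {
            "LC_RO": prep,
            "RO_RC": swing_r,
            "RC_LO": [(12, 26, 0.5)],
            "LO_LC": [(13, 27, 0.2)],
        },
    }
    return profiles


def recovery_coupling_profiles() -> dict[str, dict[str, list[tuple[int, int, float]]]]:
    """Coupling layout for parameter-recovery studies.

    Four designated channel pairs, each with a distinct, well-separated
    coupling strength per gait phase (a Latin-square-like gradient over
    {0.0, 0.3, 0.6, 0.9}), identical across conditions, so the
    phase-collapsed PLI can be checked against the generative ordering.
    """
    gradients = {
        (0, 24): (0.9, 0.6, 0.3, 0.0),
        (6, 26): (0.0, 0.9, 0.6, 0.3),
        (12, 18): (0.6, 0.3, 0.0, 0.9),
        (13, 28): (0.3, 0.0, 0.9, 0.6),
    }
    by_phase = {
        phase: [
            (i, j, g[pi]) for (i, j), g in gradients.items() if g[pi] > 0
        ]
        for pi, phase in enumerate(PHASES)
    }
    return {cond: by_phase for cond in CONDITIONS}


@dataclass
class SimConfig:
    """Parameters of one synthetic recording session.

    ``coupling_profiles`` maps condition → phase → list of
    ``(chan_i, chan_j, strength)`` with strengths in [0, 1].  ``lag_s``
    must be nonzero: a zero lag centres the phase difference at 0, whose
    signum averages to 0 and yields a phase-lag index of 0 by design.
    """

    n_channels: int = 32
    sampling_rate: float = 2000.0
    regions: dict[str, str] = field(default_factory=default_region_map)
    n_epochs_per_condition: int = 30
    carrier_freq: float = 8.0
    coupling_profiles: dict = field(default_factory=default_coupling_profiles)
    lag_s: float = 1.0 / 32.0  # quarter cycle of the 8-Hz carrier
    noise_sigma: float = 0.2
    drift_sd: float = 2.0  # rad/sqrt(s); Wiener phase diffusion of shared sources
    background_band: tuple[float, float] = (3.0, 50.0)
    line_amp: float = 0.0  # optional 50-Hz mains tone amplitude
    line_freq: float = 50.0
    jitter_s: float = 0.0  # uniform jitter on gait-event intervals
    seed: int = 0

    def __post_init__(self) -> None:
        if not (3.0 < self.carrier_freq < 50.0):
            raise ConfigurationError(
                "carrier frequency must lie strictly inside the 3-50 Hz band"
            )
        if self.lag_s == 0.0:
            raise ConfigurationError("lag_s must be nonzero for coupled pairs")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")
        for cond, by_phase in self.coupling_profiles.items():
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r} in profiles")
            for phase, pairs in by_phase.items():
                if phase not in PHASES:
                    raise ConfigurationError(f"unknown gait phase {phase!r} in profiles")
                for i, j, g in pairs:
                    if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                        raise ConfigurationError(
                            f"coupling pair ({i}, {j}) references unknown channel"
                        )
                    if i == j:
                        raise ConfigurationError("self-coupling is not allowed")
                    if not (0.0 <= g <= 1.0):
                        raise ConfigurationError(
                            f"coupling strength {g} outside [0, 1]"
                        )

    @property
    def channel_names(self) -> list[str]:
        return [f"ch{i:02d}" for i in range(self.n_channels)]


@dataclass
class GroundTruth:
    """Generative coupling structure actually used, for recovery checks.

    ``coupling`` is a ``(n_conditions, 4, n_channels, n_channels)``
    symmetric array of coupling strengths, ordered like ``conditions``
    and :data:`PHASES`; ``schedule`` is the gait-event table generated.
    """

    coupling: np.ndarray
    conditions: tuple[str, ...]
    phases: tuple[str, ...]
    schedule: GaitEventTable

    def coupled_pairs(self) -> list[tuple[int, int]]:
        mask = (self.coupling > 0).any(axis=(0, 1))
        ii, jj = np.nonzero(np.triu(mask, k=1))
        return list(zip(ii.tolist(), jj.tolist()))


def _coupling_tensor(config: SimConfig) -> tuple[np.ndarray, tuple[str, ...]]:
    conds = tuple(c for c in CONDITIONS if c in config.coupling_profiles)
    n = config.n_channels
    out = np.zeros((len(conds), len(PHASES), n, n))
    for ci, cond in enumerate(conds):
        for pi, phase in enumerate(PHASES):
            for i, j, g in config.coupling_profiles[cond].get(phase, []):
                out[ci, pi, i, j] = g
                out[ci, pi, j, i] = g
    return out, conds


def generate_gait_schedule(
    config: SimConfig,
    duration_s: float,
    condition_sequence: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> GaitEventTable:
    """Repeating LC, RO, RC, LO events with 750/250/250/250-ms intervals.

    Only complete 1.5-s cycles are emitted; each cycle carries one
    condition label, taken from ``condition_sequence`` (cycled if shorter
    than the schedule) or drawn uniformly at random.  With ``jitter_s``
    set, each interval gets an independent uniform perturbation.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    conds = tuple(c for c in CONDITIONS if c in config.coupling_profiles)
    rows = []
    t = 0.0
    cycle = 0
    while True:
        intervals = np.array(PHASE_DURATIONS_S)
        if config.jitter_s > 0:
            intervals = intervals + rng.uniform(
                -config.jitter_s, config.jitter_s, size=4
            )
        if t + intervals.sum() > duration_s + 1e-9:
            break
        if condition_sequence is not None:
            cond = condition_sequence[cycle % len(condition_sequence)]
        else:
            cond = conds[rng.integers(len(conds))]
        # events at the start of each phase: LC opens the cycle
        offsets = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
        for ev, off in zip(GAIT_EVENTS, offsets):
            rows.append((t + off, ev, cond))
        t += intervals.sum()
        cycle += 1
    if not rows:
        warnings.warn(
            f"duration {duration_s} s is shorter than one 1.5-s gait cycle; "
            "returning an empty schedule"
        )
        return GaitEventTable(
            pd.DataFrame(columns=["time_s", "event", "condition"]), validate=False
        )
    df = pd.DataFrame(rows, columns=["time_s", "event", "condition"])
    return GaitEventTable(df)


def _phase_segments(schedule: GaitEventTable) -> list[tuple[float, float, str, str]]:
    """(t_start, t_end, phase, condition) for every complete phase interval."""
    df = schedule.df
    segs = []
    times = df["time_s"].to_numpy()
    events = df["event"].tolist()
    conds = df["condition"].tolist()
    phase_of_event = {"LC": "LC_RO", "RO": "RO_RC", "RC": "RC_LO", "LO": "LO_LC"}
    for k in range(len(df) - 1):
        segs.append((times[k], times[k + 1], phase_of_event[events[k]], conds[k]))
    # final LO→LC interval runs to the nominal end of the last cycle
    if events and events[-1] == "LO":
        segs.append(
            (times[-1], times[-1] + PHASE_DURATIONS_S[3], "LO_LC", conds[-1])
        )
    return segs


def _wiener_oscillator(
    n: int, rate: float, freq: float, drift_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Instantaneous phase of one source: carrier ramp + Wiener drift."""
    t = np.arange(n) / rate
    phase = 2.0 * np.pi * freq * t
    if drift_sd > 0:
        steps = rng.normal(0.0, drift_sd / np.sqrt(rate), size=n)
        phase = phase + np.cumsum(steps)
    return phase


def simulate_recording(
    config: SimConfig,
    duration_s: float | None = None,
    condition_sequence: list[str] | None = None,
) -> tuple[Recording, GaitEventTable, GroundTruth]:
    """Simulate one session: recording, gait schedule and ground truth.

    Channel ``i`` at time ``t`` is a sum of lagged shared sources weighted
    by the coupling strength of the gait phase/condition active at ``t``,
    plus a private source scaled to keep unit total amplitude, plus white
    Gaussian noise of SD ``noise_sigma`` (and an optional mains tone).
    Bit-reproducible for a fixed config (including seed).

    By default the session is sized and condition-balanced so that every
    condition contributes ``n_epochs_per_condition`` RC-locked epochs with
    a full ±(1.0/1.5)-s context window inside the recording.
    """
    rng = np.random.default_rng(config.seed)
    coupling, conds = _coupling_tensor(config)

    if condition_sequence is None:
        seq = np.repeat(conds, config.n_epochs_per_condition)
        condition_sequence = list(rng.permutation(seq))
    n_cycles = len(condition_sequence)
    if duration_s is None:
        # pad one extra second so the last cycle's RC keeps +1.5 s of context
        duration_s = n_cycles * CYCLE_S + 1.0

    schedule = generate_gait_schedule(
        config, duration_s, condition_sequence=condition_sequence, rng=rng
    )
    n = int(round(duration_s * config.sampling_rate))
    rate = config.sampling_rate
    lag_samp = int(round(config.lag_s * rate))
    if lag_samp == 0:
        raise ConfigurationError("lag_s is below one sample at this sampling rate")

    # per-sample (phase, condition) indices; -1 outside complete cycles
    phase_idx = np.full(n, -1, dtype=int)
    cond_idx = np.full(n, -1, dtype=int)
    cond_pos = {c: k for k, c in enumerate(conds)}
    phase_pos = {p: k for k, p in enumerate(PHASES)}
    for t0, t1, phase, cond in _phase_segments(schedule):
        a = int(round(t0 * rate))
        b = min(int(round(t1 * rate)), n)
        phase_idx[a:b] = phase_pos[phase]
        cond_idx[a:b] = cond_pos[cond]

    pairs = sorted(
        {
            (min(i, j), max(i, j))
            for by_phase in config.coupling_profiles.values()
            for plist in by_phase.values()
            for i, j, _ in plist
        }
    )

    data = np.zeros((config.n_channels, n))
    shared_amp = np.zeros((config.n_channels, n))  # running per-channel total g
    inside = phase_idx >= 0
    for i, j in pairs:
        # per-sample coupling strength of this pair under the active
        # (condition, phase); zero outside complete cycles
        g = np.zeros(n)
        g[inside] = coupling[cond_idx[inside], phase_idx[inside], i, j]
        if not np.any(g):
            continue
        # simulate with a lead-in of lag_samp samples so the lagged copy
        # is defined from t = 0: src[lag:] is s(t), src[:n] is s(t - lag)
        phase = _wiener_oscillator(n + abs(lag_samp), rate, config.carrier_freq,
                                   config.drift_sd, rng)
        src = np.cos(phase)
        data[i] += g * src[abs(lag_samp):]
        data[j] += g * src[:n]
        shared_amp[i] += g
        shared_amp[j] += g

    # private backgrounds: band-limited noise at amplitude 1 - total shared
    # amplitude (floored at 0), scaled to the RMS of a unit oscillator
    from scipy import signal as _signal

    sos = _signal.butter(
        4, config.background_band, btype="bandpass", fs=rate, output="sos"
    )
    for ch in range(config.n_channels):
        bg = _signal.sosfiltfilt(sos, rng.normal(0.0, 1.0, size=n))
        bg *= (1.0 / np.sqrt(2.0)) / max(bg.std(), 1e-12)
        own_amp = np.clip(1.0 - shared_amp[ch], 0.0, None)
        data[ch] += own_amp * bg

    if config.noise_sigma > 0:
        data += rng.normal(0.0, config.noise_sigma, size=data.shape)
    if config.line_amp > 0:
        t = np.arange(n) / rate
        data += config.line_amp * np.sin(2 * np.pi * config.line_freq * t)

    rec = Recording(
        data=data,
        rate=rate,
        channel_names=config.channel_names,
        region_map=config.regions,
    )
    truth = GroundTruth(
        coupling=coupling, conditions=conds, phases=PHASES, schedule=schedule
    )
    return rec, schedule, truth
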