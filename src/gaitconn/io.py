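"""Readers and writers for the pipeline's on-disk formats.

Delimited text is comma-separated UTF-8 with a '.' decimal and a
mandatory header row.  A recording CSV has one column per channel (header
= channel names) and one sample per line; the sampling rate and the
channel→region map travel in a JSON sidecar ``<path>.meta.json``.  EDF is
supported for signals (16-bit, physical units interpreted as microvolts);
reading uses MNE, writing a minimal built-in EDF encoder.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet, GaitEventTable, Recording
from .synth import GroundTruth


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------- recordings

def write_recording_csv(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {"rate_hz": rec.rate, "region_map": rec.region_map}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_recording_csv(path: str | Path, rate: float | None = None) -> Recording:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: ragged or missing values near line {bad}")
    region_map: dict[str, str] = {}
    meta_path = Path(str(path) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        rate = rate if rate is not None else meta.get("rate_hz")
        region_map = meta.get("region_map", {})
    if rate is None:
        raise ParseError(f"{path}: sampling rate not given and no sidecar found")
    return Recording(df.to_numpy().T, float(rate), list(df.columns), region_map)


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = f"{value:.{max(width - 7, 1)}g}" if isinstance(value, float) else s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> None:
    """Minimal EDF writer: 16-bit samples, physical units microvolts.

    The signal is split into records of 1 s (or 0.5 s when that fits the
    length better); a trailing partial record is zero-padded with a
    warning.
    """
    import warnings

    path = Path(path)
    n_ch, n = rec.n_channels, rec.n_samples
    rec_dur = 1.0
    for cand in (1.0, 0.5, 0.25, 0.1):
        spr = rec.rate * cand
        if abs(spr - round(spr)) < 1e-9 and abs((n / spr) - round(n / spr)) < 1e-9:
            rec_dur = cand
            break
    spr = int(round(rec.rate * rec_dur))
    n_rec = int(np.ceil(n / spr))
    if n_rec * spr != n:
        warnings.warn("recording length is not a whole number of EDF records; "
                      "zero-padding the final record")
    pmin = float(min(rec.data.min(), -1e-6))
    pmax = float(max(rec.data.max(), 1e-6))
    dmin, dmax = -32768, 32767
    scale = (pmax - pmin) / (dmax - dmin)
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :n] = rec.data
    digital = np.clip(np.round((padded - pmin) / scale) + dmin, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field("X", 80))
        fh.write(_edf_field("Startdate X gaitconn", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(256 * (n_ch + 1), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field(n_rec, 8))
        fh.write(_edf_field(rec_dur if rec_dur != int(rec_dur) else int(rec_dur), 8))
        fh.write(_edf_field(n_ch, 4))
        for name in rec.channel_names:
            fh.write(_edf_field(name[:16], 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for _ in range(n_ch):
            fh.write(_edf_field(f"{pmin:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_edf_field(f"{pmax:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_edf_field(dmin, 8))
        for _ in range(n_ch):
            fh.write(_edf_field(dmax, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))
        for _ in range(n_ch):
            fh.write(_edf_field(spr, 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path, region_map: dict[str, str] | None = None) -> Recording:
    """Read an EDF recording via MNE (data returned in microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names),
                     region_map or {})


def read_recording(path: str | Path, fmt: str | None = None,
                   rate: float | None = None) -> Recording:
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if fmt == "edf":
        return read_edf(path)
    if fmt == "delimited":
        return read_recording_csv(path, rate=rate)
    raise ParseError(f"unknown recording format {fmt!r}")


# -------------------------------------------------------------- event tables

def write_events(events: GaitEventTable, path: str | Path) -> None:
    events.df.to_csv(path, index=False, float_format="%.9g")


def read_events(path: str | Path) -> GaitEventTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return GaitEventTable(df)


def write_region_map(region_map: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"channel": list(region_map), "region": list(region_map.values())}
    ).to_csv(path, index=False)


def read_region_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["channel"].astype(str), df["region"].astype(str)))


# -------------------------------------------------------------- ground truth

def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth as JSON: coupling tensor plus the generated schedule."""
    doc = {
        "conditions": list(truth.conditions),
        "phases": list(truth.phases),
        "coupling": truth.coupling.tolist(),
        "schedule": truth.schedule.df.to_dict(orient="list"),
    }
    Path(path).write_text(json.dumps(doc))


def read_ground_truth(path: str | Path) -> GroundTruth:
    doc = json.loads(Path(path).read_text())
    return GroundTruth(
        coupling=np.asarray(doc["coupling"], dtype=float),
        conditions=tuple(doc["conditions"]),
        phases=tuple(doc["phases"]),
        schedule=GaitEventTable(pd.DataFrame(doc["schedule"])),
    )


# ----------------------------------------------------------- epoch/PLI dumps

def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    """EpochSet as .npz plus a JSON sidecar with rate/offset/conditions."""
    path = Path(path)
    np.savez_compressed(path, data=epochs.data)
    meta = {
        "rate_hz": epochs.rate,
        "t0_offset_s": epochs.t0_offset_s,
        "conditions": [str(c) for c in epochs.conditions],
        "channel_names": list(epochs.channel_names),
        "region_map": epochs.region_map,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    data = np.load(path)["data"]
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    return EpochSet(
        data,
        meta["rate_hz"],
        np.asarray(meta["conditions"], dtype=object),
        meta["channel_names"],
        meta.get("region_map", {}),
        t0_offset_s=meta["t0_offset_s"],
    )


def write_tensor(values: np.ndarray, path: str | Path, **header) -> None:
    """Any PLI tensor as .npz with a JSON header describing the dims."""
    np.savez_compressed(path, values=values)
    header = {"shape": list(values.shape), **header}
    Path(str(path) + ".meta.json").write_text(json.dumps(header, indent=1, default=str))


def read_tensor(path: str | Path) -> tuple[np.ndarray, dict]:
    values = np.load(path)["values"]
    header = json.loads(Path(str(path) + ".meta.json").read_text())
    return values, header


def export_slice_csv(matrix: np.ndarray, path: str | Path,
                     labels: list[str] | None = None) -> None:
    """One channel x channel connectivity slice as CSV."""
    df = pd.DataFrame(matrix, index=labels, columns=labels)
    df.to_csv(path, float_format="%.9g")


def write_edge_list(weights: np.ndarray, path: str | Path,
                    labels: list[str] | None = None) -> None:
    n = weights.shape[0]
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(n)]
    rows = [
        {"node_i": labels[i], "node_j": labels[j], "weight": weights[i, j]}
        for i in range(n)
        for j in range(i + 1, n)
        if weights[i, j] > 0
    ]
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path, index=False, float_format="%.9g"
    )
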