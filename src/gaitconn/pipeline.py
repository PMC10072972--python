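"""End-to-end pipeline: simulate-or-load through classification.

Every run writes its artifacts plus a machine-readable ``log.json``
(package/library versions, seed, SHA-256 of the canonical config) into
the output directory, and is deterministic for a fixed config: all
randomness flows from the single config seed through a documented
derivation rule (:func:`derive_seed`).
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, connectivity, features, io, network, preprocess, stats, synth

#: stage order used both for execution and for seed derivation
STAGES = ("simulate", "preprocess", "connect", "metrics", "stats", "classify")


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed: SeedSequence(seed, spawn_key=(stage index,))."""
    ss = np.random.SeedSequence(seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Validated parameters of one pipeline run."""

    out_dir: str = "gaitconn_run"
    recording_path: str | None = None  # None -> simulate
    events_path: str | None = None
    region_map_path: str | None = None
    n_epochs_per_condition: int = 30
    noise_sigma: float = 0.2
    notch_hz: float | None = 50.0
    band: tuple[float, float] = (3.0, 50.0)
    target_rate: float = 500.0
    win_len_s: float = 0.250
    step_s: float = 0.125
    threshold_fraction: float = 0.5
    classifiers: tuple[str, ...] = ("SVM", "NB", "KNN")
    families: tuple[str, ...] = ("whole_pli", "tv_pli", "merged_phases")
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.target_rate / 2):
            raise ValueError("band must lie inside (0, target Nyquist)")
        if not (0 <= self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must lie in [0, 1)")
        if abs(self.step_s - self.win_len_s / 2) > 1e-12:
            raise ValueError("step must be half the window length (50% overlap)")
        for clf in self.classifiers:
            if clf not in features.CLASSIFIERS:
                raise ValueError(f"unknown classifier {clf!r}")
        for fam in self.families:
            if fam not in features.FAMILIES and fam != "raw":
                raise ValueError(f"unknown feature family {fam!r}")
        if (self.recording_path is None) != (self.events_path is None):
            raise ValueError("recording_path and events_path must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in doc:
            doc["band"] = tuple(doc["band"])
        for key in ("classifiers", "families"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _log(out: Path, config: PipelineConfig) -> None:
    import scipy
    import sklearn

    doc = {
        "gaitconn": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }
    (out / "log.json").write_text(json.dumps(doc, indent=1, default=str))


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures propagate as ``PipelineError`` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if config.recording_path is None:
            sim = synth.SimConfig(
                n_epochs_per_condition=config.n_epochs_per_condition,
                noise_sigma=config.noise_sigma,
                seed=derive_seed(config.seed, "simulate"),
            )
            rec, events, truth = synth.simulate_recording(sim)
            io.write_events(events, out / "events.csv")
            io.write_ground_truth(truth, out / "ground_truth.json")
            io.write_region_map(rec.region_map, out / "region_map.csv")
        else:
            rec = io.read_recording(config.recording_path)
            events = io.read_events(config.events_path)
            if config.region_map_path:
                rec.region_map = io.read_region_map(config.region_map_path)

        stage = "preprocess"
        epochs = preprocess.preprocess_recording(
            rec, events, notch_hz=config.notch_hz, band=config.band,
            target_hz=config.target_rate,
        )
        if epochs.n_epochs == 0:
            raise ValueError("no usable epochs")
        io.write_epochs(epochs, out / "epochs.npz")

        stage = "connect"
        grid = connectivity.WindowGrid(
            config.win_len_s, config.step_s, epochs.n_samples / epochs.rate
        )
        tensor = connectivity.sliding_pli(epochs, grid)
        io.write_tensor(tensor.values, out / "pli_windows.npz",
                        kind="windowed PLI", grid=asdict_grid(grid),
                        conditions=[str(c) for c in tensor.conditions])
        phase_conn = connectivity.collapse_phases(tensor)
        io.write_tensor(phase_conn.values, out / "pli_phases.npz",
                        kind="phase-collapsed PLI", phases=list(phase_conn.phases),
                        conditions=[str(c) for c in phase_conn.conditions])
        cond_avg, conds = connectivity.condition_average(phase_conn)
        io.write_tensor(cond_avg, out / "pli_condition_average.npz",
                        kind="condition-average PLI", conditions=list(conds),
                        phases=list(phase_conn.phases))

        stage = "metrics"
        rows = []
        labels = list(tensor.channel_names)
        for ci, cond in enumerate(conds):
            for pi, phase in enumerate(phase_conn.phases):
                g = network.WeightedGraph(cond_avg[ci, pi], labels, rec.region_map)
                gm = network.global_metrics(g)
                for name, val in zip(network.GLOBAL_METRIC_NAMES, gm.as_tuple()):
                    rows.append({"condition": cond, "phase": phase,
                                 "metric": name, "value": val})
                lm = network.local_metrics(g)
                for name in network.LOCAL_METRIC_NAMES:
                    for region, val in network.region_means(
                        lm.by_name(name), labels, rec.region_map
                    ).items():
                        rows.append({"condition": cond, "phase": phase,
                                     "metric": f"{name}[{region}]", "value": val})
                io.write_edge_list(
                    network.threshold_edges(g, config.threshold_fraction).weights,
                    out / f"edges_{cond}_{phase}.csv", labels,
                )
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        network.timecourse_global(tensor).to_csv(out / "timecourse.csv", index=False)

        stage = "stats"
        per_epoch: dict[str, dict[str, dict[str, np.ndarray]]] = {
            m: {} for m in network.GLOBAL_METRIC_NAMES
        }
        ep_labels = np.asarray(phase_conn.conditions, dtype=str)
        vals = np.zeros((phase_conn.values.shape[0], 4, 3))
        for e in range(vals.shape[0]):
            for p in range(4):
                vals[e, p] = network.global_metrics(
                    network.WeightedGraph(phase_conn.values[e, p])
                ).as_tuple()
        for mi, metric in enumerate(network.GLOBAL_METRIC_NAMES):
            for pi, phase in enumerate(phase_conn.phases):
                per_epoch[metric][phase] = {
                    c: vals[ep_labels == c, pi, mi] for c in conds
                }
        stats.metric_anova_table(per_epoch).to_csv(out / "anova.csv", index=False)

        stage = "classify"
        fsets = {}
        for fam in config.families:
            if fam == "merged_phases":
                for k in range(1, 5):
                    fsets[f"merged_phases_{k}"] = features.build_features(
                        "merged_phases", phase_conn=phase_conn, k_phases=k
                    )
            elif fam in ("raw", "whole_pli"):
                fsets[fam] = features.build_features(fam, epochs=epochs)
            else:
                fsets[fam] = features.build_features(fam, phase_conn=phase_conn)
        table = features.compare_families(
            fsets, config.classifiers, config.n_folds,
            seed=derive_seed(config.seed, "classify"),
        )
        table.to_csv(out / "classification.csv", index=False)
        (out / "classification.json").write_text(
            json.dumps(table.to_dict(orient="records"), indent=1)
        )
        _log(out, config)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return out


class PipelineError(RuntimeError):
    pass


def asdict_grid(grid: connectivity.WindowGrid) -> dict:
    return {
        "win_len_s": grid.win_len_s,
        "step_s": grid.step_s,
        "epoch_len_s": grid.epoch_len_s,
        "n_windows": grid.n_windows,
    }
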