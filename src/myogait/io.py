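"""Trial persistence and multi-rate stream alignment.

Trials are stored either in a single HDF5 container (groups ``/emg``, ``/fsr``,
``/angle``, ``/labels``; sampling rates, condition and seed as attributes) or
as a directory of plain CSV files (one per stream, first column time in
seconds, plus ``meta.json`` for rates and channel names). The container format
round-trips bit-exactly.

Alignment places every stream on the sEMG clock: the phase label of an sEMG
sample is the label of the nearest foot-switch sample in time (nearest
neighbour, because phase is categorical), and the angle is exposed as a
linearly interpolated query function clamped at the trace ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .simulate import PHASES, PhaseLabels, Trial


def save_trial(trial: Trial, path: str | Path, format: str = "container") -> Path:
    """Write a trial to ``path`` in the given format ('container' or 'csv-dir')."""
    path = Path(path)
    if format == "container":
        _save_h5(trial, path)
    elif format == "csv-dir":
        _save_csv_dir(trial, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def load_trial(path: str | Path, format: str | None = None) -> Trial:
    """Read a trial written by :func:`save_trial`."""
    path = Path(path)
    if format is None:
        format = "csv-dir" if path.is_dir() else "container"
    if format == "container":
        return _load_h5(path)
    if format == "csv-dir":
        return _load_csv_dir(path)
    raise ValueError(f"unknown format {format!r}")


def _save_h5(trial: Trial, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("emg")
        g.create_dataset("data", data=trial.emg)
        g.create_dataset(
            "channel_names", data=np.array(trial.channel_names, dtype="S16")
        )
        g.attrs["fs"] = trial.fs_emg
        g = f.create_group("fsr")
        g.create_dataset("heel", data=trial.fsr_heel)
        g.create_dataset("toe", data=trial.fsr_toe)
        g.attrs["fs"] = trial.fs_fsr
        g = f.create_group("angle")
        g.create_dataset("data", data=trial.angle)
        g.attrs["fs"] = trial.fs_angle
        g = f.create_group("labels")
        g.create_dataset("phase", data=trial.phase_truth.labels)
        g.create_dataset("cycle_starts", data=trial.phase_truth.cycle_starts)
        g.attrs["fs"] = trial.phase_truth.fs
        f.attrs["condition"] = trial.condition
        f.attrs["meta"] = json.dumps(trial.meta)


def _require(f: h5py.File, name: str):
    if name.split("/")[0] not in f:
        raise KeyError(f"stream '{name.split('/')[0]}' not found")
    try:
        return f[name]
    except KeyError:
        raise KeyError(f"stream '{name}' not found") from None


def _fs_attr(group) -> float:
    if "fs" not in group.attrs:
        raise KeyError(f"rate attribute 'fs' absent from group '{group.name}'")
    return float(group.attrs["fs"])


def _load_h5(path: Path) -> Trial:
    with h5py.File(path, "r") as f:
        emg = _require(f, "emg/data")[()]
        names = tuple(n.decode() for n in _require(f, "emg/channel_names")[()])
        fs_emg = _fs_attr(f["emg"])
        heel = _require(f, "fsr/heel")[()]
        toe = _require(f, "fsr/toe")[()]
        fs_fsr = _fs_attr(f["fsr"])
        angle = _require(f, "angle/data")[()]
        fs_angle = _fs_attr(f["angle"])
        labels = _require(f, "labels/phase")[()]
        cyc = _require(f, "labels/cycle_starts")[()]
        fs_lab = _fs_attr(f["labels"])
        condition = str(f.attrs.get("condition", "noExo"))
        meta = json.loads(f.attrs.get("meta", "{}"))
    return Trial(
        emg=emg,
        fsr_heel=heel,
        fsr_toe=toe,
        angle=angle,
        phase_truth=PhaseLabels(labels=labels, fs=fs_lab, cycle_starts=cyc),
        channel_names=names,
        fs_emg=fs_emg,
        fs_fsr=fs_fsr,
        fs_angle=fs_angle,
        condition=condition,
        meta=meta,
    )


def _save_csv_dir(trial: Trial, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    t = np.arange(trial.emg.shape[1]) / trial.fs_emg
    df = pd.DataFrame({"time_s": t})
    for name, row in zip(trial.channel_names, trial.emg):
        df[name] = row
    df.to_csv(path / "emg.csv", index=False)
    t = np.arange(len(trial.fsr_heel)) / trial.fs_fsr
    pd.DataFrame({"time_s": t, "heel": trial.fsr_heel, "toe": trial.fsr_toe}).to_csv(
        path / "fsr.csv", index=False
    )
    t = np.arange(len(trial.angle)) / trial.fs_angle
    pd.DataFrame({"time_s": t, "angle_deg": trial.angle}).to_csv(
        path / "angle.csv", index=False
    )
    t = np.arange(len(trial.phase_truth)) / trial.phase_truth.fs
    pd.DataFrame(
        {"time_s": t, "phase": [PHASES[k] for k in trial.phase_truth.labels]}
    ).to_csv(path / "labels.csv", index=False)
    meta = {
        "fs_emg": trial.fs_emg,
        "fs_fsr": trial.fs_fsr,
        "fs_angle": trial.fs_angle,
        "fs_labels": trial.phase_truth.fs,
        "channel_names": list(trial.channel_names),
        "condition": trial.condition,
        "cycle_starts": [int(i) for i in trial.phase_truth.cycle_starts],
        "meta": trial.meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _load_csv_dir(path: Path) -> Trial:
    for stream in ("emg", "fsr", "angle", "labels"):
        if not (path / f"{stream}.csv").exists():
            raise FileNotFoundError(f"stream '{stream}' not found in {path}")
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"meta.json (rate attributes) not found in {path}")
    meta = json.loads(meta_path.read_text())
    emg_df = pd.read_csv(path / "emg.csv")
    names = tuple(meta["channel_names"])
    emg = emg_df[list(names)].to_numpy().T
    fsr = pd.read_csv(path / "fsr.csv")
    angle = pd.read_csv(path / "angle.csv")["angle_deg"].to_numpy()
    lab_df = pd.read_csv(path / "labels.csv")
    codes = np.array([PHASES.index(p) for p in lab_df["phase"]], dtype=np.int8)
    labels = PhaseLabels(
        labels=codes,
        fs=float(meta["fs_labels"]),
        cycle_starts=np.asarray(meta["cycle_starts"], dtype=np.int64),
    )
    return Trial(
        emg=emg,
        fsr_heel=fsr["heel"].to_numpy(),
        fsr_toe=fsr["toe"].to_numpy(),
        angle=angle,
        phase_truth=labels,
        channel_names=names,
        fs_emg=float(meta["fs_emg"]),
        fs_fsr=float(meta["fs_fsr"]),
        fs_angle=float(meta["fs_angle"]),
        condition=meta.get("condition", "noExo"),
        meta=meta.get("meta", {}),
    )


@dataclass
class AlignedTrial:
    """A trial with all streams referenced to the sEMG clock.

    ``phase`` holds one label per sEMG sample (nearest-neighbour transfer from
    the foot-switch clock); :meth:`angle_at` linearly interpolates the angle
    trace, clamping queries outside the recorded interval.
    """

    emg: np.ndarray
    fs_emg: float
    phase: np.ndarray
    angle: np.ndarray
    fs_angle: float
    channel_names: tuple[str, ...]
    condition: str = "noExo"
    meta: dict = field(default_factory=dict)

    @property
    def duration_s(self) -> float:
        return self.emg.shape[1] / self.fs_emg

    @property
    def angle_t_last(self) -> float:
        return (len(self.angle) - 1) / self.fs_angle

    def angle_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        ta = np.arange(len(self.angle)) / self.fs_angle
        return np.interp(t, ta, self.angle)  # np.interp clamps at both ends


def align(trial: Trial | AlignedTrial) -> AlignedTrial:
    """Place all streams of a trial on the sEMG clock (idempotent)."""
    if isinstance(trial, AlignedTrial):
        return trial
    if trial.emg.size == 0 or len(trial.phase_truth) == 0:
        raise ValueError("cannot align a trial with empty streams or labels")
    n_emg = trial.emg.shape[1]
    t_emg = np.arange(n_emg) / trial.fs_emg
    idx = np.rint(t_emg * trial.phase_truth.fs).astype(np.int64)
    idx = np.clip(idx, 0, len(trial.phase_truth) - 1)
    phase = trial.phase_truth.labels[idx]
    return AlignedTrial(
        emg=trial.emg,
        fs_emg=trial.fs_emg,
        phase=phase,
        angle=trial.angle,
        fs_angle=trial.fs_angle,
        channel_names=trial.channel_names,
        condition=trial.condition,
        meta=dict(trial.meta),
    )
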